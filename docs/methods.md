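# Methods

## Model class and assumptions

The package analyzes autonomous ODE systems `dx_i/dt = F_i(x)` in which every
`F_i` is continuous, monotonic in each of its arguments, and strictly
decreasing in `x_i` (an implicit first-order decay).  Models carry a
rectangular *region of validity* — per-variable closed intervals whose
endpoints may be `±inf` — within which all statements, bounds, and
adversarial controls live.  *Uncertain terms* such as `f(y)` are functions of
the state about which only a global range `[f_lo, f_hi]` and optional
per-argument monotonicity are known; every bound computed here uses only the
range, so results are uniform over all admissible realizations, including
discontinuous or stochastic ones.

Weakly decreasing self-dependence (e.g. piecewise-constant decay) is rejected
by `validate_decay`: uniqueness of the per-variable steady states in the
cascade solver relies on strict decay.  Self-referencing Boolean rules
(`A, A`) convert to ODEs whose net self-derivative `(H'(x) − 1)/τ` changes
sign for steep Hill coefficients; such models are flagged by `validate_decay`
and are outside the automated loop analysis (they still parse, convert, and
support direct bound computations).

## Sign establishment

Interaction signs are established symbolically: the partial derivative of
`F_i` is rewritten over fresh nonnegative symbols that sweep exactly the
validity box (`[lo, ∞) → lo + t`, `[lo, hi] → (lo + hi·t)/(1 + t)` with
`t ≥ 0`), reduced to a ratio of polynomial-like expressions, and sign-checked
term by term.  Influence through an uncertain term is chained through the
term's declared monotonicity.  If the symbolic attempt is inconclusive the
model's declared signs (`sign y -> x +` lines) are consulted; otherwise the
sign is *indefinite*, which blocks graph construction for that pair but is a
value, not an error.  Finite-difference property tests cross-check the
symbolic signs at random interior points.

## Monotone bounds

`monotone_bound` bounds `F_i` over a sub-box by substituting, for each
argument, the interval endpoint dictated by its sign and the requested side.
Finite endpoints are substituted simultaneously; infinite endpoints are
resolved afterwards by symbolic limits, one variable at a time in sorted
order (the expressions in this class are rationals of Hill terms, for which
iterated limits are unambiguous).  A bound that diverges to the unfavorable
infinity raises `UnboundedError` rather than clamping silently.  All
certification works with closed regions; reports print strict inequalities,
matching the convention of the field.

## Worst-case construction and the characteristic map

For a candidate module over a positive-loop union, every regulatory argument
of `F_i` that is not a loop-internal edge is pinned at the extreme of its
validity interval that pushes `x_i` toward its threshold — minimizing `F_i`
for "high" statements, maximizing for "low" — with limits for infinite
endpoints.  Uncertain terms are always pinned at a range endpoint; a union
edge mediated solely by an uncertain term therefore breaks, and such a
candidate simply fails certification.

The MIOS input variable is a candidate variable whose deletion makes the
pinned subsystem acyclic.  When several qualify, variables whose RHS actually
received a worst-case substitution are preferred (the loop is opened where it
was cut off from the environment), then lexicographic order; the computed
thresholds are invariant to this choice, only the scale of the characteristic
map changes.

`characteristic_map(u)` holds the input at `u` and solves each downstream
steady state in topological order by bracketed root-finding (Brent, xtol
1e−13) on `F_i = 0`; strict decay guarantees a unique root; roots outside the
validity closure are reported with the offending variable.  Fixed points of
`h` are located by a sign-change scan (default 256 grid points) with
bisection to 1e−10, plus endpoint checks.  Tangential fixed points below grid
resolution are missed — documented, and exercised by a constructed test.  For
inputs with an infinite validity endpoint the scan window is truncated using
boundedness of `h` (every fixed point satisfies `u* ≤ sup h`, estimated by
probing `h` far out).  Monotonicity of `h`, a consequence of the positive
loop closure, is asserted on every scan grid.

## Certification

A candidate with thresholds `T` is certified iff (a) the worst-case residuals
`|F_i^{wc}(T)|` are below tolerance (default 1e−9), and (b) for every module
variable the monotone bound of the *true* RHS on the module face — that
variable at its threshold, the other module variables on their module side,
externals free over validity, uncertain terms over their full range — points
inward.  Condition (b) is the substance of the invariance claim: any
deviation of an external from its worst case only strengthens the inward
bound (monotonicity), so the module region is positively invariant under
arbitrary valid control of non-module variables.  Fixed points on the
validity boundary (e.g. 0) are kept: boundary equilibria generate the
"everything positive" style modules.  Both polarities of each candidate are
processed and duplicates removed by statement set.

## Expanded network semantics

Maintenance of `Y` by `X` is certified when the bound of the target's RHS on
`{X true} ∩ {target at its threshold}` is inward (`≥ 0` for `>`); driving
additionally requires a strictly positive inward bound over the whole
`{X true, Y false}` region, which yields finite-time activation with a
uniform margin.  A zero bound therefore certifies maintenance but only
*asymptotic* approach, not driving — e.g. `z > z0` maintains `x > z0 − 1` in
`dx/dt = z + s(y) − x` with `s ∈ [−1, 1]`, but drives only strictly looser
thresholds.  A virtual node whose face bound is inward with all other
variables free gets a self-maintenance loop; with boundary thresholds (such
as `x > 0` over the positive orthant) this is common and correct — each such
statement is genuinely self-sustaining — and it means boundary statements
appear as singleton motifs, with the larger classical modules returned as
(non-minimal) stable modules.

Composites are auto-generated per target from conjunctions (default arity
≤ 3) of virtual nodes over distinct regulator variables, kept only when the
conjunction certifies while no nonempty proper sub-conjunction does.
Explicitly constructed composites of any consistent shape can always be
certified directly.

Stable modules are enumerated inside the maximal source-free,
composite-closed subnetwork (iterative pruning).  Motif search uses recursive
strongly-connected-component decomposition (each SCC, then the SCCs of the
SCC with one node removed, and so on, with a visited-set cap of 4096
subsets), closing each core under composite factors and keeping sets that
satisfy all three module conditions; minimal ones are motifs.  An exhaustive
subset-enumeration oracle validates this against small networks in the test
suite.  Statement consistency is interval intersection per variable, with
`x > a` and `x < b` consistent iff `a < b`, and same-direction statements
merging to the stronger.

Reduction under an active module removes satisfied factor edges (composites
shrink; arity-1 composites collapse to direct edges; fully satisfied
composites — and direct edges from satisfied statements — make their targets
self-sustaining) and deletes contradicted virtual nodes with their
dependents.  Module sequences are depth-first compositions of motifs through
reductions (caps: depth 12, 256 sequences); two sequences are mutually
exclusive when statements across them contradict.  Driver sets are found by
propagation to fixpoint — composites fire when all factors are true,
virtuals when implied by a true statement or reached by a driving edge —
over all consistent seed sets up to the requested size, filtered to minimal.

## Numerical verification

The falsification harness integrates segment-wise with LSODA (rtol 1e−8,
atol 1e−10), overriding clamped variables by their schedules and realizing
uncertain terms as seeded piecewise-constant signals (10 switches).  Each
invariance trial samples the initial state uniformly in the module region
shrunk by a relative margin (default 1e−6 of the capped width — the module
boundary may itself be an equilibrium face and exact-boundary starts are
numerically fragile) and assigns every non-module variable one of four
adversarial controls: lower clamp, upper clamp, random piecewise, or a
sinusoid sweeping the interval.  Infinite validity endpoints are truncated at
a finite adversary cap (default width 10) for sampling; since certification
covers the whole box, attacking a sub-box is sound.  Margins are evaluated on
a dense trajectory grid; validity escape is reported, never clipped.
Identical seeds give bit-identical reports.  Driver checks clamp the driver
variables at satisfying values (midpoint of the capped satisfying interval
by default) and require all module statements to activate by `t_end` and to
hold from first activation onward; `t_end` defaults to 50 characteristic
times for driver checks and 20 for invariance.

## Boolean conversion and consistency

`hill_ode` interpolates each rule's truth table multilinearly over the unit
cube and substitutes a Hill function for every literal (the non-normalized
HillCube construction; a `normalized` flag divides each `H` by `H(1)` so the
production term spans exactly `[0, 1]`).  Per-edge `n` and `k` and per-
variable `τ` broadcast from scalars; missing per-edge entries are errors.
Boolean-monotone edge signs (decided by truth table) are recorded as declared
signs, giving the symbolic machinery a sound fallback for steep exponents.
The default fixture parameters are `n = 2`, `k = 1/2`, `τ = 1`; the
consistency checks use `n = 8`, where the sigmoid is steep enough that every
brute-force Boolean self-sustaining partial state has a certified continuous
module with the same high/low pattern.  The Boolean oracles (synchronous
attractors ≤ 14 variables, partial fixed states ≤ 10) are deliberately
exhaustive and independent of the continuous pipeline.

## Synthetic data and problem sizes

The random in-class generator draws a signed digraph without self-loops
(edge probability = `density`), dresses each variable with a random monotone
Boolean rule over its regulators (literals folded with random AND/OR;
regulator-free variables decay to zero), and converts it with the default
Hill parameters.  It emulates the loop structure, saturating kinetics, and
unit-interval normalization typical of converted signaling models; it does
not emulate mass conservation, multi-timescale kinetics, or extrinsic noise,
so passing tests demonstrate correctness of the certification logic on the
supported class rather than fidelity to any particular organism.  The
verification studies use 20 models of 3–6 variables at density 0.3 with 50
adversarial trials per certified module over 10 time units (about ten decay
times at `τ = 1`), sizes at which every certified module can be attacked
thoroughly while the whole study remains a desk computation.

## Known limitations

- Only single-input loop openings are automated; candidates whose pinned
  subsystem needs a multi-node cut are reported as unsupported and skipped.
- Motif enumeration is exact on small expanded networks; the recursion cap
  makes very large networks return top-level cores only.
- Driving certification requires a uniform positive margin; asymptotically
  driven statements appear as maintenance-only edges.
- The numerical harness is a falsifier, not a verifier: it cannot prove
  invariance, only fail to break it under a budget of adversarial trials.
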
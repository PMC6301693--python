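# stablemodules

Certified trap subspaces ("stable modules") in ODE models of biological
networks.

Regulatory networks — signal transduction cascades, gene circuits, metabolic
switches — are usually modeled as coupled ODEs `dx_i/dt = F_i(x)` whose kinetic
parameters are poorly known.  This package extracts *qualitative, provable*
statements from such models: sets of threshold conditions `x_i > T_i` (or
`< T_i`) that, once satisfied, remain satisfied **forever**, no matter how any
variable outside the set is manipulated within the model's region of validity.
Such a set is a control-robust positively invariant set: a decision point of
the dynamics.  If a stable module describes a disease state, no therapy
targeting outside variables can disrupt it; if it describes a healthy state,
its *driver nodes* prescribe a control strategy to reach it.

The package is aimed at systems biologists and dynamical-systems modelers
working with monotone-with-decay models, the class where each `F_i` is
continuous, monotonic in every argument, and strictly decreasing in `x_i`
(Hill-type kinetics, mass-action with linear decay, and Boolean models
converted to Hill ODEs all qualify).  Bounded terms of unknown form
(`f(y) ≥ f_min`) are supported, so conclusions hold under large dynamical
uncertainty.

## The method

1. **Signed regulatory graph** — interaction signs are established
   symbolically over the validity box (`model.interaction_sign`,
   `model.regulatory_graph`).
2. **Positive feedback loops** — every control-robust module of this class
   lives on a sign-consistent union of positive cycles; these are enumerated
   (`feedback.positive_cycles`, `feedback.cycle_unions`) and each consistent
   union yields two conjectured modules, one per polarity of its ±1 vertex
   labeling.
3. **Worst-case monotone input-output analysis** — for each candidate, every
   regulatory effect external to the loop is pinned at the validity extreme
   least favorable to it (limits are taken for infinite bounds), producing a
   monotone loop.  Opening the loop at an input variable `x_k` gives the
   *characteristic map* `h(u)`: hold `x_k = u`, cascade the unique steady
   states through the acyclic remainder, and read back the balance of `x_k`.
   Fixed points `h(u*) = u*` are worst-case equilibria; the cascade values at
   `u*` become the module thresholds (`mios.worst_case_system`,
   `mios.characteristic_map`, `mios.find_fixed_points`).
4. **Certification** — a module is accepted only if the worst-case residuals
   vanish at the threshold point and the true vector field points inward on
   every face of the module region under arbitrary external configurations
   (`mios.certify_module`).  `mios.scan_stable_modules` runs steps 1–4.
5. **Expanded network** — statements (`x > T`) become *virtual nodes*,
   AND-conjunctions become *composite nodes*, and certified
   maintenance/driving edges connect them.  Source-free, composite-closed,
   consistent subnetworks are stable modules; minimal ones are stable motifs.
   Reduction and sequential composition build the system's repertoire of
   self-reinforcing cascades, and propagation over driving edges identifies
   minimal driver node sets (`expanded.*`).
6. **Falsification harness** — adversarial simulations (clamps, random
   piecewise controls, sinusoids, random realizations of uncertain terms)
   attack each certified module numerically (`verify.check_invariance`,
   `verify.check_driver`).

Boolean rule files can be converted to in-class Hill ODE models
(`boolhill.hill_ode`, multilinear truth-table interpolation with Hill-function
literals), and a brute-force Boolean oracle cross-validates the continuous
results against discrete self-sustaining patterns.

## Worked example

The five-variable demonstration system (positive orthant as region of
validity, `f(y) ≥ 1/10` otherwise unknown):

```text
var u in [0, inf]
var w in [0, inf]
var x in [0, inf]
var y in [0, inf]
var z in [0, inf]
term f(y) in [1/10, inf] increasing in y
ode u = 1/(1+z) - u^3
ode w = y - w/2
ode x = (1 + 4*w + 4*w*z)/((1+2*w)*(1+2*z)) - x
ode y = x/(x+1/2) - y
ode z = x*f(y) - z
```

```sh
$ stablemodules graph toy.model
variables: u, w, x, y, z
  w -> x (+)
  x -> y (+)
  x -> z (+)
  y -> w (+)
  y -> z (+)
  z -> u (-)
  z -> x (-)
decay check: pass
```

The only positive feedback loop is `y → w → x → y`.  For its "all high"
candidate the external inhibition of `x` by `z` is pinned at its worst case
(`z → ∞`), which turns the `x` equation into `dx/dt = 2w/(1+2w) − x`; the
characteristic map has fixed points `{0, 7/10}`, and the cascade at `7/10`
yields the thresholds below:

```sh
$ stablemodules analyze toy.model
```

reports three certified modules (thresholds printed as decimals with exact
small fractions recognized):

```text
['0', '0', '0']                                          certified
['1.166666667 (7/6)', '0.7 (7/10)', '0.5833333333 (7/12)']  certified
['1.556917857', '1.756917857', '0.7784589287']           certified
```

Read: once `w > 7/6`, `x > 7/10`, `y > 7/12` all hold, they hold forever —
for *any* behavior of `u`, `z`, and `f`, a claim `stablemodules verify`
confirms by adversarial simulation (and refutes for a deliberately
mis-thresholded set such as `x > 2`).  The zero-threshold module says the
open positive orthant of the loop is itself invariant; the third (a "low"
module) bounds the basin below the loop's upper equilibrium.

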
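"""Worst-case monotone input-output analysis: from candidate to certified module.

For a candidate module (a high/low conjecture over a positive-loop union) the
*worst-case system* pins every regulatory effect external to the loop at the
validity-interval extreme least favorable to the candidate: for a variable
conjectured "high", its RHS is minimized over the externals; for "low",
maximized.  The resulting subsystem is sign-consistent and monotone, so the
theory of monotone input-output systems applies: opening the loop at one
variable (the MIOS input) whose removal makes the subsystem acyclic yields a
characteristic map h(u) — hold the input at u, cascade the unique per-variable
steady states through the acyclic remainder, and read off the balance value of
the input's own RHS.  Fixed points of h are equilibria of the worst-case
system; their cascade values supply thresholds at which the candidate's
statements are certified as a genuine trap subspace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import sympy as sp

from .feedback import (
    HIGH, LOW, CandidateModule, conjecture_candidates, cycle_unions,
    positive_cycles)
from .model import (
    Box, IndefiniteSignError, ModelSystem, UnboundedError, _TERM_PREFIX,
    interaction_sign, monotone_bound, regulatory_graph)


class RootOutOfBoundsError(ValueError):
    """A cascade steady state left the validity closure."""

    def __init__(self, variable: str, message: str):
        super().__init__(message)
        self.variable = variable


# --------------------------------------------------------------------------- #
# worst-case system construction
# --------------------------------------------------------------------------- #

@dataclass
class WorstCaseSystem:
    """The candidate's sign-consistent subsystem with externals pinned."""

    base: ModelSystem
    candidate: CandidateModule
    rhs: dict  # candidate variable -> substituted sympy expression
    substitutions: dict  # (target, source) -> pinned endpoint

    @property
    def variables(self) -> tuple:
        return tuple(sorted(self.candidate.variables))

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for v in self.variables:
            for s in self.rhs[v].free_symbols:
                name = str(s)
                if name != v and name in self.candidate.variables:
                    g.add_edge(name, v)
        return g


def worst_case_system(model: ModelSystem, candidate: CandidateModule) -> WorstCaseSystem:
    """Pin every regulatory argument external to the candidate's loop union at
    the validity extreme pushing the target toward its threshold (infinite
    endpoints via symbolic limits); loop-internal edges are kept symbolic."""
    directions = candidate.directions
    internal_pairs = {(s, t) for s, t, _ in candidate.union.edges}
    rhs = {}
    substitutions = {}
    for target in sorted(candidate.variables):
        expr = model.rhs_flat(target)
        finite, limits = {}, []
        for s in sorted(expr.free_symbols, key=str):
            n = str(s)
            name = n[len(_TERM_PREFIX):] if n.startswith(_TERM_PREFIX) else n
            is_term = n.startswith(_TERM_PREFIX)
            if not is_term and name == target:
                continue  # own decay stays dynamic
            if not is_term and (name, target) in internal_pairs:
                continue  # loop-internal regulation stays symbolic
            sg = interaction_sign(model, target, name)
            if sg == 0:
                continue
            if sg == "indefinite":
                raise IndefiniteSignError(
                    f"sign of {name} -> {target} could not be established")
            lo, hi = model.interval_of(name)
            minimize = directions[target] == HIGH
            endpoint = (lo if sg == 1 else hi) if minimize else (hi if sg == 1 else lo)
            substitutions[(target, name)] = endpoint
            if endpoint in (sp.oo, -sp.oo):
                limits.append((s, endpoint))
            else:
                finite[s] = endpoint
        e = expr.xreplace(finite)
        for s, endpoint in limits:
            try:
                e = sp.limit(e, s, endpoint)
            except Exception as exc:
                raise UnboundedError(
                    f"worst-case limit of F_{target} as {s} -> {endpoint} "
                    f"failed: {exc}") from exc
        if e.has(sp.oo) or e.has(-sp.oo) or e.has(sp.zoo) or e.has(sp.nan):
            raise UnboundedError(
                f"worst-case RHS for {target} diverges under pinned externals")
        rhs[target] = sp.simplify(e)
    return WorstCaseSystem(
        base=model, candidate=candidate, rhs=rhs, substitutions=substitutions)


def select_mios_input(wc: WorstCaseSystem) -> str | None:
    """A candidate variable whose deletion leaves the worst-case subsystem
    acyclic; None if no single variable suffices (the candidate is then
    unsupported by this automation and skipped).

    Tie-break: variables whose RHS received a worst-case substitution are
    preferred (the loop is opened where it was cut off from the outside, which
    keeps the characteristic equation in the variable the analysis perturbed),
    then lexicographic order.
    """
    g = wc.graph()
    pinned = {t for (t, _s) in wc.substitutions}
    for v in sorted(wc.variables, key=lambda v: (v not in pinned, v)):
        h = g.copy()
        h.remove_node(v)
        if nx.is_directed_acyclic_graph(h):
            return v
    return None


# --------------------------------------------------------------------------- #
# cascade steady states and the characteristic map
# --------------------------------------------------------------------------- #

_BRENT_XTOL = 1e-13


def _decay_root(fn, lo: float, hi: float, variable: str) -> float:
    """Unique zero of a function strictly decreasing on [lo, hi] (strict decay
    guarantees uniqueness); bracketed root-finding, geometric expansion toward
    infinite endpoints."""
    from scipy.optimize import brentq

    if math.isinf(hi):
        width = max(1.0, abs(lo) if not math.isinf(lo) else 1.0)
        hi = (lo if not math.isinf(lo) else 0.0) + width
        for _ in range(80):
            if fn(hi) < 0:
                break
            hi *= 2.0
        else:
            raise RootOutOfBoundsError(
                variable, f"steady state of {variable} diverges above validity")
    if math.isinf(lo):
        lo = hi - max(1.0, abs(hi))
        for _ in range(80):
            if fn(lo) > 0:
                break
            lo -= max(1.0, abs(lo))
        else:
            raise RootOutOfBoundsError(
                variable, f"steady state of {variable} diverges below validity")
    flo, fhi = fn(lo), fn(hi)
    if flo < 0:
        raise RootOutOfBoundsError(
            variable, f"steady state of {variable} lies below validity "
            f"(F({lo}) = {flo} < 0)")
    if fhi > 0:
        raise RootOutOfBoundsError(
            variable, f"steady state of {variable} lies above validity "
            f"(F({hi}) = {fhi} > 0)")
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    return brentq(fn, lo, hi, xtol=_BRENT_XTOL)


class _Cascade:
    """Compiled steady-state cascade of a worst-case system opened at one input."""

    def __init__(self, wc: WorstCaseSystem, input_var: str):
        g = wc.graph()
        if input_var not in g:
            raise ValueError(f"{input_var} is not a candidate variable")
        h = g.copy()
        h.remove_node(input_var)
        if not nx.is_directed_acyclic_graph(h):
            raise ValueError(f"removing {input_var} does not break all cycles")
        self.wc = wc
        self.input_var = input_var
        self.order = list(nx.lexicographical_topological_sort(h))
        self.funcs = {}
        names = [input_var] + self.order
        syms = [sp.Symbol(n, real=True) for n in names]
        for v in self.order + [input_var]:
            self.funcs[v] = sp.lambdify(
                syms, wc.rhs[v], modules=["math"])

    def steady_state(self, u: float) -> dict:
        """Hold the input at u; per-variable unique roots in topological order."""
        vals = {self.input_var: float(u)}
        for v in self.order:
            lo, hi = (float(b) for b in _validity_floats(self.wc.base, v))
            fn = lambda x, v=v: self.funcs[v](
                *[x if n == v else vals.get(n, 0.0)
                  for n in [self.input_var] + self.order])
            vals[v] = _decay_root(fn, lo, hi, v)
        return vals

    def balance(self, u: float) -> float:
        """h(u): the root of the input's own RHS given the upstream cascade."""
        vals = self.steady_state(u)
        lo, hi = (float(b) for b in _validity_floats(self.wc.base, self.input_var))
        fn = lambda r: self.funcs[self.input_var](
            *[r if n == self.input_var else vals[n]
              for n in [self.input_var] + self.order])
        return _decay_root(fn, lo, hi, self.input_var)


def _validity_floats(model: ModelSystem, v: str):
    lo, hi = model.validity[v]
    return (-math.inf if lo == -sp.oo else float(lo),
            math.inf if hi == sp.oo else float(hi))


_cascade_cache: dict = {}


def _cascade(wc: WorstCaseSystem, input_var: str) -> _Cascade:
    key = (id(wc), input_var)
    if key not in _cascade_cache:
        _cascade_cache[key] = _Cascade(wc, input_var)
    return _cascade_cache[key]


def characteristic_map(wc: WorstCaseSystem, input_var: str, u) -> float:
    """The feedback characteristic map h(u) of the worst-case system."""
    return _cascade(wc, input_var).balance(float(u))


# --------------------------------------------------------------------------- #
# fixed points and thresholds
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class FixedPoint:
    value: float
    crossing: str  # "endpoint", "down", "up", or "tangent"


def _scan_interval(casc: _Cascade, lo: float, hi: float) -> tuple[float, float]:
    """Finite scan window for the characteristic map.  An infinite upper
    endpoint is replaced using boundedness of h: every fixed point satisfies
    u* = h(u*) <= sup h, estimated by evaluating h far out."""
    if not math.isinf(hi):
        return lo, hi
    base = lo if not math.isinf(lo) else 0.0
    probe = max(1.0, base + 1.0)
    cap = None
    for _ in range(40):
        try:
            val = casc.balance(probe)
        except RootOutOfBoundsError:
            break
        if val < probe:
            cap = max(base + 1.0, 1.5 * val + 1.0)
            break
        probe *= 8.0
    if cap is None:
        cap = probe
    return lo, min(cap, probe)


def find_fixed_points(wc: WorstCaseSystem, input_var: str,
                      grid_n: int = 256, tol: float = 1e-10) -> list:
    """All solutions of h(u) = u in the validity closure of the input.

    Sign-change scan of g(u) = h(u) - u on a ``grid_n``-point grid followed by
    bisection to ``tol``; endpoint fixed points included; sorted ascending and
    annotated with the local crossing direction of g.  Tangential fixed points
    below grid resolution are missed (documented behavior).  Monotonicity of h
    (a consequence of the positive loop closure) is asserted on the scan grid.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    casc = _cascade(wc, input_var)
    lo, hi = _validity_floats(wc.base, input_var)
    lo, hi = _scan_interval(casc, lo, hi)
    us = [lo + (hi - lo) * i / (grid_n - 1) for i in range(grid_n)]
    hs = []
    for u in us:
        try:
            hs.append(casc.balance(u))
        except RootOutOfBoundsError:
            hs.append(math.nan)
    for a, b in zip(hs, hs[1:]):  # h nondecreasing on the scan grid
        if not (math.isnan(a) or math.isnan(b)):
            assert b >= a - 1e-8 * (1 + abs(a)), \
                "characteristic map is not nondecreasing"
    gs = [h - u if not math.isnan(h) else math.nan for u, h in zip(us, hs)]
    found: list[FixedPoint] = []

    def add(value: float, crossing: str):
        for fp in found:
            if abs(fp.value - value) <= max(10 * tol, 1e-9 * (1 + abs(value))):
                return
        found.append(FixedPoint(value=value, crossing=crossing))

    scale = 1 + abs(lo) + abs(hi)
    if not math.isnan(gs[0]) and abs(gs[0]) <= 1e-9 * scale:
        add(us[0], "endpoint")
    if not math.isnan(gs[-1]) and abs(gs[-1]) <= 1e-9 * scale:
        add(us[-1], "endpoint")
    for i in range(grid_n - 1):
        a, b = gs[i], gs[i + 1]
        if math.isnan(a) or math.isnan(b):
            continue
        if abs(a) <= tol:
            add(us[i], "tangent" if 0 < i else "endpoint")
            continue
        if a * b < 0:
            x0, x1, f0 = us[i], us[i + 1], a
            while x1 - x0 > tol:
                mid = 0.5 * (x0 + x1)
                try:
                    fm = casc.balance(mid) - mid
                except RootOutOfBoundsError:
                    break
                if fm == 0.0:
                    x0 = x1 = mid
                elif (fm > 0) == (f0 > 0):
                    x0 = mid
                else:
                    x1 = mid
            add(0.5 * (x0 + x1), "down" if a > 0 else "up")
    if not math.isnan(gs[-1]) and abs(gs[-1]) <= tol:
        add(us[-1], "endpoint")
    return sorted(found, key=lambda fp: fp.value)


def thresholds_from_fixed_point(wc: WorstCaseSystem, input_var: str, u_star) -> dict:
    """Full steady state of the worst-case subsystem at input ``u_star`` — one
    threshold per candidate variable."""
    vals = _cascade(wc, input_var).steady_state(float(u_star))
    return dict(sorted(vals.items()))


# --------------------------------------------------------------------------- #
# certification
# --------------------------------------------------------------------------- #

@dataclass
class StableModule:
    """A set of certified threshold statements with provenance."""

    statements: tuple  # of (variable, ">" or "<", threshold)
    provenance: dict = field(default_factory=dict)
    certified: bool = False
    residuals: dict = field(default_factory=dict)
    faces: dict = field(default_factory=dict)  # variable -> inward bound (or note)

    @property
    def statement_set(self) -> frozenset:
        return frozenset(
            (v, d, round(float(t), 9)) for v, d, t in self.statements)

    def region(self, model: ModelSystem) -> Box:
        box = Box()
        for v, d, t in self.statements:
            lo, hi = model.validity[v]
            box[v] = (sp.Float(t), hi) if d == ">" else (lo, sp.Float(t))
        return box


def certify_module(model: ModelSystem, candidate: CandidateModule,
                   thresholds: dict, tol: float = 1e-9) -> StableModule:
    """Certify a candidate at given thresholds.

    (a) the worst-case RHS residual at the threshold point is <= tol for every
        candidate variable, and
    (b) for every variable, the monotone bound of the *true* RHS on the module
        face (that variable at its threshold, other module variables on their
        module side, externals free over validity) points inward.

    Uncertified modules carry the failed face in ``faces``.
    """
    directions = candidate.directions
    wc = worst_case_system(model, candidate)
    point = {sp.Symbol(v, real=True): sp.Float(thresholds[v])
             for v in candidate.variables}
    residuals = {}
    for v in sorted(candidate.variables):
        residuals[v] = float(sp.N(wc.rhs[v].xreplace(point)))
    faces: dict = {}
    ok = all(abs(r) <= max(tol, 1e-9) for r in residuals.values())
    for v in sorted(candidate.variables):
        t_v = sp.nsimplify(thresholds[v], rational=True, tolerance=1e-12)
        lo_v, hi_v = model.validity[v]
        if not (lo_v <= t_v <= hi_v):
            raise RootOutOfBoundsError(v, f"threshold for {v} outside validity")
        region = Box({v: (t_v, t_v)})
        for j in candidate.variables:
            if j == v:
                continue
            t_j = sp.nsimplify(thresholds[j], rational=True, tolerance=1e-12)
            lo_j, hi_j = model.validity[j]
            region[j] = (t_j, hi_j) if directions[j] == HIGH else (lo_j, t_j)
        side = "lower" if directions[v] == HIGH else "upper"
        try:
            bound = float(sp.N(monotone_bound(model, v, region, side)))
        except (UnboundedError, IndefiniteSignError) as exc:
            faces[v] = f"uncertifiable: {exc}"
            ok = False
            continue
        faces[v] = bound
        inward = bound >= -tol if directions[v] == HIGH else bound <= tol
        if not inward:
            ok = False
    statements = tuple(sorted(
        (v, ">" if directions[v] == HIGH else "<", float(thresholds[v]))
        for v in candidate.variables))
    return StableModule(
        statements=statements,
        provenance={
            "polarity": candidate.polarity,
            "directions": dict(sorted(directions.items())),
            "substitutions": {f"{t}<-{s}": _fmt_endpoint(e)
                              for (t, s), e in wc.substitutions.items()},
        },
        certified=ok, residuals=residuals, faces=faces)


def _fmt_endpoint(e) -> str:
    if e == sp.oo:
        return "inf"
    if e == -sp.oo:
        return "-inf"
    return str(e)


# --------------------------------------------------------------------------- #
# end-to-end scan
# --------------------------------------------------------------------------- #

def scan_stable_modules(model: ModelSystem, max_len: int | None = None,
                        max_union: int = 3, grid_n: int = 256,
                        tol: float = 1e-9) -> list:
    """Full automation: positive loops -> unions -> candidates -> worst-case
    MIOS thresholds -> certification.  Returns certified StableModules,
    deduplicated by statement set; provenance records the fixed point and the
    MIOS input variable."""
    graph = regulatory_graph(model)
    cycles = positive_cycles(graph, max_len)
    out = []
    seen = set()
    for union in cycle_unions(graph, cycles, max_union):
        for cand in conjecture_candidates(union):
            try:
                wc = worst_case_system(model, cand)
            except (UnboundedError, IndefiniteSignError):
                continue
            input_var = select_mios_input(wc)
            if input_var is None:
                continue
            try:
                fps = find_fixed_points(wc, input_var, grid_n=grid_n)
            except RootOutOfBoundsError:
                continue
            for fp in fps:
                try:
                    thresholds = thresholds_from_fixed_point(wc, input_var, fp.value)
                    module = certify_module(model, cand, thresholds, tol=tol)
                except RootOutOfBoundsError:
                    continue
                if not module.certified:
                    continue
                module.provenance.update({
                    "fixed_point": fp.value,
                    "crossing": fp.crossing,
                    "mios_input": input_var,
                    "cycles": [list(c) for c in union.generating_cycles],
                })
                if module.statement_set in seen:
                    continue
                seen.add(module.statement_set)
                out.append(module)
    return out


# --------------------------------------------------------------------------- #
# reporting
# --------------------------------------------------------------------------- #

def _pretty_number(x: float) -> str:
    r = sp.nsimplify(x, rational=True, tolerance=1e-9)
    if r.is_Rational and abs(float(r) - x) <= 1e-9 and r.q <= 1000:
        return f"{x:.10g} ({r})" if r.q > 1 else f"{x:.10g}"
    return f"{x:.10g}"


def module_report(module: StableModule) -> dict:
    """JSON-serializable report of a stable module."""
    return {
        "statements": [
            {"variable": v, "direction": d, "threshold": float(t),
             "pretty": _pretty_number(float(t))}
            for v, d, t in module.statements],
        "certified": bool(module.certified),
        "residuals": {k: float(v) for k, v in module.residuals.items()},
        "faces": {k: (v if isinstance(v, str) else float(v))
                  for k, v in module.faces.items()},
        "provenance": module.provenance,
    }


def modules_to_json(modules: list, **kw) -> str:
    return json.dumps([module_report(m) for m in modules], indent=2, **kw)
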
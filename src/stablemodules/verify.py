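"""Numerical falsification harness for stable-module claims.

Certified modules assert positive invariance under *arbitrary* valid control
of every variable outside the module.  This module attacks that claim
numerically: it integrates the ODEs while adversarial control schedules clamp
or sweep the external variables across the region of validity and the
uncertain terms are realized as random bounded signals, then checks whether
any module statement's margin ever goes negative.  It also verifies driver
claims: clamping a driver set must activate the module in finite time.

Infinite validity endpoints are replaced by a finite adversary cap when
sampling controls and initial conditions (invariance is certified for the
whole box, so attacking a finite sub-box is sound; it just cannot explore
beyond the cap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .model import ModelSystem, _TERM_PREFIX

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_CAP = 10.0  # half-width used to truncate infinite validity endpoints


def finite_interval(lo, hi, cap: float = DEFAULT_CAP) -> tuple:
    lo = -math.inf if lo == -sp.oo else float(lo)
    hi = math.inf if hi == sp.oo else float(hi)
    if math.isinf(lo) and math.isinf(hi):
        return (-cap, cap)
    if math.isinf(hi):
        return (lo, lo + cap)
    if math.isinf(lo):
        return (hi - cap, hi)
    return (lo, hi)


# --------------------------------------------------------------------------- #
# control schedules and term realizations
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ControlSchedule:
    """External control of one variable.

    modes: ``none`` (natural dynamics), ``clamp-constant`` (level), ``clamp-
    piecewise`` (times/levels, left-closed segments), ``clamp-sinusoid``
    (offset, amplitude, period, phase).  Clamped values must stay inside the
    variable's validity interval.
    """

    variable: str
    mode: str = "none"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in (
                "none", "clamp-constant", "clamp-piecewise", "clamp-sinusoid"):
            raise ValueError(f"unknown control mode {self.mode!r}")

    @property
    def clamps(self) -> bool:
        return self.mode != "none"

    def value(self, t: float) -> float:
        p = self.parameters
        if self.mode == "clamp-constant":
            return float(p["level"])
        if self.mode == "clamp-piecewise":
            times, levels = p["times"], p["levels"]
            i = int(np.searchsorted(times, t, side="right")) - 1
            return float(levels[max(0, min(i, len(levels) - 1))])
        if self.mode == "clamp-sinusoid":
            period = float(p.get("period", 1.0))
            return float(p.get("offset", 0.0)) + float(p.get("amplitude", 0.0)) \
                * math.sin(2 * math.pi * t / period + float(p.get("phase", 0.0)))
        raise ValueError("schedule does not clamp")

    def switch_times(self, t_end: float) -> list:
        if self.mode == "clamp-piecewise":
            return [t for t in self.parameters["times"] if 0 < t < t_end]
        return []

    def validate(self, model: ModelSystem, t_end: float):
        lo, hi = model.validity[self.variable]
        lo = -math.inf if lo == -sp.oo else float(lo)
        hi = math.inf if hi == sp.oo else float(hi)
        probes = np.linspace(0, t_end, 101) if self.clamps else []
        for t in probes:
            v = self.value(float(t))
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(
                    f"control of {self.variable} leaves validity at t={t}")


class _PiecewiseSignal:
    """Seeded piecewise-constant signal on [0, t_end] (for uncertain terms
    and random adversarial clamps)."""

    def __init__(self, rng, lo: float, hi: float, t_end: float, n_switch: int = 10):
        self.times = np.sort(rng.uniform(0.0, t_end, size=n_switch))
        self.levels = rng.uniform(lo, hi, size=n_switch + 1)

    def __call__(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, side="right"))
        return float(self.levels[i])

    def switch_times(self, t_end: float) -> list:
        return [float(t) for t in self.times if 0 < t < t_end]


def realize_terms(model: ModelSystem, policy, t_end: float, rng,
                  cap: float = DEFAULT_CAP) -> dict:
    """Realize every uncertain term as a function of time.

    ``policy``: "lower" / "upper" (constant at the range endpoint, finite-
    capped), "random" (seeded piecewise-constant with 10 switches within the
    capped range), or a mapping term name -> value or callable.
    """
    out = {}
    for name, term in model.uncertain_terms.items():
        lo, hi = finite_interval(term.lo, term.hi, cap)
        if isinstance(policy, dict) and name in policy:
            p = policy[name]
            out[name] = p if callable(p) else (lambda t, p=float(p): p)
        elif policy == "lower":
            out[name] = lambda t, v=lo: v
        elif policy == "upper":
            out[name] = lambda t, v=hi: v
        elif policy == "random":
            out[name] = _PiecewiseSignal(rng, lo, hi, t_end)
        else:
            raise ValueError(f"unknown realization policy {policy!r}")
    return out


# --------------------------------------------------------------------------- #
# simulation
# --------------------------------------------------------------------------- #

@dataclass
class Trajectory:
    times: np.ndarray
    states: dict  # variable -> np.ndarray (clamped variables included)
    controls: tuple = ()
    escaped_validity: bool = False

    def value(self, variable: str) -> np.ndarray:
        return self.states[variable]

    def margins(self, statements) -> np.ndarray:
        """Minimum statement margin at each time: min over statements of
        +(x - T) for '>' and +(T - x) for '<'."""
        ms = []
        for v, d, t in statements:
            x = self.states[v]
            ms.append(x - float(t) if d == ">" else float(t) - x)
        return np.min(np.vstack(ms), axis=0)

    def to_csv(self) -> str:
        names = sorted(self.states)
        lines = ["time," + ",".join(names)]
        for i, t in enumerate(self.times):
            lines.append(
                f"{t:.10g}," + ",".join(f"{self.states[n][i]:.10g}" for n in names))
        return "\n".join(lines) + "\n"


def _compile_rhs(model: ModelSystem, free: list, clamped: list, terms: list):
    syms = ([sp.Symbol(v, real=True) for v in free]
            + [sp.Symbol(v, real=True) for v in clamped]
            + [sp.Symbol(_TERM_PREFIX + t, real=True) for t in terms])
    return [sp.lambdify(syms, model.rhs_flat(v), modules=["math"]) for v in free]


def simulate_controlled(model: ModelSystem, x0: dict, schedules=(),
                        t_end: float = 50.0, seed: int | None = None,
                        uncertain_realization="lower", n_points: int = 201,
                        rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                        cap: float = DEFAULT_CAP) -> Trajectory:
    """Integrate the model with clamped variables overridden by their control
    schedules and uncertain terms realized per policy.

    Piecewise-constant discontinuities are handled by segment-wise adaptive
    integration (LSODA, stiff-capable).  Validity escape is reported on the
    trajectory, never silently clipped.
    """
    rng = np.random.default_rng(seed)
    schedules = tuple(s for s in schedules if s.clamps)
    for s in schedules:
        s.validate(model, t_end)
    clamped = [s.variable for s in schedules]
    if len(set(clamped)) != len(clamped):
        raise ValueError("multiple schedules clamp one variable")
    sched_of = {s.variable: s for s in schedules}
    free = [v for v in model.variables if v not in sched_of]
    terms = sorted(model.uncertain_terms)
    realizations = realize_terms(model, uncertain_realization, t_end, rng, cap)
    fns = _compile_rhs(model, free, clamped, terms)

    def rhs(t, y):
        extra = [sched_of[v].value(t) for v in clamped] + \
                [realizations[n](t) for n in terms]
        return [f(*y, *extra) for f in fns]

    for v in model.variables:
        if v not in x0:
            raise ValueError(f"initial condition missing for {v}")
    breaks = {0.0, float(t_end)}
    for s in schedules:
        breaks.update(s.switch_times(t_end))
    for n in terms:
        r = realizations[n]
        if hasattr(r, "switch_times"):
            breaks.update(r.switch_times(t_end))
    breaks = sorted(breaks)
    t_eval = np.unique(np.clip(np.linspace(0.0, float(t_end), n_points), 0, t_end))
    times_all, ys_all = [0.0], [np.array([float(x0[v]) for v in free])]
    if t_end > 0:
        y = ys_all[0]
        for a, b in zip(breaks[:-1], breaks[1:]):
            seg_eval = t_eval[(t_eval > a) & (t_eval <= b)]
            seg_eval = np.unique(np.concatenate([seg_eval, [b]]))
            sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol,
                            atol=atol, t_eval=seg_eval, dense_output=False)
            if not sol.success:
                raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
            times_all.extend(sol.t.tolist())
            ys_all.extend(list(sol.y.T))
            y = sol.y[:, -1]
    times = np.array(times_all)
    ys = np.vstack(ys_all)
    states = {v: ys[:, i] for i, v in enumerate(free)}
    for v in clamped:
        states[v] = np.array([sched_of[v].value(t) for t in times])
    escaped = False
    for v in model.variables:
        lo, hi = model.validity[v]
        lo = -math.inf if lo == -sp.oo else float(lo)
        hi = math.inf if hi == sp.oo else float(hi)
        if np.any(states[v] < lo - 1e-6) or np.any(states[v] > hi + 1e-6):
            escaped = True
    return Trajectory(times=times, states=states, controls=schedules,
                      escaped_validity=escaped)


# --------------------------------------------------------------------------- #
# invariance and driver checks
# --------------------------------------------------------------------------- #

@dataclass
class VerificationReport:
    passed: bool
    n_trials: int
    worst_margin: float
    worst_trial: dict = field(default_factory=dict)
    violations: list = field(default_factory=list)
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "passed": bool(self.passed), "n_trials": int(self.n_trials),
            "worst_margin": float(self.worst_margin),
            "worst_trial": self.worst_trial,
            "n_violations": len(self.violations), "note": self.note,
        }


def _statements_of(module):
    if hasattr(module, "statements"):
        sts = module.statements
    else:
        sts = module
    return [(v, d, float(t)) for v, d, t in sts]


def _adversary_schedule(variable: str, lo: float, hi: float, t_end: float, rng
                        ) -> ControlSchedule:
    """One of four adversarial controls spanning the (capped) validity
    interval: lower clamp, upper clamp, random piecewise with 10 switches,
    or a sinusoid sweeping the interval."""
    kind = rng.integers(0, 4)
    if kind == 0:
        return ControlSchedule(variable, "clamp-constant", {"level": lo})
    if kind == 1:
        return ControlSchedule(variable, "clamp-constant", {"level": hi})
    if kind == 2:
        sig = _PiecewiseSignal(rng, lo, hi, t_end)
        return ControlSchedule(variable, "clamp-piecewise", {
            "times": [0.0] + sig.switch_times(t_end),
            "levels": sig.levels[:len(sig.switch_times(t_end)) + 1].tolist()})
    mid, amp = 0.5 * (lo + hi), 0.5 * (hi - lo)
    return ControlSchedule(variable, "clamp-sinusoid", {
        "offset": mid, "amplitude": amp,
        "period": float(rng.uniform(0.5, 0.25 * t_end + 0.5)),
        "phase": float(rng.uniform(0, 2 * math.pi))})


def check_invariance(model: ModelSystem, module, n_trials: int = 100,
                     t_end: float = 20.0, margin: float = 1e-6,
                     seed: int = 0, cap: float = DEFAULT_CAP,
                     rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                     ) -> VerificationReport:
    """Adversarial confirmation of positive invariance.

    Each trial samples an initial state uniformly in the module region shrunk
    by ``margin`` (a fraction of each variable's capped width — the boundary
    itself may be an equilibrium face, so exact-boundary starts are
    numerically fragile), an adversarial control schedule for every non-module
    variable, and a random realization of every uncertain term.  Pass iff no
    trial's minimum statement margin goes negative.
    """
    statements = _statements_of(module)
    if n_trials == 0:
        return VerificationReport(True, 0, math.inf,
                                  note="no evidence: zero trials requested")
    module_vars = {v for v, _, _ in statements}
    rng = np.random.default_rng(seed)
    worst = math.inf
    worst_trial: dict = {}
    violations = []
    for trial in range(n_trials):
        x0 = {}
        for v in model.variables:
            lo, hi = finite_interval(*model.validity[v], cap)
            if v in module_vars:
                m = margin * (hi - lo)
                s_lo, s_hi = lo, hi
                for (sv, d, t) in statements:
                    if sv != v:
                        continue
                    if d == ">":
                        s_lo = max(s_lo, t + m)
                    else:
                        s_hi = min(s_hi, t - m)
                if s_lo > s_hi:
                    s_lo = s_hi = 0.5 * (s_lo + s_hi)
                x0[v] = float(rng.uniform(s_lo, s_hi))
            else:
                x0[v] = float(rng.uniform(lo, hi))
        schedules = []
        for v in model.variables:
            if v in module_vars:
                continue
            lo, hi = finite_interval(*model.validity[v], cap)
            schedules.append(_adversary_schedule(v, lo, hi, t_end, rng))
        traj = simulate_controlled(
            model, x0, schedules, t_end,
            seed=int(rng.integers(0, 2**31)), uncertain_realization="random",
            rtol=rtol, atol=atol, cap=cap)
        mm = float(np.min(traj.margins(statements)))
        if mm < worst:
            worst = mm
            worst_trial = {"trial": trial, "x0": x0,
                           "controls": [s.mode for s in schedules]}
        if mm < 0:
            violations.append({"trial": trial, "margin": mm, "x0": x0})
    return VerificationReport(
        passed=not violations, n_trials=n_trials, worst_margin=worst,
        worst_trial=worst_trial, violations=violations)


def check_driver(model: ModelSystem, module, driver, n_trials: int = 20,
                 t_end: float = 50.0, seed: int = 0, cap: float = DEFAULT_CAP,
                 clamp_values: dict | None = None,
                 rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                 ) -> VerificationReport:
    """Confirm a driver claim: clamping the driver variables at statement-
    satisfying values activates every module statement by ``t_end`` and
    retains it afterward, from arbitrary valid initial conditions.

    Driver entries are (variable, direction, threshold) triples or virtual
    nodes with those attributes; clamp values default to the midpoint of the
    capped satisfying interval and may be overridden via ``clamp_values``.
    """
    statements = _statements_of(module)
    driver_stmts = []
    for d in driver:
        if hasattr(d, "variable"):
            driver_stmts.append((d.variable, d.direction, float(d.threshold)))
        else:
            v, dd, t = d
            driver_stmts.append((v, dd, float(t)))
    rng = np.random.default_rng(seed)
    schedules = []
    for v, d, t in driver_stmts:
        lo, hi = finite_interval(*model.validity[v], cap)
        default = 0.5 * (t + hi) if d == ">" else 0.5 * (lo + t)
        level = (clamp_values or {}).get(v, default)
        schedules.append(ControlSchedule(v, "clamp-constant", {"level": level}))
    clamped = {s.variable for s in schedules}
    worst = math.inf
    worst_trial: dict = {}
    violations = []
    for trial in range(n_trials):
        x0 = {}
        for v in model.variables:
            lo, hi = finite_interval(*model.validity[v], cap)
            x0[v] = float(rng.uniform(lo, hi))
        traj = simulate_controlled(
            model, x0, schedules, t_end,
            seed=int(rng.integers(0, 2**31)), uncertain_realization="random",
            rtol=rtol, atol=atol, cap=cap)
        margins = traj.margins(statements)
        active = np.nonzero(margins > 0)[0]
        if len(active) == 0 or margins[-1] <= 0:
            violations.append({"trial": trial, "x0": x0,
                               "final_margin": float(margins[-1])})
            continue
        t_on = active[0]
        tail = float(np.min(margins[t_on:]))
        if tail < worst:
            worst = tail
            worst_trial = {"trial": trial, "x0": x0}
        if tail < 0:
            violations.append({"trial": trial, "x0": x0, "tail_margin": tail})
    del clamped
    return VerificationReport(
        passed=not violations, n_trials=n_trials, worst_margin=worst,
        worst_trial=worst_trial, violations=violations)
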
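"""Boolean rule models, Hill-ODE conversion, and in-class fixture generators.

Boolean regulatory models are a common starting point for continuous models:
each rule's truth table is interpolated multilinearly over the unit cube and
each literal is then replaced by a Hill function ``H(x) = x^n/(x^n + k^n)``
(inhibitors arrive as ``1 - H`` automatically through the interpolation),
giving ``dx_i/dt = (R_i(x) - x_i)/tau_i`` with ``R_i`` in [0, 1].  The same
construction underlies published conversions of signaling models to ODEs.

Also provided: a brute-force synchronous attractor/partial-fixed-state oracle
for cross-validating the continuous analysis against Boolean self-sustaining
patterns, and a seeded random generator of in-class Hill models for property
tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product

import sympy as sp

from .model import ModelSpecError, ModelSystem

_RULE_RE = re.compile(r"^\s*(\w+)\s*,\s*(.+?)\s*$")


@dataclass
class BooleanModel:
    """Synchronous Boolean network: one update rule per variable.

    Variables appearing only on rule right-hand sides are *inputs*; they
    default to copying themselves (constant under synchronous update unless a
    fixed value is assigned via ``fixed``).
    """

    variables: tuple
    rules: dict  # name -> sympy boolean expression over variable symbols
    inputs: tuple = ()
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        declared = set(self.variables)
        for v, expr in self.rules.items():
            for s in sp.sympify(expr).free_symbols:
                if str(s) not in declared:
                    raise ModelSpecError(
                        f"rule for {v} uses undeclared symbol {s}")
        for v in self.fixed:
            if v not in declared:
                raise ModelSpecError(f"fixed value for undeclared {v}")

    def effective_rules(self) -> dict:
        """Rules with fixed input values substituted."""
        subs = {sp.Symbol(v): sp.S(bool(val)) for v, val in self.fixed.items()}
        out = {}
        for v in self.variables:
            if v in self.fixed:
                out[v] = sp.S(bool(self.fixed[v]))
            else:
                out[v] = sp.simplify_logic(self.rules[v].xreplace(subs))
        return out

    def step(self, state: dict) -> dict:
        subs = {sp.Symbol(v): sp.S(bool(state[v])) for v in self.variables}
        rules = self.effective_rules()
        return {v: int(bool(rules[v].xreplace(subs))) for v in self.variables}


def parse_boolean_rules(text: str) -> BooleanModel:
    """Parse BoolNet-style rules: one ``target, expression`` line per
    variable, with ``!`` (NOT), ``&``, ``|``, parentheses and constants 0/1.
    A ``targets, factors`` header and ``#`` comments are ignored.  Symbols
    appearing only in expressions become inputs with rule = themselves."""
    rules: dict = {}
    order: list = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") in ("targets,factors", "targets,rules"):
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ModelSpecError(f"line {ln}: cannot parse rule {raw!r}")
        name, expr_text = m.group(1), m.group(2)
        if name in rules:
            raise ModelSpecError(f"line {ln}: duplicate target {name}")
        expr_text = expr_text.replace("!", "~")
        try:
            expr = sp.parsing.sympy_parser.parse_expr(
                expr_text, evaluate=False,
                local_dict={"0": sp.false, "1": sp.true})
            expr = sp.sympify(expr)
            if expr in (sp.S.Zero, sp.S.One) or expr.is_Integer:
                expr = sp.S(bool(int(expr)))
        except Exception as exc:
            raise ModelSpecError(
                f"line {ln}: bad boolean expression {expr_text!r}: {exc}") from exc
        rules[name] = expr
        order.append(name)
    if not rules:
        raise ModelSpecError("empty boolean model")
    implicit = sorted(
        {str(s) for e in rules.values() for s in sp.sympify(e).free_symbols}
        - set(order))
    for v in implicit:
        rules[v] = sp.Symbol(v)
    variables = tuple(order + implicit)
    return BooleanModel(variables=variables, rules=rules,
                        inputs=tuple(implicit))


# --------------------------------------------------------------------------- #
# Hill conversion
# --------------------------------------------------------------------------- #

@dataclass
class HillParams:
    """Per-edge Hill coefficients/dissociation constants and per-variable
    timescales; scalar values broadcast to every edge/variable.

    ``n`` positive integer, ``k`` in (0, 1), ``tau`` > 0.
    """

    n: object = 2
    k: object = sp.Rational(1, 2)
    tau: object = 1

    def edge_n(self, src: str, tgt: str) -> int:
        v = self.n.get((src, tgt)) if isinstance(self.n, dict) else self.n
        if v is None or int(v) < 1:
            raise ModelSpecError(f"missing/invalid Hill n for edge {src}->{tgt}")
        return int(v)

    def edge_k(self, src: str, tgt: str):
        v = self.k.get((src, tgt)) if isinstance(self.k, dict) else self.k
        if v is None or not (0 < sp.sympify(v) < 1):
            raise ModelSpecError(f"missing/invalid Hill k for edge {src}->{tgt}")
        return sp.sympify(v)

    def var_tau(self, v: str):
        t = self.tau.get(v) if isinstance(self.tau, dict) else self.tau
        if t is None or not (sp.sympify(t) > 0):
            raise ModelSpecError(f"missing/invalid tau for {v}")
        return sp.sympify(t)


def _hill_expr(x: sp.Symbol, k, n):
    return x**n / (x**n + k**n)


def _multilinear(rule, args: list) -> sp.Expr:
    """Multilinear interpolation of a Boolean function over placeholder
    symbols (one per essential argument)."""
    placeholders = {a: sp.Symbol(f"_b_{a}", real=True) for a in args}
    total = sp.S.Zero
    for bits in product((0, 1), repeat=len(args)):
        val = rule.xreplace(
            {sp.Symbol(a): sp.S(bool(b)) for a, b in zip(args, bits)})
        if bool(val):
            term = sp.S.One
            for a, b in zip(args, bits):
                s = placeholders[a]
                term *= s if b else (1 - s)
            total += term
    return total, placeholders


def boolean_edge_sign(rule, arg: str) -> int | None:
    """Monotone sign of a Boolean rule in one argument (+1 nondecreasing,
    -1 nonincreasing, 0 independent, None non-monotone), by truth table."""
    args = sorted(str(s) for s in rule.free_symbols)
    if arg not in args:
        return 0
    others = [a for a in args if a != arg]
    up = down = False
    for bits in product((0, 1), repeat=len(others)):
        env0 = {sp.Symbol(a): sp.S(bool(b)) for a, b in zip(others, bits)}
        lo = bool(rule.xreplace({**env0, sp.Symbol(arg): sp.false}))
        hi = bool(rule.xreplace({**env0, sp.Symbol(arg): sp.true}))
        if hi and not lo:
            up = True
        if lo and not hi:
            down = True
    if up and down:
        return None
    if up:
        return 1
    if down:
        return -1
    return 0


def hill_ode(bm: BooleanModel, params: HillParams | None = None,
             normalized: bool = False) -> ModelSystem:
    """Convert a Boolean model to a Hill ODE system on [0, 1]^n.

    Each rule's truth table is interpolated multilinearly and every literal
    ``x_j`` is replaced by ``H(x_j, k, n)`` (the non-normalized HillCube
    construction; with ``normalized=True`` each ``H`` is divided by ``H(1)``
    so that ``R_i`` spans exactly [0, 1]).  The result is
    ``dx_i/dt = (R_i - x_i)/tau_i``.  Boolean-monotone regulator signs are
    recorded as declared signs on the ModelSystem.
    """
    params = params or HillParams()
    rules = bm.effective_rules()
    rhs: dict = {}
    declared: dict = {}
    for v in bm.variables:
        rule = rules[v]
        args = sorted(str(s) for s in rule.free_symbols)
        if not args:
            R = sp.S.One if bool(rule) else sp.S.Zero
        else:
            poly, placeholders = _multilinear(rule, args)
            subs = {}
            for a in args:
                n = params.edge_n(a, v)
                k = params.edge_k(a, v)
                h = _hill_expr(sp.Symbol(a, real=True), k, n)
                if normalized:
                    h = h / _hill_expr(sp.S.One, k, n)
                subs[placeholders[a]] = h
            R = poly.xreplace(subs)
            for a in args:
                sg = boolean_edge_sign(rule, a)
                if sg in (1, -1):
                    declared[(a, v)] = sg
        rhs[v] = (R - sp.Symbol(v, real=True)) / params.var_tau(v)
    return ModelSystem(
        variables=tuple(bm.variables), rhs=rhs,
        validity={v: (sp.S.Zero, sp.S.One) for v in bm.variables},
        declared_signs=declared)


# --------------------------------------------------------------------------- #
# brute-force Boolean oracles
# --------------------------------------------------------------------------- #

_MAX_BRUTE = 14


def brute_force_boolean_attractors(bm: BooleanModel) -> list:
    """Exhaustive synchronous attractors (fixed points and cycles) as
    canonically rotated tuples of state tuples (variable order as declared)."""
    n = len(bm.variables)
    if n > _MAX_BRUTE:
        raise ValueError(f"brute force limited to {_MAX_BRUTE} variables")
    rules = bm.effective_rules()
    syms = [sp.Symbol(v) for v in bm.variables]

    def succ(state: tuple) -> tuple:
        env = {s: sp.S(bool(b)) for s, b in zip(syms, state)}
        return tuple(int(bool(rules[v].xreplace(env))) for v in bm.variables)

    succ_map = {}
    attractors = set()
    for bits in product((0, 1), repeat=n):
        path = []
        seen_at = {}
        s = bits
        while s not in seen_at:
            if s in succ_map and succ_map[s] is None:
                break  # already resolved through this state
            seen_at[s] = len(path)
            path.append(s)
            s = succ(s)
        else:
            cycle = tuple(path[seen_at[s]:])
            i = cycle.index(min(cycle))
            attractors.add(cycle[i:] + cycle[:i])
        for p in path:
            succ_map[p] = None
    return sorted(attractors)


def boolean_stable_motifs(bm: BooleanModel, max_vars: int = 10) -> list:
    """Minimal self-sustaining partial fixed states (Boolean trap partial
    states): partial assignments P such that, under every completion of the
    unassigned variables, the synchronous update reproduces P; minimal by
    item-set inclusion.  Brute force over all partial assignments."""
    n = len(bm.variables)
    if n > max_vars:
        raise ValueError(f"partial-state brute force limited to {max_vars} variables")
    rules = bm.effective_rules()
    closed = []
    for assignment in product((None, 0, 1), repeat=n):
        items = {v: a for v, a in zip(bm.variables, assignment) if a is not None}
        if not items:
            continue
        free = [v for v in bm.variables if v not in items]
        ok = True
        for v, want in items.items():
            rule = rules[v]
            support_free = [f for f in free
                            if sp.Symbol(f) in rule.free_symbols]
            base = {sp.Symbol(a): sp.S(bool(b)) for a, b in items.items()}
            for bits in product((0, 1), repeat=len(support_free)):
                env = dict(base)
                env.update({sp.Symbol(f): sp.S(bool(b))
                            for f, b in zip(support_free, bits)})
                if int(bool(rule.xreplace(env))) != want:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            closed.append(frozenset(items.items()))
    minimal = [c for c in closed if not any(o < c for o in closed)]
    return sorted(minimal, key=lambda c: (len(c), sorted(c)))


def motif_matches_module(motif, modules) -> bool:
    """Whether a Boolean partial fixed state has a certified continuous
    counterpart: a stable module over exactly the motif's variables whose
    directions are '>' for 1-valued and '<' for 0-valued entries."""
    motif = dict(motif)
    for m in modules:
        if not getattr(m, "certified", True):
            continue
        stmts = {v: d for v, d, _ in m.statements}
        if set(stmts) != set(motif):
            continue
        if all((stmts[v] == ">") == bool(val) for v, val in motif.items()):
            return True
    return False


# --------------------------------------------------------------------------- #
# random in-class models
# --------------------------------------------------------------------------- #

def random_inclass_model(n_vars: int, density: float = 0.3,
                         seed: int = 0) -> ModelSystem:
    """Seeded random Hill model guaranteed to be in the supported class.

    A random signed digraph without self-loops (each ordered pair is an edge
    with probability ``density``) is dressed with a random monotone Boolean
    rule per variable (literals folded with random AND/OR) and converted with
    :func:`hill_ode`; variables without regulators decay to zero.
    """
    import numpy as np

    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n_vars)]
    rules: dict = {}
    for tgt in names:
        regs = [s for s in names
                if s != tgt and rng.random() < density]
        if not regs:
            rules[tgt] = sp.false
            continue
        expr = None
        for s in regs:
            lit = sp.Symbol(s) if rng.random() < 0.5 else sp.Not(sp.Symbol(s))
            if expr is None:
                expr = lit
            elif rng.random() < 0.5:
                expr = sp.And(expr, lit)
            else:
                expr = sp.Or(expr, lit)
        rules[tgt] = expr
    bm = BooleanModel(variables=tuple(names), rules=rules)
    return hill_ode(bm, HillParams(n=2, k=sp.Rational(1, 2), tau=1))
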
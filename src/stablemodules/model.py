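"""ODE model representation, sign inference, and monotone interval bounds.

The supported model class consists of autonomous systems ``dx_i/dt = F_i(x)``
in which every ``F_i`` is continuous, monotonic in each of its arguments, and
strictly decreasing in ``x_i`` (implicit decay).  Models live inside a
rectangular *region of validity* — a per-variable interval that may extend to
``±inf`` — and may contain *uncertain terms*: named, bounded functions of the
state (e.g. ``f(y)`` with ``f_min <= f(y) < inf``) about which only the range
and, optionally, per-argument monotonicity are known.

Everything downstream (candidate enumeration, worst-case construction,
expanded-network edge certification) reduces to two primitives implemented
here: establishing the sign of an interaction over the validity box, and
bounding a right-hand side over a sub-box by substituting monotone extremes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import sympy as sp
from sympy.core.function import AppliedUndef


class ModelSpecError(ValueError):
    """Raised for malformed model-spec documents or out-of-class models."""


class IndefiniteSignError(ValueError):
    """An interaction sign could not be established over the validity box."""


class UnboundedError(ValueError):
    """A monotone bound diverged to the unfavorable infinity."""


# --------------------------------------------------------------------------- #
# numbers and intervals
# --------------------------------------------------------------------------- #

def _to_number(tok: str):
    tok = tok.strip()
    if tok in ("inf", "+inf", "oo"):
        return sp.oo
    if tok in ("-inf", "-oo"):
        return -sp.oo
    try:
        return sp.Rational(tok)
    except (TypeError, ValueError):
        try:
            return sp.nsimplify(sp.Float(tok), rational=True)
        except (TypeError, ValueError) as exc:  # pragma: no cover
            raise ModelSpecError(f"cannot parse number {tok!r}") from exc


def as_interval(pair) -> tuple:
    lo, hi = sp.sympify(pair[0]), sp.sympify(pair[1])
    if not (lo <= hi):
        raise ModelSpecError(f"empty interval [{lo}, {hi}]")
    return (lo, hi)


@dataclass(frozen=True)
class UncertainTerm:
    """A bounded function of the state with only range/monotonicity known."""

    name: str
    args: tuple[str, ...]
    lo: sp.Expr
    hi: sp.Expr
    monotonicity: Mapping[str, int | None] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.lo <= self.hi):
            raise ModelSpecError(
                f"term {self.name}: empty range [{self.lo}, {self.hi}]")


class Box(dict):
    """Per-variable closed intervals; a sub-box of the region of validity.

    Maps names (variables or uncertain terms) to ``(lo, hi)`` pairs; pairs may
    be degenerate (``lo == hi``) but never empty.
    """

    def __init__(self, mapping: Mapping | None = None, **kw):
        super().__init__()
        for k, v in {**(dict(mapping) if mapping else {}), **kw}.items():
            self[k] = v

    def __setitem__(self, key, value):
        if not isinstance(value, tuple):
            value = (value, value)  # point constraint
        super().__setitem__(key, as_interval(value))


# --------------------------------------------------------------------------- #
# the model container
# --------------------------------------------------------------------------- #

_TERM_PREFIX = "_range_"


@dataclass
class ModelSystem:
    """An ODE model of the supported monotone-with-decay class.

    Parameters
    ----------
    variables:
        Ordered variable names.
    rhs:
        name -> sympy expression for ``dx/dt`` over the variable symbols and
        uncertain-term applications (``sp.Function("f")(y)``).
    validity:
        name -> ``(lo, hi)`` with endpoints in ``R ∪ {±oo}``.
    uncertain_terms:
        name -> :class:`UncertainTerm`.
    declared_signs:
        optional user-declared ``(source, target) -> ±1`` used as a fallback
        when symbolic sign establishment is inconclusive.
    """

    variables: tuple[str, ...]
    rhs: dict[str, sp.Expr]
    validity: dict[str, tuple]
    uncertain_terms: dict[str, UncertainTerm] = field(default_factory=dict)
    declared_signs: dict[tuple[str, str], int] = field(default_factory=dict)
    _sign_cache: dict = field(default_factory=dict, repr=False)
    _rhs_flat: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.variables = tuple(self.variables)
        if not self.variables:
            raise ModelSpecError("empty model")
        for v in self.variables:
            if v not in self.rhs:
                raise ModelSpecError(f"variable {v} has no ODE")
            if v not in self.validity:
                raise ModelSpecError(f"variable {v} has no validity interval")
            lo, hi = as_interval(self.validity[v])
            if not (lo < hi):
                raise ModelSpecError(f"degenerate validity for {v}")
            self.validity[v] = (lo, hi)
        allowed = set(self.variables)
        for v, expr in self.rhs.items():
            expr = sp.sympify(expr)
            for g in expr.atoms(AppliedUndef):
                tname = g.func.__name__
                if tname not in self.uncertain_terms:
                    raise ModelSpecError(f"undeclared term {tname!r} in ode {v}")
                term = self.uncertain_terms[tname]
                got = tuple(str(a) for a in g.args)
                if got != term.args:
                    raise ModelSpecError(
                        f"term {tname} applied to {got}, declared {term.args}")
            undecl = {str(s) for s in expr.free_symbols} - allowed
            # symbols appearing only inside term applications are term args
            undecl -= {a for t in self.uncertain_terms.values() for a in t.args}
            if undecl:
                raise ModelSpecError(
                    f"undeclared symbol(s) {sorted(undecl)} in ode for {v}")
            self.rhs[v] = expr
        for t in self.uncertain_terms.values():
            for a in t.args:
                if a not in allowed:
                    raise ModelSpecError(f"term {t.name} argument {a} undeclared")

    # -- symbol plumbing ---------------------------------------------------- #
    def sym(self, name: str) -> sp.Symbol:
        return sp.Symbol(name, real=True)

    def term_sym(self, name: str) -> sp.Symbol:
        """The symbol standing for the *value* of an uncertain term."""
        return sp.Symbol(_TERM_PREFIX + name, real=True)

    def rhs_flat(self, target: str) -> sp.Expr:
        """RHS with each uncertain-term application replaced by its value symbol."""
        if target not in self._rhs_flat:
            expr = self.rhs[target]
            for g in expr.atoms(AppliedUndef):
                expr = expr.xreplace({g: self.term_sym(g.func.__name__)})
            self._rhs_flat[target] = expr
        return self._rhs_flat[target]

    def interval_of(self, name: str) -> tuple:
        if name in self.validity:
            return self.validity[name]
        t = self.uncertain_terms[name]
        return (t.lo, t.hi)

    def is_term(self, name: str) -> bool:
        return name in self.uncertain_terms


# --------------------------------------------------------------------------- #
# sign establishment over the validity box
# --------------------------------------------------------------------------- #

def _box_substitution(model: ModelSystem, names: Iterable[str]):
    """Map each plain symbol to an expression over fresh nonnegative symbols
    that sweeps exactly its validity (or term range) interval.

    [lo, oo)  -> lo + t          (-oo, hi] -> hi - t
    [lo, hi]  -> (lo + hi*t)/(1 + t)      (-oo, oo) -> plain real symbol
    """
    subs = {}
    for i, name in enumerate(sorted(names)):
        lo, hi = model.interval_of(name)
        src = model.term_sym(name) if model.is_term(name) else model.sym(name)
        t = sp.Symbol(f"_t{i}", nonnegative=True)
        if lo == -sp.oo and hi == sp.oo:
            subs[src] = sp.Symbol(f"_r{i}", real=True)
        elif hi == sp.oo:
            subs[src] = lo + t
        elif lo == -sp.oo:
            subs[src] = hi - t
        else:
            subs[src] = (lo + hi * t) / (1 + t)
    return subs


def _definite_sign(expr: sp.Expr) -> int | None:
    """Sign of ``expr`` assuming its symbols' assumptions; None if unknown.

    Returns +1 (nonnegative, not identically 0), -1 (nonpositive, not
    identically 0), 0 (identically zero), or None.
    """
    expr = sp.cancel(sp.together(expr))
    if expr == 0:
        return 0
    num, den = sp.fraction(expr)
    sn = _poly_like_sign(num)
    sd = _poly_like_sign(den)
    if sn is not None and sd is not None and sn != 0 and sd != 0:
        return sn * sd
    if sn == 0:
        return 0
    e = sp.expand(expr)
    if e.is_nonnegative:
        return 1
    if e.is_nonpositive:
        return -1
    e = sp.factor(e)
    if e.is_nonnegative:
        return 1
    if e.is_nonpositive:
        return -1
    return None


def _poly_like_sign(e: sp.Expr) -> int | None:
    e = sp.expand(e)
    if e == 0:
        return 0
    if e.is_nonnegative:
        return 1
    if e.is_nonpositive:
        return -1
    if e.is_Add:
        signs = {t.is_nonnegative for t in e.args}
        if signs == {True}:
            return 1
        if {t.is_nonpositive for t in e.args} == {True}:
            return -1
    return None


def _symbol_sign_on_box(model: ModelSystem, expr: sp.Expr, wrt: sp.Symbol) -> int | None:
    d = sp.diff(expr, wrt)
    if d == 0:
        return 0
    names = set()
    for s in d.free_symbols:
        n = str(s)
        if n.startswith(_TERM_PREFIX):
            names.add(n[len(_TERM_PREFIX):])
        elif n in model.validity:
            names.add(n)
    d = d.xreplace(_box_substitution(model, names))
    return _definite_sign(d)


def interaction_sign(model: ModelSystem, target: str, source: str):
    """Monotone sign of the influence of ``source`` on ``d(target)/dt``.

    Returns ``+1`` / ``-1`` when the partial derivative of ``F_target`` with
    respect to ``source`` is nonnegative / nonpositive (and not identically
    zero) everywhere on the validity box, ``0`` when ``F_target`` does not
    depend on ``source``, and the string ``"indefinite"`` when no sign can be
    established.  Influence through an uncertain term is chained through the
    term's declared per-argument monotonicity.
    """
    key = (target, source)
    if key in self_cache(model):
        return self_cache(model)[key]
    expr = model.rhs_flat(target)
    contributions: set = set()
    if model.is_term(source):
        s = _symbol_sign_on_box(model, expr, model.term_sym(source))
        result = "indefinite" if s is None else s
        self_cache(model)[key] = result
        return result
    # direct dependence
    s = _symbol_sign_on_box(model, expr, model.sym(source))
    if s is None:
        contributions.add(None)
    elif s != 0:
        contributions.add(s)
    # chained through uncertain terms
    for tname, term in model.uncertain_terms.items():
        if source not in term.args:
            continue
        outer = _symbol_sign_on_box(model, expr, model.term_sym(tname))
        if outer == 0:
            continue
        mono = term.monotonicity.get(source)
        if outer is None or mono is None:
            contributions.add(None)
        else:
            contributions.add(outer * mono)
    if not contributions:
        result = 0
    elif contributions == {1}:
        result = 1
    elif contributions == {-1}:
        result = -1
    else:
        result = model.declared_signs.get((source, target), "indefinite")
    self_cache(model)[key] = result
    return result


def self_cache(model: ModelSystem) -> dict:
    return model._sign_cache


# --------------------------------------------------------------------------- #
# regulatory graph and decay validation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SignedDigraph:
    """A signed regulatory network: at most one signed edge per ordered pair."""

    nodes: tuple[str, ...]
    edges: frozenset  # of (source, target, sign)

    def __post_init__(self):
        pairs = [(s, t) for s, t, _ in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ModelSpecError("parallel +/- edges for one ordered pair")

    def sign(self, source: str, target: str) -> int | None:
        for s, t, sg in self.edges:
            if s == source and t == target:
                return sg
        return None

    def to_networkx(self):
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sg in self.edges:
            g.add_edge(s, t, sign=sg)
        return g


def regulatory_graph(model: ModelSystem) -> SignedDigraph:
    """Signed digraph of direct influences (self-loops excluded: decay is
    implicit in the model class).  Raises on any indefinite sign."""
    edges = set()
    for tgt in model.variables:
        for src in model.variables:
            if src == tgt:
                continue
            s = interaction_sign(model, tgt, src)
            if s == "indefinite":
                raise IndefiniteSignError(
                    f"sign of {src} -> {tgt} could not be established")
            if s != 0:
                edges.add((src, tgt, s))
    return SignedDigraph(nodes=model.variables, edges=frozenset(edges))


@dataclass
class DecayReport:
    signs: dict[str, object]

    @property
    def passed(self) -> bool:
        return all(s == -1 for s in self.signs.values())

    @property
    def failures(self) -> list[str]:
        return [v for v, s in self.signs.items() if s != -1]


def validate_decay(model: ModelSystem) -> DecayReport:
    """Check that every RHS is decreasing in its own variable (model class
    requirement); a failing report blocks downstream automation."""
    return DecayReport(
        signs={v: interaction_sign(model, v, v) for v in model.variables})


# --------------------------------------------------------------------------- #
# monotone bounds over boxes
# --------------------------------------------------------------------------- #

def monotone_bound(model: ModelSystem, target: str, region, side: str):
    """Bound ``F_target`` over a box by substituting monotone extremes.

    Each argument of the RHS (variable or uncertain-term value) is replaced by
    the interval endpoint dictated by its interaction sign and the requested
    ``side`` ("lower" or "upper"); infinite endpoints are handled by symbolic
    limits.  The returned value is attained on the closure of the region or is
    a limit value.  Raises :class:`UnboundedError` when a needed limit
    diverges to the unfavorable infinity.
    """
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    region = Box(region or {})
    expr = model.rhs_flat(target)
    finite_subs = {}
    limits = []
    for s in sorted(expr.free_symbols, key=str):
        n = str(s)
        name = n[len(_TERM_PREFIX):] if n.startswith(_TERM_PREFIX) else n
        sg = interaction_sign(model, target, name)
        if sg == 0:
            continue
        if sg == "indefinite":
            raise IndefiniteSignError(
                f"sign of {name} -> {target} could not be established")
        lo, hi = region.get(name, model.interval_of(name))
        want_low = (side == "lower") == (sg == 1)
        endpoint = lo if want_low else hi
        if endpoint in (sp.oo, -sp.oo):
            limits.append((s, endpoint))
        else:
            finite_subs[s] = endpoint
    val = expr.xreplace(finite_subs)
    for s, endpoint in limits:
        try:
            val = sp.limit(val, s, endpoint)
        except Exception as exc:
            raise UnboundedError(
                f"limit of F_{target} as {s} -> {endpoint} failed: {exc}") from exc
    val = sp.simplify(val)
    if (side == "lower" and val == -sp.oo) or (side == "upper" and val == sp.oo):
        raise UnboundedError(
            f"{side} bound on F_{target} diverges; no finite certification")
    return val


# --------------------------------------------------------------------------- #
# model-spec parser
# --------------------------------------------------------------------------- #

_VAR_RE = re.compile(r"^var\s+(\w+)\s+in\s+\[([^,\]]+),([^,\]]+)\]\s*$")
_TERM_RE = re.compile(r"^term\s+(\w+)\(([^)]*)\)\s+in\s+\[([^,\]]+),([^,\]]+)\]\s*(.*)$")
_ODE_RE = re.compile(r"^ode\s+(\w+)\s*=\s*(.+)$")
_SIGN_RE = re.compile(r"^sign\s+(\w+)\s*->\s*(\w+)\s*([+-])\s*$")
_MONO_RE = re.compile(r"(increasing|decreasing|unknown)\s+in\s+(\w+)")


def _hill(x, k, n):
    return x**n / (x**n + k**n)


def parse_expression(text: str, local_dict: dict) -> sp.Expr:
    from sympy.parsing.sympy_parser import (
        parse_expr, standard_transformations, rationalize)
    text = text.replace("^", "**")
    try:
        return parse_expr(
            text,
            local_dict=local_dict,
            transformations=standard_transformations + (rationalize,),
            evaluate=True,
        )
    except Exception as exc:
        raise ModelSpecError(f"syntax error in expression {text!r}: {exc}") from exc


def parse_model(text: str) -> ModelSystem:
    """Parse a plain-text model-spec document into a :class:`ModelSystem`.

    Format, one statement per line (``#`` starts a comment)::

        var x in [0, inf]
        term f(y) in [0.1, inf] increasing in y
        ode x = (1 + 4*w + 4*w*z) / ((1 + 2*w)*(1 + 2*z)) - x
        sign y -> z +        # optional declared regulation sign

    Expressions may use ``+ - * / ^``, ``exp``, ``log``, ``min``, ``max`` and
    ``hill(x, k, n) = x^n/(x^n + k^n)``; interval endpoints accept ``inf``.
    """
    variables: list[str] = []
    validity: dict[str, tuple] = {}
    terms: dict[str, UncertainTerm] = {}
    odes: dict[str, str] = {}
    declared: dict[tuple[str, str], int] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if m := _VAR_RE.match(line):
            name, lo, hi = m.group(1), _to_number(m.group(2)), _to_number(m.group(3))
            if name in validity:
                raise ModelSpecError(f"line {ln}: duplicate var {name}")
            variables.append(name)
            validity[name] = (lo, hi)
        elif m := _TERM_RE.match(line):
            name = m.group(1)
            args = tuple(a.strip() for a in m.group(2).split(",") if a.strip())
            lo, hi = _to_number(m.group(3)), _to_number(m.group(4))
            mono: dict[str, int | None] = {}
            for word, arg in _MONO_RE.findall(m.group(5)):
                if arg not in args:
                    raise ModelSpecError(
                        f"line {ln}: monotonicity for non-argument {arg}")
                mono[arg] = {"increasing": 1, "decreasing": -1, "unknown": None}[word]
            terms[name] = UncertainTerm(name, args, lo, hi, mono)
        elif m := _ODE_RE.match(line):
            if m.group(1) in odes:
                raise ModelSpecError(f"line {ln}: duplicate ode for {m.group(1)}")
            odes[m.group(1)] = m.group(2)
        elif m := _SIGN_RE.match(line):
            declared[(m.group(1), m.group(2))] = 1 if m.group(3) == "+" else -1
        else:
            raise ModelSpecError(f"line {ln}: cannot parse {raw!r}")
    if not variables:
        raise ModelSpecError("empty model")
    local: dict = {v: sp.Symbol(v, real=True) for v in variables}
    local.update({t: sp.Function(t) for t in terms})
    local.update({"hill": _hill, "exp": sp.exp, "log": sp.log,
                  "min": sp.Min, "max": sp.Max, "Min": sp.Min, "Max": sp.Max})
    rhs = {v: parse_expression(e, local) for v, e in odes.items()}
    missing = [v for v in variables if v not in rhs]
    if missing:
        raise ModelSpecError(f"no ode for variable(s) {missing}")
    extra = [v for v in rhs if v not in validity]
    if extra:
        raise ModelSpecError(f"ode for undeclared symbol(s) {extra}")
    return ModelSystem(
        variables=tuple(variables), rhs=rhs, validity=validity,
        uncertain_terms=terms, declared_signs=declared)


def write_model(model: ModelSystem) -> str:
    """Serialize a ModelSystem back to the model-spec format."""
    lines = []
    for v in model.variables:
        lo, hi = model.validity[v]
        lines.append(f"var {v} in [{_fmt(lo)}, {_fmt(hi)}]")
    for t in model.uncertain_terms.values():
        parts = [f"term {t.name}({', '.join(t.args)}) in [{_fmt(t.lo)}, {_fmt(t.hi)}]"]
        for a, m in t.monotonicity.items():
            word = {1: "increasing", -1: "decreasing", None: "unknown"}[m]
            parts.append(f"{word} in {a}")
        lines.append(" ".join(parts))
    for v in model.variables:
        lines.append(f"ode {v} = {sp.sstr(model.rhs[v])}")
    for (s, t), sg in model.declared_signs.items():
        lines.append(f"sign {s} -> {t} {'+' if sg > 0 else '-'}")
    return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    if x == sp.oo:
        return "inf"
    if x == -sp.oo:
        return "-inf"
    return str(x)
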
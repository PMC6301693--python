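"""Shared fixtures: the worked toy model, small reference systems, and
independent test oracles (kept separate from the library implementations)."""

from itertools import chain, combinations

import pytest
import sympy as sp

from stablemodules.model import parse_model

# Five-variable toy network with an uncertain bounded production term f(y):
# the positive orthant is its region of validity and the (w, x, y) loop is
# its only positive feedback loop.
TOY_SPEC = """
# toy monotone network with an uncertain bounded term
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
"""

HARMONIC_SPEC = """
var x in [-1, 1]
var y in [-1, 1]
ode x = y
ode y = -x
"""

# x' = z + s(y) - x with s an unsigned bounded term (a stand-in for sin(y))
BOUNDED_SINE_SPEC = """
var x in [-10, 10]
var y in [-10, 10]
var z in [0, 10]
term s(y) in [-1, 1] unknown in y
ode x = z + s(y) - x
ode y = x - y
ode z = 1 - z
"""

# A PAG-regulation fragment: inhibition by TCRb and activation by Fyn combine
# through the Hill-interpolated rule (!TCRb & !Fyn) | Fyn.
PAG_FRAGMENT_SPEC = """
var PAG in [0, 1]
var Fyn in [0, 1]
var TCRb in [0, 1]
ode PAG = (1 - hill(TCRb, 1/2, 1))*(1 - hill(Fyn, 1/2, 2)) + hill(Fyn, 1/2, 2) - PAG
ode Fyn = hill(PAG, 1/2, 2) - Fyn
ode TCRb = 1/2 - TCRb
"""


@pytest.fixture(scope="session")
def toy_model():
    return parse_model(TOY_SPEC)


@pytest.fixture(scope="session")
def harmonic_model():
    return parse_model(HARMONIC_SPEC)


@pytest.fixture(scope="session")
def bounded_sine_model():
    return parse_model(BOUNDED_SINE_SPEC)


@pytest.fixture(scope="session")
def pag_model():
    return parse_model(PAG_FRAGMENT_SPEC)


@pytest.fixture(scope="session")
def toy_high_candidate(toy_model):
    from stablemodules.feedback import (
        conjecture_candidates, cycle_unions, positive_cycles)
    from stablemodules.model import regulatory_graph

    g = regulatory_graph(toy_model)
    unions = cycle_unions(g, positive_cycles(g))
    assert len(unions) == 1
    cands = conjecture_candidates(unions[0])
    return next(c for c in cands if c.polarity == "high-set")


# --------------------------------------------------------------------------- #
# independent oracles (deliberately naive implementations)
# --------------------------------------------------------------------------- #

def oracle_is_stable_module(enet, nodes) -> bool:
    """Standalone re-implementation of the stable-module conditions:
    source-free, composite-closed, consistent (interval intersection)."""
    from stablemodules.expanded import CompositeNode, VirtualNode

    nodes = frozenset(nodes)
    if not nodes:
        return False
    parents = {}
    for (s, t) in enet.edges:
        parents.setdefault(t, set()).add(s)
    for n in nodes:
        if isinstance(n, CompositeNode):
            if not set(n.factors) <= nodes:
                return False
        else:
            if not parents.get(n, set()) & nodes:
                return False
    intervals = {}
    for n in nodes:
        factors = n.factors if isinstance(n, CompositeNode) else [n]
        for v in factors:
            lo, hi = intervals.get(v.variable, (-sp.oo, sp.oo))
            if v.direction == ">":
                lo = max(lo, v.threshold)
            else:
                hi = min(hi, v.threshold)
            if lo >= hi:
                return False
            intervals[v.variable] = (lo, hi)
    return True


def oracle_all_stable_modules(enet, max_nodes: int = 12):
    """Exhaustive enumeration of every stable module by subset search."""
    nodes = sorted(enet.nodes, key=str)
    assert len(nodes) <= max_nodes, "oracle limited to small networks"
    out = []
    for r in range(1, len(nodes) + 1):
        for combo in combinations(nodes, r):
            if oracle_is_stable_module(enet, combo):
                out.append(frozenset(combo))
    return out


def oracle_simple_cycles(edges, max_len):
    """Naive DFS enumeration of simple directed cycles up to max_len."""
    adj = {}
    for s, t in edges:
        adj.setdefault(s, []).append(t)
    cycles = set()

    def dfs(start, node, path):
        if len(path) > max_len:
            return
        for nxt in adj.get(node, []):
            if nxt == start and len(path) >= 1:
                i = path.index(min(path))
                cycles.add(tuple(path[i:] + path[:i]))
            elif nxt not in path and nxt > start:
                dfs(start, nxt, path + [nxt])
            elif nxt == start:
                pass

    for v in sorted(adj):
        dfs(v, v, [v])
    # restrict to cycles whose minimum node is the start (dedup handled above)
    return sorted(cycles, key=lambda c: (tuple(sorted(c)), len(c), c))


def powerset(iterable):
    s = list(iterable)
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))
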
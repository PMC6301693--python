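"""Positive feedback loop enumeration and candidate stable modules.

In the supported model class, every control-robust trap subspace certified by
the downstream worst-case analysis lives on a sign-consistent union of
positive feedback loops of the regulatory graph.  This module enumerates the
positive simple cycles, combines them into chain-intersecting unions, tests
each union for sign-consistency (a ±1 vertex labeling with every edge sign
equal to the product of its endpoint labels), and emits the two conjectured
candidate modules per consistent union: one with the +1-labeled variables
"high" (above an as-yet-unspecified threshold), and its mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .model import SignedDigraph

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class CycleUnion:
    """A connected union of one or more positive simple cycles."""

    nodes: frozenset
    edges: frozenset  # of (source, target, sign)
    generating_cycles: tuple  # of node tuples

    def __post_init__(self):
        covered = set()
        for cyc in self.generating_cycles:
            for i, a in enumerate(cyc):
                covered.add((a, cyc[(i + 1) % len(cyc)]))
        for s, t, _ in self.edges:
            if (s, t) not in covered:
                raise ValueError(f"edge {s}->{t} lies on no generating cycle")


@dataclass(frozen=True)
class CandidateModule:
    """A conjectured stable module: per-variable high/low directions with
    thresholds left unspecified."""

    union: CycleUnion
    direction: tuple  # sorted tuple of (variable, "high"/"low")
    polarity: str  # "high-set" or "mirror"

    @property
    def directions(self) -> dict:
        return dict(self.direction)

    @property
    def variables(self) -> frozenset:
        return self.union.nodes


def _cycle_canonical(cycle: tuple) -> tuple:
    """Rotate a simple cycle so it starts at its lexicographically smallest node."""
    i = cycle.index(min(cycle))
    return cycle[i:] + cycle[:i]


def positive_cycles(graph: SignedDigraph, max_len: int | None = None) -> list:
    """All simple directed cycles of length <= max_len with edge-sign product +1.

    Returned as node tuples in deterministic order (sorted by the sorted node
    names, then length, then the rotation-canonical tuple).  Length-1 positive
    self-loops are admitted as degenerate feedback loops.
    """
    if max_len is None:
        max_len = len(graph.nodes)
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    sign = {(s, t): sg for s, t, sg in graph.edges}
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(sign)
    out = []
    for cyc in nx.simple_cycles(g, length_bound=max_len):
        cyc = _cycle_canonical(tuple(cyc))
        prod = 1
        for i, a in enumerate(cyc):
            prod *= sign[(a, cyc[(i + 1) % len(cyc)])]
        if prod == 1:
            out.append(cyc)
    out.sort(key=lambda c: (tuple(sorted(c)), len(c), c))
    for cyc in out:  # output invariant: every returned cycle is positive
        assert _cycle_sign(cyc, sign) == 1
    return out


def _cycle_sign(cyc, sign):
    prod = 1
    for i, a in enumerate(cyc):
        prod *= sign[(a, cyc[(i + 1) % len(cyc)])]
    return prod


def _cycle_edges(cyc, sign):
    return frozenset(
        (a, cyc[(i + 1) % len(cyc)], sign[(a, cyc[(i + 1) % len(cyc)])])
        for i, a in enumerate(cyc))


def cycle_unions(graph: SignedDigraph, cycles: list, max_union: int = 3) -> list:
    """All unions of up to ``max_union`` positive cycles that chain-intersect.

    Chain-intersection: the cycles of the union, viewed as vertices of an
    intersection graph with an edge whenever two cycles share at least one
    node, form a connected subgraph.  Single cycles are included; unions are
    deduplicated by their node+edge sets.
    """
    sign = {(s, t): sg for s, t, sg in graph.edges}
    node_sets = [frozenset(c) for c in cycles]
    seen = {}
    for r in range(1, min(max_union, len(cycles)) + 1):
        for idx in combinations(range(len(cycles)), r):
            if r > 1 and not _chain_connected([node_sets[i] for i in idx]):
                continue
            nodes = frozenset().union(*(node_sets[i] for i in idx))
            edges = frozenset().union(
                *(_cycle_edges(cycles[i], sign) for i in idx))
            key = (nodes, edges)
            if key not in seen:
                seen[key] = CycleUnion(
                    nodes=nodes, edges=edges,
                    generating_cycles=tuple(cycles[i] for i in idx))
    return sorted(
        seen.values(),
        key=lambda u: (len(u.nodes), tuple(sorted(u.nodes)),
                       tuple(sorted(u.edges))))


def _chain_connected(node_sets) -> bool:
    g = nx.Graph()
    g.add_nodes_from(range(len(node_sets)))
    for i, j in combinations(range(len(node_sets)), 2):
        if node_sets[i] & node_sets[j]:
            g.add_edge(i, j)
    return nx.is_connected(g)


def consistent_labeling(union: CycleUnion) -> dict | None:
    """A vertex labeling node -> ±1 with sign(u→v) = label(u)·label(v) on
    every union edge, or None.  When a labeling exists exactly two do (it and
    its negation); the one assigning +1 to the lexicographically smallest node
    is returned."""
    label: dict = {}
    adj: dict = {}
    for s, t, sg in union.edges:
        adj.setdefault(s, []).append((t, sg))
        adj.setdefault(t, []).append((s, sg))
    for start in sorted(union.nodes):
        if start in label:
            continue
        label[start] = 1
        stack = [start]
        while stack:
            u = stack.pop()
            for v, sg in adj.get(u, ()):
                want = label[u] * sg
                if v not in label:
                    label[v] = want
                    stack.append(v)
                elif label[v] != want:
                    return None
    smallest = min(union.nodes)
    if label[smallest] == -1:
        label = {k: -v for k, v in label.items()}
    return label


def conjecture_candidates(union: CycleUnion) -> list:
    """The (at most two) candidate stable modules of a cycle union: the
    consistent labeling with +1 ↦ high, and its mirror; empty if the union is
    sign-inconsistent."""
    label = consistent_labeling(union)
    if label is None:
        return []
    direction = tuple(sorted(
        (v, HIGH if s == 1 else LOW) for v, s in label.items()))
    mirror = tuple(sorted(
        (v, LOW if s == 1 else HIGH) for v, s in label.items()))
    cands = [
        CandidateModule(union=union, direction=direction, polarity="high-set"),
        CandidateModule(union=union, direction=mirror, polarity="mirror"),
    ]
    lab = {1: HIGH, -1: LOW}
    for cand in cands:  # output invariant: labeling equation on every edge
        d = cand.directions
        for s, t, sg in union.edges:
            ls = 1 if d[s] == HIGH else -1
            lt = 1 if d[t] == HIGH else -1
            assert sg == ls * lt, "direction violates labeling equation"
    del lab
    return cands


def union_to_dot(union: CycleUnion) -> str:
    """Export a cycle union as a DOT digraph (edge labels carry signs)."""
    lines = ["digraph cycle_union {"]
    for n in sorted(union.nodes):
        lines.append(f'  "{n}";')
    for s, t, sg in sorted(union.edges):
        style = "normal" if sg > 0 else "tee"
        lines.append(f'  "{s}" -> "{t}" [sign={sg:+d}, arrowhead={style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
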
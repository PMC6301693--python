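"""The expanded network: statements as nodes, certified causality as edges.

Nodes are *virtual nodes* — threshold statements ``x > T`` or ``x < T`` about
single variables — and *composite nodes*, AND-conjunctions of virtual nodes.
A *maintenance edge* X → Y certifies that Y cannot switch from true to false
while X is true; a *driving edge* additionally certifies that sustained truth
of X makes Y true in finite time.  Both are established with the monotone
bound machinery: maintenance needs the vector field to point (weakly) inward
on Y's boundary face restricted to X's region; driving needs a strictly
positive inward bound over the whole "X true, Y false" region.

A *stable module* is a source-free, composite-closed, consistent subnetwork;
once all its statements hold they hold forever, under arbitrary valid control
of every variable outside the statements.  A *stable motif* is a stable module
with no proper stable submodule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import sympy as sp

from .model import (
    Box, IndefiniteSignError, ModelSystem, UnboundedError, interaction_sign,
    monotone_bound)

MAINTENANCE = "maintenance"
DRIVING = "driving"


# --------------------------------------------------------------------------- #
# nodes
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class VirtualNode:
    """A statement ``variable > threshold`` or ``variable < threshold``."""

    variable: str
    direction: str  # ">" or "<"
    threshold: object  # sympy number

    def __post_init__(self):
        if self.direction not in (">", "<"):
            raise ValueError("direction must be '>' or '<'")
        object.__setattr__(self, "threshold", sp.nsimplify(
            sp.sympify(self.threshold), rational=True, tolerance=1e-12))

    def __str__(self):
        return f"{self.variable} {self.direction} {self.threshold}"

    def implies(self, other: "VirtualNode") -> bool:
        """Logical implication between statements on the same variable."""
        if self.variable != other.variable or self.direction != other.direction:
            return False
        if self.direction == ">":
            return bool(self.threshold >= other.threshold)
        return bool(self.threshold <= other.threshold)

    def contradicts(self, other: "VirtualNode") -> bool:
        if self.variable != other.variable or self.direction == other.direction:
            return False
        gt, lt = (self, other) if self.direction == ">" else (other, self)
        return bool(gt.threshold >= lt.threshold)

    def satisfying_interval(self, model: ModelSystem) -> tuple:
        lo, hi = model.validity[self.variable]
        if self.direction == ">":
            return (self.threshold, hi)
        return (lo, self.threshold)


@dataclass(frozen=True)
class CompositeNode:
    """AND-conjunction of two or more virtual nodes."""

    factors: frozenset

    def __post_init__(self):
        object.__setattr__(self, "factors", frozenset(self.factors))
        if len(self.factors) < 2:
            raise ValueError("composite node needs >= 2 factors")
        if not statements_consistent(self.factors):
            raise ValueError("composite factors are mutually inconsistent")

    def __str__(self):
        return " AND ".join(sorted(str(f) for f in self.factors))


def _sort_key(node):
    if isinstance(node, VirtualNode):
        return (0, node.variable, node.direction, float(node.threshold))
    return (1, str(node))


def statements_consistent(nodes) -> bool:
    """Whether a set of statements can hold simultaneously: per variable,
    max of '>' thresholds must lie strictly below min of '<' thresholds."""
    virtuals = []
    for n in nodes:
        if isinstance(n, CompositeNode):
            virtuals.extend(n.factors)
        else:
            virtuals.append(n)
    per_var: dict = {}
    for v in virtuals:
        lo, hi = per_var.get(v.variable, (-sp.oo, sp.oo))
        if v.direction == ">":
            lo = max(lo, v.threshold)
        else:
            hi = min(hi, v.threshold)
        if lo >= hi:
            return False
        per_var[v.variable] = (lo, hi)
    return True


def region_of(nodes, model: ModelSystem) -> Box | None:
    """The sub-box of validity where all statements hold (closure); None if
    the statements are inconsistent with the validity box."""
    box = Box()
    for n in nodes:
        factors = n.factors if isinstance(n, CompositeNode) else (n,)
        for v in factors:
            lo, hi = model.validity[v.variable]
            cur = box.get(v.variable, (lo, hi))
            s_lo, s_hi = v.satisfying_interval(model)
            new = (max(cur[0], s_lo), min(cur[1], s_hi))
            if new[0] > new[1]:
                return None
            box[v.variable] = new
    return box


# --------------------------------------------------------------------------- #
# edge certification
# --------------------------------------------------------------------------- #

def certify_edge(model: ModelSystem, source, target: VirtualNode,
                 kind: str = MAINTENANCE, tol: float = 1e-9) -> bool:
    """Certify a maintenance or driving edge from ``source`` (virtual or
    composite) to the virtual node ``target``.

    Maintenance: the monotone bound of the target's RHS on the face
    {target variable at its threshold} ∩ {source region} ∩ validity has the
    inward sign.  Driving: additionally, the inward bound over
    {source region} ∩ {target false} is strictly positive (finite-time
    escape).  Indefinite signs or diverging bounds yield False.
    """
    if kind not in (MAINTENANCE, DRIVING):
        raise ValueError(f"unknown edge kind {kind!r}")
    region = region_of([source], model)
    if region is None:
        return True  # source unsatisfiable within validity: vacuous
    v = target.variable
    t = target.threshold
    lo, hi = model.validity[v]
    if not (lo <= t <= hi):
        return False
    side = "lower" if target.direction == ">" else "upper"
    # --- face condition (maintenance) ---
    cur = region.get(v, (lo, hi))
    if not (cur[0] <= t <= cur[1]):
        face_ok = True  # face unreachable while source true: vacuous
    else:
        face = Box(region)
        face[v] = (t, t)
        try:
            bound = monotone_bound(model, v, face, side)
        except (UnboundedError, IndefiniteSignError):
            return False
        b = float(sp.N(bound))
        face_ok = b >= -tol if target.direction == ">" else b <= tol
    if kind == MAINTENANCE or not face_ok:
        return face_ok
    # --- escape condition (driving) ---
    false_int = (lo, t) if target.direction == ">" else (t, hi)
    inter = (max(cur[0], false_int[0]), min(cur[1], false_int[1]))
    if inter[0] > inter[1]:
        return True  # target cannot be false while source true: vacuous drive
    esc = Box(region)
    esc[v] = inter
    try:
        bound = monotone_bound(model, v, esc, side)
    except (UnboundedError, IndefiniteSignError):
        return False
    b = float(sp.N(bound))
    return b > tol if target.direction == ">" else b < -tol


# --------------------------------------------------------------------------- #
# the network
# --------------------------------------------------------------------------- #

@dataclass
class ExpandedNetwork:
    """Virtual/composite nodes with certified maintenance/driving edges.

    ``edges`` maps (source node, target virtual) to the strongest certified
    kind; factor edges (factor virtual → composite) are structural and implied
    by the composites' factor sets.
    """

    virtuals: frozenset = field(default_factory=frozenset)
    composites: frozenset = field(default_factory=frozenset)
    edges: dict = field(default_factory=dict)

    def __post_init__(self):
        for c in self.composites:
            for f in c.factors:
                if f not in self.virtuals:
                    raise ValueError(f"composite factor {f} not in network")
        for (s, t), kind in self.edges.items():
            if kind not in (MAINTENANCE, DRIVING):
                raise ValueError(f"bad edge kind {kind}")
            if not isinstance(t, VirtualNode):
                raise ValueError("maintenance/driving edges must target virtuals")

    @property
    def nodes(self) -> frozenset:
        return self.virtuals | self.composites

    def graph(self) -> nx.DiGraph:
        """Directed graph over all nodes: certified edges plus factor edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), kind in self.edges.items():
            g.add_edge(s, t, kind=kind)
        for c in self.composites:
            for f in c.factors:
                g.add_edge(f, c, kind="factor")
        return g

    def maintenance_parents(self, node) -> set:
        if isinstance(node, CompositeNode):
            return set(node.factors)
        return {s for (s, t) in self.edges if t == node}

    def driving_edges(self) -> set:
        return {(s, t) for (s, t), k in self.edges.items() if k == DRIVING}


def build_expanded_network(model: ModelSystem, virtuals, max_arity: int = 3,
                           with_driving: bool = True, tol: float = 1e-9
                           ) -> ExpandedNetwork:
    """All certified edges among the given virtual nodes, plus auto-generated
    composite nodes.

    Composites: for each target virtual node, conjunctions of up to
    ``max_arity`` virtual nodes over distinct regulator variables of the
    target are added when the conjunction certifies a maintenance edge to the
    target while no nonempty proper sub-conjunction does.
    """
    virtuals = tuple(sorted(set(virtuals), key=_sort_key))
    edges: dict = {}
    for tgt in virtuals:
        for src in virtuals:
            if certify_edge(model, src, tgt, MAINTENANCE, tol):
                kind = MAINTENANCE
                if with_driving and certify_edge(model, src, tgt, DRIVING, tol):
                    kind = DRIVING
                edges[(src, tgt)] = kind
    composites: set = set()
    for tgt in virtuals:
        regs = [v for v in model.variables
                if v != tgt.variable
                and interaction_sign(model, tgt.variable, v) not in (0,)]
        pool = [v for v in virtuals if v.variable in regs]
        certifying_subsets: set = {
            frozenset([src]) for src in pool
            if (src, tgt) in edges}
        for arity in range(2, max_arity + 1):
            for combo in combinations(pool, arity):
                vars_ = [c.variable for c in combo]
                if len(set(vars_)) != arity:
                    continue
                fs = frozenset(combo)
                if not statements_consistent(fs):
                    continue
                if any(sub < fs for sub in certifying_subsets):
                    continue  # a smaller conjunction already suffices
                comp = CompositeNode(factors=fs)
                if certify_edge(model, comp, tgt, MAINTENANCE, tol):
                    certifying_subsets.add(fs)
                    composites.add(comp)
                    kind = MAINTENANCE
                    if with_driving and certify_edge(model, comp, tgt, DRIVING, tol):
                        kind = DRIVING
                    edges[(comp, tgt)] = kind
    return ExpandedNetwork(
        virtuals=frozenset(virtuals), composites=frozenset(composites),
        edges=edges)


# --------------------------------------------------------------------------- #
# stable modules and motifs
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class GraphStableModule:
    """A source-free, composite-closed, consistent expanded subnetwork."""

    nodes: frozenset
    kind: str  # "motif" (no proper stable submodule) or "module"

    @property
    def virtuals(self) -> frozenset:
        return frozenset(n for n in self.nodes if isinstance(n, VirtualNode))

    @property
    def statements(self) -> frozenset:
        return frozenset(
            (v.variable, v.direction, float(v.threshold)) for v in self.virtuals)

    def __str__(self):
        return "{" + ", ".join(sorted(str(n) for n in self.nodes)) + "}"


def is_stable_module(enet: ExpandedNetwork, nodes) -> bool:
    """Conditions: (i) source-free — every node has a parent inside; (ii)
    composite-closed — factors of member composites are members; (iii)
    consistent — all statements can hold simultaneously."""
    nodes = frozenset(nodes)
    if not nodes or not nodes <= enet.nodes:
        return False
    for n in nodes:
        if isinstance(n, CompositeNode):
            if not n.factors <= nodes:
                return False
            if not n.factors:  # pragma: no cover - composites have factors
                return False
        else:
            if not (enet.maintenance_parents(n) & nodes):
                return False
    return statements_consistent(nodes)


def _composite_closure(enet: ExpandedNetwork, nodes: frozenset) -> frozenset:
    out = set(nodes)
    changed = True
    while changed:
        changed = False
        for n in list(out):
            if isinstance(n, CompositeNode) and not n.factors <= out:
                out |= n.factors
                changed = True
    return frozenset(out)


def maximal_stable_subnetwork(enet: ExpandedNetwork) -> frozenset:
    """The maximal source-free, composite-closed subnetwork, via iterative
    pruning of parentless virtuals and factor-incomplete composites.  (It may
    be inconsistent; consistency is checked by the callers.)"""
    alive = set(enet.nodes)
    changed = True
    while changed:
        changed = False
        for n in list(alive):
            if isinstance(n, CompositeNode):
                ok = n.factors <= alive
            else:
                ok = bool(enet.maintenance_parents(n) & alive)
            if not ok:
                alive.discard(n)
                changed = True
    return frozenset(alive)


_RECURSE_CAP = 4096  # visited-subset guard for the SCC recursion


def _scc_cores(graph: nx.DiGraph) -> set:
    """All cyclic cores obtainable by recursive SCC decomposition: the SCCs of
    the graph and, recursively, the SCCs of every SCC with one node deleted.
    Enumerates the strongly-connected seeds of all candidate stable modules
    (exact on the small expanded networks this package targets)."""
    out: set = set()
    seen: set = set()

    def rec(nodes: frozenset):
        if nodes in seen or len(seen) > _RECURSE_CAP:
            return
        seen.add(nodes)
        sub = graph.subgraph(nodes)
        for comp in nx.strongly_connected_components(sub):
            comp = frozenset(comp)
            cyclic = len(comp) > 1 or any(
                sub.has_edge(v, v) for v in comp)
            if not cyclic:
                continue
            out.add(comp)
            if len(comp) > 1:
                for v in sorted(comp, key=_sort_key):
                    rec(comp - {v})

    rec(frozenset(graph.nodes))
    return out


def find_stable_modules(enet: ExpandedNetwork) -> list:
    """Stable modules of the network: motifs (no proper stable submodule)
    enumerated from recursive strongly-connected cores plus their composite
    closures, together with all larger closure modules and, when consistent,
    the maximal source-free composite-closed subnetwork.  Deterministic order
    (motifs first, then by size and node names)."""
    arena = maximal_stable_subnetwork(enet)
    graph = enet.graph().subgraph(arena)
    candidates: set = set()
    for core in _scc_cores(graph):
        closed = _composite_closure(enet, core)
        if closed <= arena and is_stable_module(enet, closed):
            candidates.add(closed)
    if arena and statements_consistent(arena) and is_stable_module(enet, arena):
        candidates.add(arena)
    minimal = {c for c in candidates
               if not any(o < c for o in candidates)}
    out = [GraphStableModule(nodes=c, kind="motif" if c in minimal else "module")
           for c in candidates]
    out.sort(key=lambda m: (m.kind != "motif", len(m.nodes),
                            tuple(sorted(_sort_key(n) for n in m.nodes))))
    return out


# --------------------------------------------------------------------------- #
# reduction and sequences
# --------------------------------------------------------------------------- #

def reduce_network(enet: ExpandedNetwork, active: GraphStableModule
                   ) -> ExpandedNetwork:
    """Simplify the network under the assumption that ``active`` holds.

    Satisfied factor edges are removed (composite arity shrinks; arity-1
    composites collapse to direct edges; fully satisfied composites make their
    targets self-sustaining); a maintenance/driving edge whose source
    statement is implied by the active module likewise becomes unconditional,
    i.e. a self-loop on its target; virtual nodes contradicting an active
    statement are removed along with incident edges and dependent composites.
    """
    if active.nodes and not is_stable_module(enet, active.nodes):
        raise ValueError("active set is not a stable module of the network")
    act_virtuals = {n for n in active.nodes if isinstance(n, VirtualNode)}

    def satisfied(v: VirtualNode) -> bool:
        return any(a.implies(v) for a in act_virtuals)

    def contradicted(v: VirtualNode) -> bool:
        return any(a.contradicts(v) for a in act_virtuals)

    had_parent = {v for v in enet.virtuals if enet.maintenance_parents(v)}
    keep_virtuals = {v for v in enet.virtuals if not contradicted(v)}
    edges: dict = {}
    comp_map: dict = {}  # old composite -> replacement node (or None if gone)
    composites: set = set()
    for c in enet.composites:
        if any(f not in keep_virtuals for f in c.factors):
            comp_map[c] = None
            continue
        remaining = frozenset(f for f in c.factors if not satisfied(f))
        if len(remaining) >= 2:
            newc = CompositeNode(factors=remaining)
            composites.add(newc)
            comp_map[c] = newc
        elif len(remaining) == 1:
            comp_map[c] = next(iter(remaining))
        else:
            comp_map[c] = "TRUE"
    for (s, t), kind in enet.edges.items():
        if t not in keep_virtuals:
            continue
        if isinstance(s, CompositeNode):
            s2 = comp_map.get(s)
            if s2 is None:
                continue
            if s2 == "TRUE":
                edges[(t, t)] = _stronger(edges.get((t, t)), kind)
                continue
            edges[(s2, t)] = _stronger(edges.get((s2, t)), kind)
        else:
            if s not in keep_virtuals:
                continue
            if satisfied(s):
                edges[(t, t)] = _stronger(edges.get((t, t)), kind)
            else:
                edges[(s, t)] = _stronger(edges.get((s, t)), kind)
    reduced = ExpandedNetwork(
        virtuals=frozenset(keep_virtuals), composites=frozenset(composites),
        edges=edges)
    for v in reduced.virtuals:  # reduction only orphans contradiction victims
        if v in had_parent and not reduced.maintenance_parents(v):
            assert any(
                isinstance(p, VirtualNode) and contradicted(p) or
                isinstance(p, CompositeNode) and any(
                    contradicted(f) for f in p.factors)
                for p in enet.maintenance_parents(v)), \
                f"reduction orphaned {v} without a contradiction"
    return reduced


def _stronger(a, b):
    if a == DRIVING or b == DRIVING:
        return DRIVING
    return MAINTENANCE


def module_sequences(enet: ExpandedNetwork, max_depth: int = 12,
                     max_sequences: int = 256) -> tuple:
    """Depth-first composition of motifs: the motifs of the network, then the
    motifs of each reduction, recursively to quiescence.

    Returns ``(sequences, exclusivity)``: each sequence is an ordered list of
    GraphStableModules (statements refer to original-model variables); two
    sequences are mutually exclusive when a module statement of one
    contradicts a module statement of the other.
    """
    sequences: list = []

    def rec(net: ExpandedNetwork, prefix: list, active_stmts: set, depth: int):
        if len(sequences) >= max_sequences:
            return
        motifs = [m for m in find_stable_modules(net) if m.kind == "motif"]
        motifs = [m for m in motifs
                  if statements_consistent(
                      set(m.virtuals) | active_stmts)
                  and not _already_implied(m, active_stmts)]
        if not motifs or depth >= max_depth:
            if prefix:
                sequences.append(list(prefix))
            return
        for m in motifs:
            reduced = reduce_network(net, m)
            rec(reduced, prefix + [m], active_stmts | set(m.virtuals),
                depth + 1)

    rec(enet, [], set(), 0)
    exclusivity = []
    for i, j in combinations(range(len(sequences)), 2):
        si = {v for m in sequences[i] for v in m.virtuals}
        sj = {v for m in sequences[j] for v in m.virtuals}
        if any(a.contradicts(b) for a in si for b in sj):
            exclusivity.append((i, j))
    return sequences, exclusivity


def _already_implied(module: GraphStableModule, active_stmts: set) -> bool:
    return all(any(a.implies(v) for a in active_stmts)
               for v in module.virtuals)


# --------------------------------------------------------------------------- #
# driver node sets
# --------------------------------------------------------------------------- #

def propagate_truth(enet: ExpandedNetwork, seeds) -> set:
    """Fixpoint truth propagation with the seed statements held true: a
    composite becomes true when all factors are true; a virtual becomes true
    when implied by a true statement or when any incoming *driving* edge has a
    true source."""
    true: set = set(seeds)
    changed = True
    driving = enet.driving_edges()
    while changed:
        changed = False
        for v in enet.virtuals:
            if v in true:
                continue
            if any(t.implies(v) for t in true if isinstance(t, VirtualNode)):
                true.add(v)
                changed = True
                continue
            if any((s, v) in driving and s in true
                   for s in {e[0] for e in driving if e[1] == v}):
                true.add(v)
                changed = True
        for c in enet.composites:
            if c not in true and c.factors <= true:
                true.add(c)
                changed = True
    return true


def driver_sets(enet: ExpandedNetwork, module: GraphStableModule,
                max_size: int = 3) -> list:
    """All minimal consistent sets of virtual nodes, of size <= max_size,
    whose imposed truth propagates (through driving edges and composites) to
    every node of the module."""
    target = set(module.nodes)
    pool = sorted(enet.virtuals, key=_sort_key)
    found: list = []
    for size in range(1, max_size + 1):
        for combo in combinations(pool, size):
            d = frozenset(combo)
            if any(f < d for f in found):
                continue  # not minimal
            if not statements_consistent(d):
                continue
            if target <= propagate_truth(enet, d):
                found.append(d)
    return sorted(found, key=lambda d: (len(d),
                                        tuple(sorted(_sort_key(n) for n in d))))


# --------------------------------------------------------------------------- #
# export
# --------------------------------------------------------------------------- #

def to_dot(enet: ExpandedNetwork) -> str:
    """DOT export: virtual nodes as boxes, composites as circles, driving
    edges solid, maintenance-only edges dotted, factor edges dashed."""
    ids = {n: f"n{i}" for i, n in enumerate(
        sorted(enet.nodes, key=_sort_key))}
    lines = ["digraph expanded_network {"]
    for n, i in ids.items():
        shape = "box" if isinstance(n, VirtualNode) else "circle"
        lines.append(f'  {i} [label="{n}", shape={shape}];')
    for (s, t), kind in sorted(enet.edges.items(),
                               key=lambda e: (_sort_key(e[0][0]), _sort_key(e[0][1]))):
        style = "solid" if kind == DRIVING else "dotted"
        lines.append(f'  {ids[s]} -> {ids[t]} [style={style}];')
    for c in sorted(enet.composites, key=_sort_key):
        for f in sorted(c.factors, key=_sort_key):
            lines.append(f'  {ids[f]} -> {ids[c]} [style=dashed];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(enet: ExpandedNetwork) -> str:
    g = nx.DiGraph()
    for n in enet.nodes:
        g.add_node(str(n), node_type=(
            "virtual" if isinstance(n, VirtualNode) else "composite"))
    for (s, t), kind in enet.edges.items():
        g.add_edge(str(s), str(t), kind=kind)
    for c in enet.composites:
        for f in c.factors:
            g.add_edge(str(f), str(c), kind="factor")
    return "\n".join(nx.generate_graphml(g)) + "\n"


def modules_to_json(modules: list) -> str:
    payload = []
    for m in modules:
        payload.append({
            "kind": m.kind,
            "virtual_nodes": sorted(str(v) for v in m.virtuals),
            "composite_nodes": sorted(
                str(c) for c in m.nodes if isinstance(c, CompositeNode)),
        })
    return json.dumps(payload, indent=2)
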
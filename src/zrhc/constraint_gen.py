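"""Constraint generation over all loci (Step 2).

Each non-tree edge present in a locus graph yields either a *cycle
constraint* (the whole fundamental cycle survives in the locus graph: the
XOR of its d-constants) or a *path constraint* (the cycle is broken by
predetermined nodes: walking from the edge's endpoints to the first
predetermined node on each side, the XOR of endpoint p-values and path
d-constants).  Tree constraints connect predetermined nodes within each
locus-forest component through a seed.  All three sets are keyed so that a
re-derived constraint is either a silent duplicate or -- if its value
disagrees -- a logged genotype inconsistency (consistency checkpoint 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_build import LocusData, SpanningTree

__all__ = [
    "CycleConstraint",
    "PathConstraint",
    "TreeConstraint",
    "ConstraintSystem",
    "add_constraint",
    "gen_edge_constraints",
    "gen_tree_constraints",
    "generate_all",
]


@dataclass(frozen=True)
class CycleConstraint:
    """XOR of inheritance bits around the fundamental cycle of ``edge`` = b."""

    edge: int
    b: int
    locus: int = -1


@dataclass(frozen=True)
class PathConstraint:
    """XOR of inheritance bits along a locus-graph path through non-tree
    ``edge`` between predetermined nodes ``a`` and ``b_node``.

    ``a_side``/``b_side`` record which endpoint of ``edge`` lies on each
    constraint endpoint's side of the path (needed by the Step-4 linking
    formula)."""

    a: int
    b_node: int
    b: int
    edge: int
    a_side: int
    b_side: int
    locus: int = -1

    @property
    def key(self) -> tuple[int, int, int]:
        lo, hi = sorted((self.a, self.b_node))
        return (lo, hi, self.edge)


@dataclass(frozen=True)
class TreeConstraint:
    """XOR of inheritance bits along the tree path between predetermined
    nodes ``a`` and ``b_node`` = b; symmetric in its endpoints."""

    a: int
    b_node: int
    b: int
    locus: int = -1

    @property
    def key(self) -> tuple[int, int]:
        lo, hi = sorted((self.a, self.b_node))
        return (lo, hi)


@dataclass
class ConstraintSystem:
    """The keyed sets C^C (by edge), C^P (by endpoints+edge) and C^T (by
    endpoints), with a log of value conflicts found during insertion."""

    cycle: dict[int, CycleConstraint] = field(default_factory=dict)
    path: dict[tuple[int, int, int], PathConstraint] = field(default_factory=dict)
    tree: dict[tuple[int, int], TreeConstraint] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def paths_of_edge(self, eid: int) -> list[PathConstraint]:
        return sorted(
            (c for c in self.path.values() if c.edge == eid),
            key=lambda c: c.key,
        )


def add_constraint(system: ConstraintSystem, c) -> str:
    """Keyed insertion; returns 'added', 'duplicate' or 'conflict'.

    Conflicts (same key, different value) are logged rather than raised so
    checking can continue across the whole input.
    """
    if isinstance(c, CycleConstraint):
        store, key = system.cycle, c.edge
    elif isinstance(c, PathConstraint):
        store, key = system.path, c.key
    elif isinstance(c, TreeConstraint):
        store, key = system.tree, c.key
    else:  # pragma: no cover - programming error
        raise TypeError(f"not a constraint: {c!r}")
    old = store.get(key)
    if old is None:
        store[key] = c
        return "added"
    if old.b == c.b:
        return "duplicate"
    system.conflicts.append(
        f"constraint conflict at key {key}: value {old.b} (locus {old.locus + 1}) "
        f"vs {c.b} (locus {c.locus + 1})"
    )
    return "conflict"


def _walk_to_predetermined(
    seq_nodes: list[int], seq_edges: list[int], ld: LocusData
) -> tuple[int, int, list[int]]:
    """Walk along ``seq_nodes`` (starting at a non-tree-edge endpoint) until
    the first predetermined node; returns (stop node, its p-value, edges
    traversed).  Every maximal locus-graph segment inside a fundamental
    cycle ends at a predetermined node, so the walk always terminates."""
    node = seq_nodes[0]
    used: list[int] = []
    i = 0
    while not ld.predetermined[node]:
        if i >= len(seq_edges) or not ld.in_locus_graph[seq_edges[i]]:
            raise AssertionError(
                "locus-graph segment ended at a non-predetermined node; "
                "predetermination invariant violated"
            )
        used.append(seq_edges[i])
        node = seq_nodes[i + 1]
        i += 1
    return node, int(ld.p0[node]), used


def gen_edge_constraints(
    tree: SpanningTree, ld: LocusData, eid: int
) -> list[CycleConstraint | PathConstraint]:
    """Cycle or path constraint of non-tree edge ``eid`` at one locus.

    No-op when the edge is absent from the locus graph.  When the whole
    fundamental cycle survives, the cycle constraint takes priority; else
    the unique locus-graph path through the edge is delimited by the first
    predetermined node on each side.
    """
    if not ld.in_locus_graph[eid]:
        return []
    nodes, edges = tree.fundamental_cycle(eid)
    # nodes runs u..v along the tree path; edges = tree path edges + [eid]
    if all(ld.in_locus_graph[e] for e in edges):
        b = 0
        for e in edges:
            b ^= int(ld.d[e])
        return [CycleConstraint(eid, b, ld.locus)]
    u, v = nodes[0], nodes[-1]
    # walk away from e on u's side (towards v along the tree path) and on
    # v's side (towards u), each stopping at the first predetermined node
    stop_u, p_u, used_u = _walk_to_predetermined(nodes, edges[:-1], ld)
    stop_v, p_v, used_v = _walk_to_predetermined(
        list(reversed(nodes)), list(reversed(edges[:-1])), ld
    )
    b = p_u ^ p_v ^ int(ld.d[eid])
    for e in used_u:
        b ^= int(ld.d[e])
    for e in used_v:
        b ^= int(ld.d[e])
    return [PathConstraint(stop_u, stop_v, b, eid, a_side=u, b_side=v, locus=ld.locus)]


def gen_tree_constraints(tree: SpanningTree, ld: LocusData) -> list[TreeConstraint]:
    """Tree constraints of one locus forest.

    Per connected component of the locus forest with at least two
    predetermined nodes: seed = smallest-index predetermined node; one
    traversal accumulates the d-XOR from the seed, and every other
    predetermined node k yields (seed, k, p_seed ^ p_k ^ d-XOR).
    """
    n = tree.graph.n
    out: list[TreeConstraint] = []
    seen = [False] * n
    for start in range(n):
        if seen[start]:
            continue
        # collect the locus-forest component containing start
        comp: list[int] = []
        acc: dict[int, int] = {start: 0}
        stack = [start]
        seen[start] = True
        while stack:
            x = stack.pop()
            comp.append(x)
            for y, e in tree.tree_adj[x]:
                if not seen[y] and ld.in_locus_graph[e]:
                    seen[y] = True
                    acc[y] = acc[x] ^ int(ld.d[e])
                    stack.append(y)
        predet = sorted(x for x in comp if ld.predetermined[x])
        if len(predet) < 2:
            continue
        seed = predet[0]
        for k in predet[1:]:
            b = int(ld.p0[seed]) ^ int(ld.p0[k]) ^ acc[seed] ^ acc[k]
            out.append(TreeConstraint(seed, k, b, ld.locus))
    return out


def generate_all(
    tree: SpanningTree, locus_data: list[LocusData]
) -> ConstraintSystem:
    """Run constraint generation for every locus, with keyed dedup and
    conflict logging (checkpoint 1)."""
    system = ConstraintSystem()
    for ld in locus_data:
        for eid in tree.nontree_edges:
            for c in gen_edge_constraints(tree, ld, eid):
                add_constraint(system, c)
        for c in gen_tree_constraints(tree, ld):
            add_constraint(system, c)
    return system
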
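"""Constraint reduction and transformation (Step 3).

Path constraints of any edge that owns a cycle constraint are linearly
dependent on it and fold into tree constraints (Type-1 redundancy).  The
surviving tree constraints become edges of a *constraint graph* over the
individuals; within each connected component ("W-frame") a breadth-first
traversal from a seed assigns every node a cumulative value ``W`` such that
``W[i] + W[j]`` is the tree-path constraint between i and j.  Revisits must
agree -- that re-check is the second consistency checkpoint (Type-2
redundancy turned into an error detector).

Global non-tree edges still lacking a cycle constraint may acquire a
*synthetic* one: an odd number of their path constraints linking W-frames
forms a cycle whose value is the XOR of endpoint W-values and path values;
that synthetic cycle constraint then converts all the edge's path
constraints to tree constraints and merges frames.  The procedure iterates
because each merge can enable further syntheses.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .constraint_gen import (
    ConstraintSystem,
    CycleConstraint,
    PathConstraint,
    TreeConstraint,
    add_constraint,
)
from .gf2_core import ZERO, GF2Expr, gf2_add

__all__ = [
    "GStarEdge",
    "ConstraintGraph",
    "transform_type1",
    "build_constraint_graph",
    "extend_by_synthetic_cycles",
]


@dataclass
class GStarEdge:
    i: int
    j: int
    weight: GF2Expr
    tag: str  # 'tree' | 'founder' | 'free'


class ConstraintGraph:
    """G*: nodes are individuals; edges carry tree-constraint weights.

    ``frame[v]`` is the id of v's connected component (the smallest node
    index it contains, which is also the traversal seed with W = 0).
    Isolated nodes are singleton frames with W = 0.
    """

    def __init__(self, n: int):
        self.n = n
        self.edges: list[GStarEdge] = []
        self.adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        self.frame: list[int] = list(range(n))
        self.W: list[GF2Expr] = [ZERO] * n
        self.conflicts: list[str] = []
        self._conflict_keys: set[str] = set()

    def add_edge(self, i: int, j: int, weight: GF2Expr, tag: str) -> None:
        eid = len(self.edges)
        self.edges.append(GStarEdge(i, j, weight, tag))
        self.adj[i].append((j, eid))
        self.adj[j].append((i, eid))

    def _log_conflict(self, msg: str) -> None:
        if msg not in self._conflict_keys:
            self._conflict_keys.add(msg)
            self.conflicts.append(msg)

    def recompute(self) -> None:
        """Deterministic BFS W-assignment per frame, seed = smallest node.

        A revisit whose W disagrees with the stored value exposes an
        inconsistent constraint loop (checkpoint 2)."""
        self.frame = [-1] * self.n
        self.W = [ZERO] * self.n
        for seed in range(self.n):
            if self.frame[seed] >= 0:
                continue
            self.frame[seed] = seed
            self.W[seed] = ZERO
            queue = deque([seed])
            while queue:
                u = queue.popleft()
                for v, eid in sorted(self.adj[u]):
                    w_v = gf2_add(self.W[u], self.edges[eid].weight)
                    if self.frame[v] < 0:
                        self.frame[v] = seed
                        self.W[v] = w_v
                        queue.append(v)
                    elif self.W[v] != w_v:
                        self._log_conflict(
                            f"W-value disagreement at node {v} in frame {seed}: "
                            f"{self.W[v]} vs {w_v}"
                        )

    def frames(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for v in range(self.n):
            out.setdefault(self.frame[v], []).append(v)
        return out


def transform_type1(system: ConstraintSystem) -> list[TreeConstraint]:
    """Fold every path constraint of a cycle-constrained edge into a tree
    constraint (b_t = b_c + b_p); conflicts are logged via keyed insertion."""
    new: list[TreeConstraint] = []
    for eid in sorted(system.cycle):
        bc = system.cycle[eid].b
        for pc in system.paths_of_edge(eid):
            del system.path[pc.key]
            tc = TreeConstraint(pc.a, pc.b_node, bc ^ pc.b, pc.locus)
            if add_constraint(system, tc) == "added":
                new.append(tc)
    return new


def build_constraint_graph(system: ConstraintSystem, n: int) -> ConstraintGraph:
    """One G*-edge per tree constraint, then a seeded W-assignment."""
    gstar = ConstraintGraph(n)
    for key in sorted(system.tree):
        tc = system.tree[key]
        gstar.add_edge(tc.a, tc.b_node, GF2Expr(tc.b), "tree")
    gstar.recompute()
    return gstar


def _find_odd_cycle(
    pcs: list[PathConstraint], frame: list[int]
) -> list[PathConstraint] | None:
    """First odd cycle, in deterministic scan order, in the multigraph whose
    vertices are W-frames and whose edges are the path constraints of one
    non-tree edge.  Self-loops (both endpoints in one frame) come first."""
    for pc in pcs:
        if frame[pc.a] == frame[pc.b_node]:
            return [pc]
    # two-colour the frame multigraph; an edge joining equal colours closes
    # an odd cycle with the colouring-forest path between its endpoints
    vertices = sorted({frame[pc.a] for pc in pcs} | {frame[pc.b_node] for pc in pcs})
    adjacency: dict[int, list[tuple[int, int]]] = {v: [] for v in vertices}
    for idx, pc in enumerate(pcs):
        u, v = frame[pc.a], frame[pc.b_node]
        adjacency[u].append((v, idx))
        adjacency[v].append((u, idx))
    colour: dict[int, int] = {}
    parent: dict[int, tuple[int, int] | None] = {}
    depth: dict[int, int] = {}
    for root in vertices:
        if root in colour:
            continue
        colour[root] = 0
        parent[root] = None
        depth[root] = 0
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for v, idx in sorted(adjacency[u]):
                if v not in colour:
                    colour[v] = colour[u] ^ 1
                    parent[v] = (u, idx)
                    depth[v] = depth[u] + 1
                    queue.append(v)
                elif colour[v] == colour[u]:
                    # a colouring-forest edge always joins opposite colours,
                    # so idx is a genuine closing edge
                    # recover the odd cycle: idx plus the forest path u..v
                    cycle = [idx]
                    a, b = u, v
                    while depth[a] > depth[b]:
                        a, e = parent[a][0], parent[a][1]
                        cycle.append(e)
                    while depth[b] > depth[a]:
                        b, e = parent[b][0], parent[b][1]
                        cycle.append(e)
                    while a != b:
                        pa, ea = parent[a]
                        pb, eb = parent[b]
                        cycle.append(ea)
                        cycle.append(eb)
                        a, b = pa, pb
                    return [pcs[i] for i in cycle]
    return None


def extend_by_synthetic_cycles(
    system: ConstraintSystem,
    gstar: ConstraintGraph,
    global_edges: list[int],
) -> list[int]:
    """Iteratively synthesise cycle constraints for global non-tree edges
    that lack one; returns the edges that remain unsynthesised.

    Local non-tree edges are never attempted (their locus-graph appearances
    cannot contribute new tree constraints).  Each success converts all of
    the edge's path constraints to tree constraints, updates G* and re-runs
    the W-assignment; the outer loop repeats because a merge may enable a
    later synthesis.  Terminates in at most |E^S| passes.
    """
    pending = [eid for eid in sorted(global_edges) if eid not in system.cycle]
    changed = True
    while pending and changed:
        changed = False
        for eid in list(pending):
            pcs = system.paths_of_edge(eid)
            if not pcs:
                pending.remove(eid)
                changed = True
                continue
            s_e = _find_odd_cycle(pcs, gstar.frame)
            if s_e is None:
                continue
            b_hat_expr = ZERO
            for pc in s_e:
                b_hat_expr = gf2_add(
                    b_hat_expr,
                    gf2_add(gf2_add(gstar.W[pc.a], gstar.W[pc.b_node]), GF2Expr(pc.b)),
                )
            if not b_hat_expr.is_constant:  # pragma: no cover - free vars only exist later
                raise AssertionError("synthetic cycle value must be constant")
            b_hat = b_hat_expr.constant
            add_constraint(system, CycleConstraint(eid, b_hat, locus=-1))
            for pc in system.paths_of_edge(eid):
                del system.path[pc.key]
                tc = TreeConstraint(pc.a, pc.b_node, b_hat ^ pc.b, pc.locus)
                if add_constraint(system, tc) == "added":
                    gstar.add_edge(tc.a, tc.b_node, GF2Expr(tc.b), "tree")
            gstar.recompute()
            pending.remove(eid)
            changed = True
    return pending
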
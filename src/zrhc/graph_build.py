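"""Preprocessing: pedigree graph, spanning tree, locus graphs.

The pedigree is turned into an undirected graph with one edge per
parent-child pair.  A deterministic depth-first spanning tree is built per
connected component; each non-tree edge closes exactly one fundamental cycle
and is classified as *local* (a couple and two of their common children, a
length-4 cycle) or *global* (a mating loop).  Per locus we keep the
heterozygosity indicator ``w`` of every node, the locus-graph edge set
(edges whose parent endpoint is heterozygous), the per-edge constant ``d``
(0 on father-child edges, the child's ``w`` on mother-child edges), and the
predetermined paternal alleles forced by homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree_io import GenotypeMatrix, Pedigree

__all__ = [
    "PedEdge",
    "PedigreeGraph",
    "SpanningTree",
    "LocusData",
    "build_graph",
    "build_spanning_tree",
    "classify_nontree_edges",
    "build_locus_data",
]


@dataclass(frozen=True)
class PedEdge:
    parent: int
    child: int

    def other(self, node: int) -> int:
        return self.child if node == self.parent else self.parent


class PedigreeGraph:
    """Undirected parent-child graph; adjacency lists sorted by neighbor index."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.n = ped.n
        self.edges: list[PedEdge] = []
        self.adj: list[list[tuple[int, int]]] = [[] for _ in range(ped.n)]
        for j in range(ped.n):
            for parent in (ped.father[j], ped.mother[j]):
                if parent >= 0:
                    eid = len(self.edges)
                    self.edges.append(PedEdge(parent, j))
                    self.adj[parent].append((j, eid))
                    self.adj[j].append((parent, eid))
        for lst in self.adj:
            lst.sort()
        self.edge_index = {
            frozenset((e.parent, e.child)): i for i, e in enumerate(self.edges)
        }

    def edge_id(self, a: int, b: int) -> int:
        return self.edge_index[frozenset((a, b))]

    def edge_label(self, eid: int) -> str:
        e = self.edges[eid]
        return f"{self.ped.labels[e.parent]}-{self.ped.labels[e.child]}"


def build_graph(ped: Pedigree) -> PedigreeGraph:
    """One undirected edge per parent-child pair (at most 2n edges)."""
    return PedigreeGraph(ped)


class SpanningTree:
    """A rooted spanning forest of the pedigree graph.

    ``parent_node``/``parent_edge`` give the rooted structure (roots have
    -1); ``component`` assigns each node its connected-component id (the id
    is the smallest node index in the component, which is also its root).
    """

    def __init__(self, graph: PedigreeGraph, tree_edges: set[int]):
        self.graph = graph
        self.tree_edges = set(tree_edges)
        self.nontree_edges = [
            eid for eid in range(len(graph.edges)) if eid not in self.tree_edges
        ]
        n = graph.n
        self.parent_node = [-1] * n
        self.parent_edge = [-1] * n
        self.depth = [0] * n
        self.component = [-1] * n
        self.roots: list[int] = []
        tree_adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for eid in self.tree_edges:
            e = graph.edges[eid]
            tree_adj[e.parent].append((e.child, eid))
            tree_adj[e.child].append((e.parent, eid))
        for lst in tree_adj:
            lst.sort()
        self.tree_adj = tree_adj
        for start in range(n):
            if self.component[start] >= 0:
                continue
            self.roots.append(start)
            self.component[start] = start
            queue = [start]
            while queue:
                u = queue.pop()
                for v, eid in tree_adj[u]:
                    if self.component[v] < 0:
                        self.component[v] = start
                        self.parent_node[v] = u
                        self.parent_edge[v] = eid
                        self.depth[v] = self.depth[u] + 1
                        queue.append(v)
        # sanity: a spanning forest has n - #components tree edges and no cycles
        if len(self.tree_edges) != n - len(self.roots):
            raise ValueError("edge set does not form a spanning forest")

    @property
    def n_components(self) -> int:
        return len(self.roots)

    def tree_path(self, u: int, v: int) -> tuple[list[int], list[int]]:
        """Nodes and edge ids of the unique tree path from u to v (inclusive)."""
        if self.component[u] != self.component[v]:
            raise ValueError("nodes lie in different components")
        up_u: list[tuple[int, int]] = []
        up_v: list[tuple[int, int]] = []
        a, b = u, v
        while self.depth[a] > self.depth[b]:
            up_u.append((a, self.parent_edge[a]))
            a = self.parent_node[a]
        while self.depth[b] > self.depth[a]:
            up_v.append((b, self.parent_edge[b]))
            b = self.parent_node[b]
        while a != b:
            up_u.append((a, self.parent_edge[a]))
            a = self.parent_node[a]
            up_v.append((b, self.parent_edge[b]))
            b = self.parent_node[b]
        nodes = [x for x, _ in up_u] + [a] + [x for x, _ in reversed(up_v)]
        edges = [e for _, e in up_u] + [e for _, e in reversed(up_v)]
        return nodes, edges

    def fundamental_cycle(self, eid: int) -> tuple[list[int], list[int]]:
        """Cycle closed by non-tree edge ``eid``: node sequence u..v and its
        edges (tree-path edges then ``eid`` itself, closing v back to u)."""
        e = self.graph.edges[eid]
        nodes, edges = self.tree_path(e.parent, e.child)
        return nodes, edges + [eid]

    @classmethod
    def from_tree_edges(cls, graph: PedigreeGraph, tree_edges: set[int]) -> "SpanningTree":
        """Build from an explicitly chosen tree-edge set (validated)."""
        return cls(graph, tree_edges)


def build_spanning_tree(graph: PedigreeGraph) -> SpanningTree:
    """Depth-first spanning tree, rooted at the smallest node index of each
    component, visiting neighbors in ascending index order (deterministic)."""
    n = graph.n
    visited = [False] * n
    tree_edges: set[int] = set()
    for start in range(n):
        if visited[start]:
            continue
        visited[start] = True
        stack = [(start, iter(graph.adj[start]))]
        while stack:
            u, it = stack[-1]
            advanced = False
            for v, eid in it:
                if not visited[v]:
                    visited[v] = True
                    tree_edges.add(eid)
                    stack.append((v, iter(graph.adj[v])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
    return SpanningTree(graph, tree_edges)


def _is_local_cycle(graph: PedigreeGraph, nodes: list[int], edges: list[int]) -> bool:
    """Length-4 cycle made of a couple and two of their common children."""
    if len(nodes) != 4:
        return False
    parents = {graph.edges[e].parent for e in edges}
    children = {graph.edges[e].child for e in edges}
    if len(parents) != 2 or len(children) != 2 or parents & children:
        return False
    return all(
        frozenset((p, c)) in graph.edge_index
        and graph.edges[graph.edge_index[frozenset((p, c))]].parent == p
        for p in parents
        for c in children
    )


def classify_nontree_edges(
    tree: SpanningTree,
) -> tuple[list[int], list[int], dict[int, tuple[list[int], list[int]]]]:
    """Split non-tree edges into local (sibling cycles) and global (mating
    loops); returns (local ids, global ids, fundamental cycles by edge id)."""
    local: list[int] = []
    global_: list[int] = []
    cycles: dict[int, tuple[list[int], list[int]]] = {}
    for eid in tree.nontree_edges:
        nodes, edges = tree.fundamental_cycle(eid)
        cycles[eid] = (nodes, edges)
        if _is_local_cycle(tree.graph, nodes, edges):
            local.append(eid)
        else:
            global_.append(eid)
    return local, global_, cycles


_ALLELES = {0: (0,), 1: (1,), 2: (0, 1)}


def _mendel_ok(gf: int, gm: int, gc: int) -> bool:
    """Can the child's allele pair be split into one paternal, one maternal?"""
    fa, ma = _ALLELES[gf], _ALLELES[gm]
    if gc == 2:
        return (0 in fa and 1 in ma) or (1 in fa and 0 in ma)
    return gc in fa and gc in ma


@dataclass
class LocusData:
    """Per-locus constants: w per node, locus-graph membership and d per edge,
    predetermined flags and forced p-values, plus any Mendelian errors."""

    locus: int
    w: np.ndarray                 # (n,) heterozygosity indicator
    in_locus_graph: np.ndarray    # (#edges,) bool: parent endpoint heterozygous
    d: np.ndarray                 # (#edges,) GF(2) constant
    predetermined: np.ndarray     # (n,) bool
    p0: np.ndarray                # (n,) forced paternal allele, -1 if free
    mendel_errors: list[str] = field(default_factory=list)


def build_locus_data(graph: PedigreeGraph, geno: GenotypeMatrix, l: int) -> LocusData:
    """Compute w/d constants, locus-graph membership and predetermined
    p-values at locus ``l``; records single-locus Mendelian violations."""
    ped = graph.ped
    n = graph.n
    g = geno.g[:, l]
    w = (g == 2).astype(np.int8)
    in_el = np.zeros(len(graph.edges), dtype=bool)
    d = np.zeros(len(graph.edges), dtype=np.int8)
    for eid, e in enumerate(graph.edges):
        in_el[eid] = w[e.parent] == 1
        if ped.mother[e.child] == e.parent:
            d[eid] = w[e.child]
    predet = np.zeros(n, dtype=bool)
    p0 = np.full(n, -1, dtype=np.int8)
    errors: list[str] = []
    for j in range(n):
        fa, mo = ped.father[j], ped.mother[j]
        if g[j] != 2:
            predet[j] = True
            p0[j] = g[j]
        elif fa >= 0 and g[fa] != 2:
            predet[j] = True
            p0[j] = g[fa]
        elif mo >= 0 and g[mo] != 2:
            # heterozygous child: paternal allele is the complement of the
            # maternal one the homozygous mother necessarily transmitted
            predet[j] = True
            p0[j] = 1 - g[mo]
        if fa >= 0 and not _mendel_ok(int(g[fa]), int(g[mo]), int(g[j])):
            errors.append(
                f"Mendelian violation at locus {l + 1} for individual "
                f"{ped.labels[j]} (father {ped.labels[fa]} g={g[fa]}, "
                f"mother {ped.labels[mo]} g={g[mo]}, child g={g[j]})"
            )
    return LocusData(l, w, in_el, d, predet, p0, errors)
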
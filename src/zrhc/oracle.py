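"""Exhaustive reference solver for tiny pedigrees.

Independent cross-check for the constraint-graph solver: it enumerates every
assignment of per-edge transmission bits outright and, for each, solves
every locus by plain breadth-first substitution -- no spanning tree, no
constraint sets, no symbolic algebra.  Exponential in the number of edges,
so only usable for toy problem sizes, which is exactly its job.

The founder-phase convention matches the solver's output convention: the
transmission bit from a founder to its smallest tree-child is pinned to 0
(equivalently, founder haplotype pairs are reported transmitted-first).
"""

from __future__ import annotations

import itertools

import numpy as np

from .graph_build import build_graph, build_spanning_tree
from .pedigree_io import GenotypeMatrix, Pedigree

__all__ = ["enumerate_valid_configurations", "is_consistent"]


def _conventional_zero_edges(ped: Pedigree) -> set[int]:
    """Edge ids whose transmission bit the phasing convention pins to 0."""
    graph = build_graph(ped)
    tree = build_spanning_tree(graph)
    fixed: set[int] = set()
    for f in ped.founders:
        children = [c for c, _ in tree.tree_adj[f]]
        if children:
            fixed.add(graph.edge_id(f, min(children)))
    return fixed


def _locus_solutions(
    ped: Pedigree, g: np.ndarray, h: list[int], graph
) -> list[np.ndarray] | None:
    """All paternal-allele vectors at one locus given fixed transmission
    bits, or None if the locus is unsatisfiable under them."""
    n = ped.n
    w = (g == 2).astype(np.int8)
    p = np.full(n, -1, dtype=np.int8)
    comps: list[list[int]] = []
    seen = [False] * n
    for start in range(n):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        stack = [start]
        while stack:
            x = stack.pop()
            for y, eid in graph.adj[x]:
                if not seen[y]:
                    seen[y] = True
                    comp.append(y)
                    stack.append(y)
        comps.append(sorted(comp))

    def offset(x: int, y: int, eid: int) -> int:
        # p_x and p_y differ by this constant along edge eid
        e = graph.edges[eid]
        parent, child = e.parent, e.child
        # child paternal = father hap bit; child maternal = mother hap bit
        if ped.father[child] == parent:
            return int(w[parent]) & h[eid]
        return (int(w[parent]) & h[eid]) ^ int(w[child])

    solutions_per_comp: list[list[np.ndarray]] = []
    for comp in comps:
        fixed = [x for x in comp if g[x] != 2]
        vals = np.full(n, -1, dtype=np.int8)
        choices: list[np.ndarray] = []
        for anchor_bit in (0, 1):
            vals[:] = -1
            root = comp[0]
            vals[root] = g[root] if g[root] != 2 else anchor_bit
            ok = True
            stack = [root]
            while stack and ok:
                x = stack.pop()
                for y, eid in graph.adj[x]:
                    v = vals[x] ^ offset(x, y, eid)
                    if vals[y] < 0:
                        vals[y] = v
                        stack.append(y)
                    elif vals[y] != v:
                        ok = False
                        break
            if ok:
                for x in fixed:
                    if vals[x] != g[x]:
                        ok = False
                        break
            if ok:
                choices.append(vals[comp].copy())
            if g[root] != 2:
                break  # root fixed: the anchor loop is moot
        if not choices:
            return None
        # deduplicate (both anchors can yield the same vector only if comp is empty)
        solutions_per_comp.append(choices)

    out: list[np.ndarray] = []
    for pick in itertools.product(*solutions_per_comp):
        vec = np.zeros(n, dtype=np.int8)
        for comp, vals in zip(comps, pick):
            vec[comp] = vals
        out.append(vec)
    return out


def enumerate_valid_configurations(
    ped: Pedigree,
    geno: GenotypeMatrix,
    convention: bool = True,
    max_edges: int = 18,
) -> set[bytes]:
    """Every zero-recombinant paternal-allele matrix, as row-major bytes.

    ``convention`` restricts to configurations obeying the founder-phase
    normalization; without it the full (founder-swap-redundant) set is
    returned.
    """
    graph = build_graph(ped)
    n_edges = len(graph.edges)
    fixed = _conventional_zero_edges(ped) if convention else set()
    free = [e for e in range(n_edges) if e not in fixed]
    if len(free) > max_edges:
        raise ValueError(f"{len(free)} free transmission bits exceed cap {max_edges}")
    out: set[bytes] = set()
    m = geno.m
    for bits in itertools.product((0, 1), repeat=len(free)):
        h = [0] * n_edges
        for e, b in zip(free, bits):
            h[e] = b
        per_locus: list[list[np.ndarray]] = []
        feasible = True
        for l in range(m):
            sols = _locus_solutions(ped, geno.g[:, l], h, graph)
            if sols is None:
                feasible = False
                break
            per_locus.append(sols)
        if not feasible:
            continue
        for pick in itertools.product(*per_locus):
            out.add(np.stack(pick, axis=1).astype(np.int8).tobytes())
    return out


def is_consistent(ped: Pedigree, geno: GenotypeMatrix, max_edges: int = 18) -> bool:
    """True iff at least one zero-recombinant configuration exists."""
    graph = build_graph(ped)
    n_edges = len(graph.edges)
    fixed = _conventional_zero_edges(ped)
    free = [e for e in range(n_edges) if e not in fixed]
    if len(free) > max_edges:
        raise ValueError(f"{len(free)} free transmission bits exceed cap {max_edges}")
    for bits in itertools.product((0, 1), repeat=len(free)):
        h = [0] * n_edges
        for e, b in zip(free, bits):
            h[e] = b
        if all(
            _locus_solutions(ped, geno.g[:, l], h, graph) is not None
            for l in range(geno.m)
        ):
            return True
    return False
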
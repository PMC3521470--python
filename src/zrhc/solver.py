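"""Haplotype determination (Step 4) and the end-to-end pipeline.

After constraint reduction the constraint graph G* may still be
disconnected.  Founders -- necessarily isolated in G* -- are attached to
their smallest tree-child with weight 0, which fixes the per-founder phase
convention "the haplotype transmitted to that child is listed first".
Remaining path constraints whose endpoints pair up inside W-frames determine
the h-value of their non-tree edge and *link* the two frames' connectivity
(without imposing a W-relation between them, which would amount to an
unobserved cycle constraint).  Whatever connectivity components remain are
joined by a star of free W-edges, each weighted with a fresh linker
variable.  Tree edges inside a W-frame then get h = W[i] + W[j]; per locus,
paternal alleles propagate from predetermined nodes through known-h
locus-graph edges, with fresh anchor variables realising the genuinely free
phase of all-heterozygous regions.  A final audit re-checks the inheritance
identity on every edge and locus.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .constraint_gen import ConstraintSystem, generate_all
from .constraint_reduce import (
    ConstraintGraph,
    build_constraint_graph,
    extend_by_synthetic_cycles,
    transform_type1,
)
from .gf2_core import ZERO, FreeVarRegistry, GF2Expr, gf2_add, gf2_eval, gf2_scale, var
from .graph_build import (
    LocusData,
    PedigreeGraph,
    SpanningTree,
    build_graph,
    build_locus_data,
    build_spanning_tree,
    classify_nontree_edges,
)
from .pedigree_io import GenotypeMatrix, Pedigree

__all__ = [
    "LinkForest",
    "HSolution",
    "SolutionFamily",
    "attach_founders",
    "link_by_path_constraints",
    "connect_free",
    "extract_h",
    "propagate_p",
    "verify_family",
    "enumerate_solutions",
    "solve_h",
    "phase",
]


class LinkForest:
    """Union-find tracking which W-frames are connected.

    Free W-edges merge frames *with* a W-relation; non-tree links merge
    connectivity *without* one (the two frames keep independent W origins).
    """

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller index as representative (determinism)
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def attach_founders(gstar: ConstraintGraph, tree: SpanningTree) -> list[tuple[int, int]]:
    """Attach each founder to its smallest-index tree-child with a weight-0
    G*-edge (declares h(founder, child) = 0); returns the edges added.

    Founders cannot be endpoints of path or tree constraints, so they are
    singleton frames; a non-singleton founder frame (possible only on
    hand-built constraint systems) is left alone.
    """
    ped = tree.graph.ped
    added: list[tuple[int, int]] = []
    for f in sorted(ped.founders):
        if gstar.frame[f] != f or any(gstar.frame[v] == f for v in range(gstar.n) if v != f):
            continue  # not a singleton frame: skip rather than over-constrain
        children = [c for c, _eid in tree.tree_adj[f]]
        if not children:
            continue  # childless individual stays a singleton frame
        c = min(children)
        gstar.add_edge(f, c, ZERO, "founder")
        added.append((f, c))
    if added:
        gstar.recompute()
    return added


@dataclass
class LinkRecord:
    edge: int          # pedigree non-tree edge id
    h: GF2Expr
    frames: tuple[int, int]


def link_by_path_constraints(
    gstar: ConstraintGraph,
    system: ConstraintSystem,
    graph: PedigreeGraph,
    forest: LinkForest,
) -> tuple[dict[int, GF2Expr], list[str]]:
    """Determine h-values of non-tree edges from leftover path constraints.

    A constraint (k, l, b, e=(i,j)) applies when k pairs with i inside one
    W-frame and l with j inside another (or the same): the tree sub-paths
    contribute W[k]+W[i] and W[j]+W[l], so h_e = b + W[k]+W[i]+W[j]+W[l].
    Distinct frames are merged in connectivity only.  Re-determinations of
    the same edge must agree.
    """
    links: dict[int, GF2Expr] = {}
    conflicts: list[str] = []
    changed = True
    while changed:
        changed = False
        for key in sorted(system.path):
            pc = system.path[key]
            ni, nj = pc.a_side, pc.b_side
            if gstar.frame[pc.a] != gstar.frame[ni] or gstar.frame[pc.b_node] != gstar.frame[nj]:
                continue
            h = GF2Expr(pc.b)
            for node in (pc.a, ni, nj, pc.b_node):
                h = gf2_add(h, gstar.W[node])
            if pc.edge in links:
                if links[pc.edge] != h:
                    msg = (
                        f"conflicting h determinations for edge "
                        f"{graph.edge_label(pc.edge)}: {links[pc.edge]} vs {h}"
                    )
                    if msg not in conflicts:
                        conflicts.append(msg)
                continue
            links[pc.edge] = h
            forest.union(ni, nj)
            changed = True
    return links, conflicts


def connect_free(
    gstar: ConstraintGraph,
    tree: SpanningTree,
    forest: LinkForest,
    registry: FreeVarRegistry,
) -> list[tuple[int, int, int]]:
    """Join the remaining connectivity components of each pedigree component
    with a star of free W-edges weighted by fresh linker variables.

    The star is centred on the component containing the smallest node index;
    edges join W-frame seeds.  Frames already joined by a non-tree link get
    no free edge.  Returns (seed_a, seed_b, var id) triples.
    """
    ped = tree.graph.ped
    # connectivity roots must reflect W-frames too
    for v in range(gstar.n):
        forest.union(v, gstar.frame[v])
    added: list[tuple[int, int, int]] = []
    by_component: dict[int, dict[int, int]] = {}
    for v in range(gstar.n):
        comp = tree.component[v]
        root = forest.find(v)
        by_component.setdefault(comp, {})
        rep = by_component[comp].get(root)
        if rep is None or v < rep:
            by_component[comp][root] = v
    for comp in sorted(by_component):
        groups = sorted(by_component[comp].values())
        hub = groups[0]
        hub_seed = gstar.frame[hub]
        for v in groups[1:]:
            seed = gstar.frame[v]
            fid = registry.fresh(
                "linker",
                f"free W-edge between component seeds "
                f"{ped.labels[hub_seed]} and {ped.labels[seed]}",
            )
            gstar.add_edge(hub_seed, seed, var(fid), "free")
            forest.union(hub_seed, seed)
            added.append((hub_seed, seed, fid))
    if added:
        gstar.recompute()
    return added


def _substitute(expr: GF2Expr, v: int, repl: GF2Expr) -> GF2Expr:
    if v not in expr.vars:
        return expr
    rest = GF2Expr(expr.constant, tuple(x for x in expr.vars if x != v))
    return gf2_add(rest, repl)


class Eliminator:
    """Enforces linear relations among residual free variables.

    The constraint-graph machinery resolves almost everything, but leftover
    constraints occasionally determine a combination of the variables that
    were introduced as free (linkers, edge-h bits, anchors).  When two
    symbolic derivations of one quantity differ by a non-constant
    expression, that difference must be zero: the highest variable in it is
    solved for and substituted out of every registered container.  A
    constant-1 difference is a genuine inconsistency.
    """

    def __init__(self) -> None:
        self.solved: dict[int, GF2Expr] = {}
        self._targets: list = []

    def register(self, target) -> None:
        """Track a dict[?, GF2Expr] or (nested) list of GF2Expr for substitution."""
        self._targets.append(target)

    def _apply(self, v: int, repl: GF2Expr) -> None:
        def sub_list(lst) -> None:
            for i, x in enumerate(lst):
                if isinstance(x, list):
                    sub_list(x)
                elif x is not None:
                    lst[i] = _substitute(x, v, repl)

        for t in self._targets:
            if isinstance(t, dict):
                for k in t:
                    t[k] = _substitute(t[k], v, repl)
            else:
                sub_list(t)
        for k in list(self.solved):
            self.solved[k] = _substitute(self.solved[k], v, repl)

    def resolve(self, diff: GF2Expr) -> bool:
        """Enforce ``diff == 0``; False iff the difference is the constant 1."""
        if diff.is_constant:
            return diff.constant == 0
        v = max(diff.vars)
        repl = GF2Expr(diff.constant, tuple(x for x in diff.vars if x != v))
        self._apply(v, repl)
        self.solved[v] = repl
        return True


def assign_edge_h_vars(
    tree: SpanningTree,
    gstar: ConstraintGraph,
    h: dict[int, GF2Expr],
    registry: FreeVarRegistry,
) -> list[int]:
    """Give every tree edge still lacking an h-expression a fresh free
    variable (the inheritance bit nothing so far constrains); leftover
    constraints may later solve these via elimination."""
    graph = tree.graph
    added = []
    for eid in sorted(tree.tree_edges):
        if eid not in h:
            fid = registry.fresh("edge_h", f"inheritance bit of edge {graph.edge_label(eid)}")
            h[eid] = var(fid)
            added.append(fid)
    return added


def consume_residual_constraints(
    system: ConstraintSystem,
    tree: SpanningTree,
    h: dict[int, GF2Expr],
    elim: Eliminator,
) -> list[str]:
    """Turn every leftover path and cycle constraint into an h-equation.

    With all tree edges symbolic, a path constraint (a, b, b_p, e) says the
    XOR of h along tree-path(a .. a-side endpoint of e), h_e, and tree-path
    (b-side endpoint .. b) equals b_p: it either determines h_e or -- if h_e
    is already known -- yields a relation resolved by elimination.  Cycle
    constraints of still-unknown non-tree edges define h_e the same way.
    Iterates to a fixpoint; returns real conflicts."""
    graph = tree.graph
    conflicts: list[str] = []

    def settle(eid: int, expr: GF2Expr) -> bool:
        old = h.get(eid)
        if old is None:
            h[eid] = expr
            return True
        if old == expr:
            return False
        if not elim.resolve(gf2_add(old, expr)):
            msg = (
                f"conflicting h determinations for edge "
                f"{graph.edge_label(eid)}: {old} vs {expr}"
            )
            if msg not in conflicts:
                conflicts.append(msg)
            return False  # no state change: the contradiction is only logged
        return True

    changed = True
    while changed:
        changed = False
        for key in sorted(system.path):
            pc = system.path[key]
            expr = GF2Expr(pc.b)
            for u, v in ((pc.a, pc.a_side), (pc.b_side, pc.b_node)):
                for e in tree.tree_path(u, v)[1]:
                    expr = gf2_add(expr, h[e])
            if settle(pc.edge, expr):
                changed = True
        for eid in sorted(system.cycle):
            cyc = system.cycle[eid]
            expr = GF2Expr(cyc.b)
            for e in tree.fundamental_cycle(eid)[1][:-1]:
                expr = gf2_add(expr, h[e])
            if settle(eid, expr):
                changed = True
    return conflicts


def extract_h(
    gstar: ConstraintGraph,
    tree: SpanningTree,
    links: dict[int, GF2Expr],
) -> dict[int, GF2Expr]:
    """h of every tree edge whose endpoints share a W-frame is W[i]+W[j];
    non-tree links carry their recorded expressions; the rest stay unknown."""
    h: dict[int, GF2Expr] = {}
    for eid in sorted(tree.tree_edges):
        e = tree.graph.edges[eid]
        if gstar.frame[e.parent] == gstar.frame[e.child]:
            h[eid] = gf2_add(gstar.W[e.parent], gstar.W[e.child])
    h.update(links)
    return h


def propagate_p(
    graph: PedigreeGraph,
    ld: LocusData,
    h: dict[int, GF2Expr],
    registry: FreeVarRegistry,
    elim: Eliminator | None = None,
) -> tuple[list[GF2Expr], list[str]]:
    """Determine every node's paternal-allele expression at one locus.

    Breadth-first from all predetermined nodes across locus-graph edges with
    known h (the inheritance identity is symmetric: the unknown endpoint is
    the known one plus h plus d).  Where two derivations meet they must
    agree: a non-constant difference is a relation among residual free
    variables and is resolved by elimination; a constant-1 difference is a
    genotype inconsistency.  Nodes left unreachable get a fresh anchor
    variable at the smallest undetermined index, then propagation resumes.
    """
    ped = graph.ped
    n = graph.n
    if elim is None:
        elim = Eliminator()
        elim.register(h)
    p: list[GF2Expr | None] = [None] * n
    elim.register(p)
    conflicts: list[str] = []
    queue: deque[int] = deque()
    for j in range(n):
        if ld.predetermined[j]:
            p[j] = GF2Expr(int(ld.p0[j]))
            queue.append(j)

    def drain() -> None:
        while queue:
            x = queue.popleft()
            for y, eid in graph.adj[x]:
                if not ld.in_locus_graph[eid] or eid not in h:
                    continue
                expr = gf2_add(gf2_add(p[x], h[eid]), GF2Expr(int(ld.d[eid])))
                if p[y] is None:
                    p[y] = expr
                    queue.append(y)
                elif p[y] != expr and not elim.resolve(gf2_add(p[y], expr)):
                    msg = (
                        f"inconsistent paternal allele for {ped.labels[y]} at locus "
                        f"{ld.locus + 1}: {p[y]} vs {expr} via {graph.edge_label(eid)}"
                    )
                    if msg not in conflicts:
                        conflicts.append(msg)

    drain()
    while any(v is None for v in p):
        j = min(i for i in range(n) if p[i] is None)
        fid = registry.fresh(
            "anchor", f"phase of {ped.labels[j]} at locus {ld.locus + 1}"
        )
        p[j] = var(fid)
        queue.append(j)
        drain()
    return p, conflicts  # type: ignore[return-value]


@dataclass
class HSolution:
    """Outcome of the h-side of the algorithm (Steps 3-4a)."""

    graph: PedigreeGraph
    tree: SpanningTree
    system: ConstraintSystem
    gstar: ConstraintGraph
    registry: FreeVarRegistry
    h: dict[int, GF2Expr]
    links: dict[int, GF2Expr]
    founder_edges: list[tuple[int, int]]
    free_edges: list[tuple[int, int, int]]
    unsynthesised: list[int]
    conflicts: list[str]
    elim: Eliminator = field(default_factory=Eliminator)

    @property
    def eliminated(self) -> dict[int, GF2Expr]:
        return self.elim.solved

    @property
    def n_free_variables(self) -> int:
        return len(self.registry) - len(self.elim.solved)


def solve_h(
    graph: PedigreeGraph,
    tree: SpanningTree,
    system: ConstraintSystem,
    global_edges: list[int],
    registry: FreeVarRegistry | None = None,
) -> HSolution:
    """Steps 3-4a: reduce the constraint system and solve the h-values."""
    registry = registry if registry is not None else FreeVarRegistry()
    transform_type1(system)
    gstar = build_constraint_graph(system, graph.n)
    unsynth = extend_by_synthetic_cycles(system, gstar, global_edges)
    founder_edges = attach_founders(gstar, tree)
    forest = LinkForest(graph.n)
    links, link_conflicts = link_by_path_constraints(gstar, system, graph, forest)
    free_edges = connect_free(gstar, tree, forest, registry)
    h = extract_h(gstar, tree, links)
    assign_edge_h_vars(tree, gstar, h, registry)
    elim = Eliminator()
    elim.register(h)
    residual_conflicts = consume_residual_constraints(system, tree, h, elim)
    conflicts = (
        list(system.conflicts) + list(gstar.conflicts)
        + link_conflicts + residual_conflicts
    )
    return HSolution(
        graph, tree, system, gstar, registry, h, links,
        founder_edges, free_edges, unsynth, conflicts, elim,
    )


@dataclass
class SolutionFamily:
    """The general solution: symbolic h per edge and p per node and locus.

    ``status`` is ``consistent`` iff no checkpoint or audit found a
    conflict; the particular solution instantiates all free variables at 0.
    """

    graph: PedigreeGraph
    geno: GenotypeMatrix
    registry: FreeVarRegistry
    h: dict[int, GF2Expr]
    p: list[list[GF2Expr]] | None
    conflicts: list[str] = field(default_factory=list)
    unconstrained_edges: list[int] = field(default_factory=list)
    eliminated: dict[int, GF2Expr] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return self.graph.ped.labels

    @property
    def status(self) -> str:
        return "consistent" if not self.conflicts else "inconsistent"

    @property
    def n_free_variables(self) -> int:
        # variables the refinement pass solved for are no longer free
        return len(self.registry) - len(self.eliminated)

    def instantiate(self, assignment: dict[int, int]) -> np.ndarray:
        """Concrete paternal-allele matrix under a free-variable assignment."""
        if self.p is None:
            raise ValueError("family has no p-expressions")
        n, m = self.graph.n, self.geno.m
        out = np.zeros((n, m), dtype=np.int8)
        for j in range(n):
            for l in range(m):
                out[j, l] = gf2_eval(self.p[j][l], assignment)
        return out

    def particular_haplotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """(paternal, maternal) allele matrices with all free variables 0."""
        zeros = {i: 0 for i in range(len(self.registry))}
        pat = self.instantiate(zeros)
        het = (self.geno.g == 2).astype(np.int8)
        return pat, pat ^ het

    def report(self) -> dict:
        """JSON-serialisable general-solution report."""
        ped = self.graph.ped
        return {
            "status": self.status,
            "free_variables": [
                {"id": i, "kind": kind, "provenance": prov}
                for i, (kind, prov) in enumerate(self.registry)
                if i not in self.eliminated
            ],
            "h": {
                self.graph.edge_label(eid): str(self.h[eid])
                for eid in sorted(self.h)
            },
            "p": {
                ped.labels[j]: {
                    str(l + 1): str(self.p[j][l]) for l in range(self.geno.m)
                }
                for j in range(self.graph.n)
            } if self.p is not None else {},
            "unconstrained_edges": [
                self.graph.edge_label(e) for e in self.unconstrained_edges
            ],
            "conflicts": list(self.conflicts),
        }


def verify_family(
    family: SolutionFamily, locus_data: list[LocusData]
) -> str:
    """Post-hoc audit: the inheritance identity must hold symbolically on
    every known-h edge at every locus, and every unknown-h edge must imply
    one single h-expression across its heterozygous loci (this is the
    zero-recombination condition).  Appends findings to the family's
    conflict list and returns the resulting status."""
    graph = family.graph
    assert family.p is not None
    for eid, e in enumerate(graph.edges):
        derived: list[tuple[int, GF2Expr]] = []
        for ld in locus_data:
            pi = family.p[e.parent][ld.locus]
            pj = family.p[e.child][ld.locus]
            d = GF2Expr(int(ld.d[eid]))
            w = int(ld.w[e.parent])
            if eid in family.h:
                lhs = gf2_add(pi, gf2_scale(w, family.h[eid]))
                rhs = gf2_add(pj, d)
                if lhs != rhs:
                    family.conflicts.append(
                        f"inheritance identity fails on edge {graph.edge_label(eid)} "
                        f"at locus {ld.locus + 1}: {lhs} != {rhs}"
                    )
            elif w == 1:
                derived.append((ld.locus, gf2_add(gf2_add(pi, pj), d)))
        if eid not in family.h:
            if not derived:
                family.unconstrained_edges.append(eid)
            else:
                first_locus, first = derived[0]
                for locus, expr in derived[1:]:
                    if expr != first:
                        family.conflicts.append(
                            f"edge {graph.edge_label(eid)} would need different "
                            f"inheritance bits at loci {first_locus + 1} and "
                            f"{locus + 1}: {first} vs {expr}"
                        )
    return family.status


def enumerate_solutions(family: SolutionFamily, max_vars: int = 16) -> set[bytes]:
    """Every concrete paternal-allele matrix in the family, as row-major
    byte strings.  Refuses when more than ``max_vars`` free variables
    actually occur in the p-expressions."""
    if family.p is None:
        raise ValueError("family has no p-expressions")
    used = sorted({i for row in family.p for expr in row for i in expr.vars})
    if len(used) > max_vars:
        raise ValueError(
            f"{len(used)} free variables exceed the enumeration cap {max_vars}"
        )
    out: set[bytes] = set()
    for bits in itertools.product((0, 1), repeat=len(used)):
        assignment = dict(zip(used, bits))
        out.add(family.instantiate(assignment).tobytes())
    return out


@dataclass
class PhaseStats:
    n: int
    m: int
    n_edges: int
    k_global: int
    n_local: int
    n_cycle: int
    n_path: int
    n_tree: int
    n_frames_final: int
    n_free_variables: int = 0


def phase(
    ped: Pedigree,
    geno: GenotypeMatrix,
    tree: SpanningTree | None = None,
) -> tuple[SolutionFamily, PhaseStats]:
    """Run the full pipeline on one pedigree + genotype matrix.

    All consistency checkpoints (single-locus Mendelian screen, constraint
    generation, W-assignment, linking, propagation meets, final audit) feed
    the family's conflict list; the pipeline always runs to completion so
    `check` mode can report every finding.
    """
    graph = build_graph(ped)
    if tree is None:
        tree = build_spanning_tree(graph)
    local_e, global_e, _cycles = classify_nontree_edges(tree)
    locus_data = [build_locus_data(graph, geno, l) for l in range(geno.m)]
    mendel = [msg for ld in locus_data for msg in ld.mendel_errors]
    system = generate_all(tree, locus_data)
    n_cycle, n_path, n_tree = len(system.cycle), len(system.path), len(system.tree)
    hsol = solve_h(graph, tree, system, global_e)
    p_cols: list[list[GF2Expr]] = []
    prop_conflicts: list[str] = []
    for ld in locus_data:
        # one shared elimination context: a relation discovered at one locus
        # (through a shared h-variable) also rewrites the other loci's
        # expressions (propagate_p registers its result list with it)
        p_l, conf = propagate_p(graph, ld, hsol.h, hsol.registry, elim=hsol.elim)
        prop_conflicts.extend(conf)
        p_cols.append(p_l)
    p_rows = [[p_cols[l][j] for l in range(geno.m)] for j in range(graph.n)]
    family = SolutionFamily(
        graph, geno, hsol.registry, hsol.h, p_rows,
        conflicts=mendel + hsol.conflicts + prop_conflicts,
        eliminated=hsol.eliminated,
    )
    verify_family(family, locus_data)
    stats = PhaseStats(
        n=graph.n, m=geno.m, n_edges=len(graph.edges), k_global=len(global_e),
        n_local=len(local_e), n_cycle=n_cycle, n_path=n_path, n_tree=n_tree,
        n_frames_final=len(set(hsol.gstar.frame)),
        n_free_variables=len(hsol.registry),
    )
    return family, stats
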
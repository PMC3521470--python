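"""A bundled worked example: a 19-member pedigree with one mating loop.

Eight founders, three sibling (local) cycles and one global cycle through a
consanguineous union.  The spanning tree is pinned explicitly (non-tree
edges A-H, E-L, Q-R, B-F) and the constraint sets over four loci are given
at the constraint level, so the reduction and haplotype-determination steps
can be exercised and inspected without genotype data: Type-1 folding yields
the tree constraints (R,Q,0) and (I,H,0); the three path constraints of
B-F link three W-frames (seeded at H, G and Q) into a synthetic cycle with
value 0; after founder attachment a single free variable parameterises the
whole solution family.
"""

from __future__ import annotations

from .constraint_gen import (
    ConstraintSystem,
    CycleConstraint,
    PathConstraint,
    TreeConstraint,
    add_constraint,
)
from .graph_build import PedigreeGraph, SpanningTree, build_graph
from .pedigree_io import Pedigree
from .solver import HSolution, solve_h

__all__ = [
    "loop_pedigree",
    "loop_pedigree_graph",
    "pinned_spanning_tree",
    "printed_constraint_system",
    "solve_worked_example",
]

# (iid, father, mother, sex); founders A-E, J, M, P
_MEMBERS = [
    ("A", "0", "0", 2),
    ("B", "0", "0", 1),
    ("C", "0", "0", 2),
    ("D", "0", "0", 1),
    ("E", "0", "0", 2),
    ("F", "B", "C", 1),
    ("G", "D", "C", 2),
    ("H", "B", "A", 1),
    ("I", "B", "A", 2),
    ("J", "0", "0", 1),
    ("K", "D", "E", 1),
    ("L", "D", "E", 1),
    ("M", "0", "0", 2),
    ("N", "J", "I", 1),
    ("O", "L", "M", 2),
    ("P", "0", "0", 1),
    ("Q", "N", "O", 2),
    ("R", "P", "Q", 1),
    ("S", "P", "Q", 2),
]

_NONTREE = [("A", "H"), ("B", "F"), ("E", "L"), ("Q", "R")]


def loop_pedigree() -> Pedigree:
    """The 19-member pedigree (couples (B,A), (B,C), (C,D), (D,E), (J,I),
    (L,M), (N,O), (P,Q); the (N,O) union closes the mating loop)."""
    return Pedigree.from_rows([("FAM1", iid, f, m, s) for iid, f, m, s in _MEMBERS])


def loop_pedigree_graph() -> PedigreeGraph:
    return build_graph(loop_pedigree())


def pinned_spanning_tree(graph: PedigreeGraph) -> SpanningTree:
    """The spanning tree used throughout the worked example (chosen so the
    non-tree edges are A-H, B-F, E-L and Q-R)."""
    ped = graph.ped
    idx = {lab: i for i, lab in enumerate(ped.labels)}
    nontree = {graph.edge_id(idx[a], idx[b]) for a, b in _NONTREE}
    tree_edges = set(range(len(graph.edges))) - nontree
    return SpanningTree.from_tree_edges(graph, tree_edges)


def printed_constraint_system(graph: PedigreeGraph) -> ConstraintSystem:
    """The constraint sets the four locus graphs of the example generate:
    three cycle constraints, five path constraints (with their side-maps)
    and five tree constraints, all with value 0."""
    idx = {lab: i for i, lab in enumerate(graph.ped.labels)}
    e = lambda a, b: graph.edge_id(idx[a], idx[b])
    system = ConstraintSystem()
    for a, b in (("E", "L"), ("Q", "R"), ("A", "H")):
        add_constraint(system, CycleConstraint(e(a, b), 0))
    path_specs = [
        # (endpoint a, endpoint b, edge, a-side endpoint of edge, b-side)
        ("I", "H", ("A", "H"), "A", "H"),
        ("N", "G", ("B", "F"), "B", "F"),
        ("G", "Q", ("B", "F"), "F", "B"),
        ("R", "Q", ("Q", "R"), "R", "Q"),
        ("N", "Q", ("B", "F"), "B", "F"),
    ]
    for a, b, (eu, ev), sa, sb in path_specs:
        add_constraint(
            system,
            PathConstraint(idx[a], idx[b], 0, e(eu, ev), idx[sa], idx[sb]),
        )
    for a, b in (("I", "N"), ("G", "K"), ("G", "L"), ("G", "O"), ("Q", "S")):
        add_constraint(system, TreeConstraint(idx[a], idx[b], 0))
    return system


def solve_worked_example() -> HSolution:
    """Run Steps 3-4a on the bundled constraint sets."""
    graph = loop_pedigree_graph()
    tree = pinned_spanning_tree(graph)
    system = printed_constraint_system(graph)
    idx = {lab: i for i, lab in enumerate(graph.ped.labels)}
    global_edges = [graph.edge_id(idx["B"], idx["F"])]
    return solve_h(graph, tree, system, global_edges)
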
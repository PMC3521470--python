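"""Pedigree graph, spanning tree, cycle classification, locus constants."""

import pytest

from zrhc.graph_build import (
    build_graph,
    build_locus_data,
    build_spanning_tree,
    classify_nontree_edges,
)
from zrhc.examples import loop_pedigree, loop_pedigree_graph, pinned_spanning_tree
from conftest import genotypes, make_pedigree


def test_trio_graph(trio):
    g = build_graph(trio)
    assert len(g.edges) == 2
    tree = build_spanning_tree(g)
    assert tree.nontree_edges == []


def test_local_cycle_couple_two_children(nuclear2):
    g = build_graph(nuclear2)
    assert len(g.edges) == 4
    tree = build_spanning_tree(g)
    assert len(tree.nontree_edges) == 1  # |E| - |V| + 1
    local, global_, cycles = classify_nontree_edges(tree)
    assert len(local) == 1 and not global_
    nodes, edges = cycles[local[0]]
    assert len(nodes) == 4 and len(edges) == 4


def test_three_children_two_local_cycles():
    ped = make_pedigree(
        [("1", "0", "0", 1), ("2", "0", "0", 2)]
        + [(str(i), "1", "2", 1) for i in (3, 4, 5)]
    )
    tree = build_spanning_tree(build_graph(ped))
    local, global_, _ = classify_nontree_edges(tree)
    assert len(local) == 2 and not global_


def test_mating_loop_gives_global_cycle():
    # grandcouple, two married-out children, grandchildren who intermarry
    ped = make_pedigree(
        [
            ("1", "0", "0", 1), ("2", "0", "0", 2),
            ("3", "1", "2", 1), ("4", "1", "2", 2),
            ("5", "0", "0", 2), ("6", "0", "0", 1),
            ("7", "3", "5", 1), ("8", "6", "4", 2),
            ("9", "7", "8", 1),
        ]
    )
    tree = build_spanning_tree(build_graph(ped))
    local, global_, cycles = classify_nontree_edges(tree)
    assert len(global_) == 1 and len(local) == 1  # sibling square + mating loop
    assert len(cycles[global_[0]][0]) == 6  # loop through the common ancestor


def test_spanning_tree_deterministic():
    g1 = loop_pedigree_graph()
    g2 = loop_pedigree_graph()
    assert build_spanning_tree(g1).tree_edges == build_spanning_tree(g2).tree_edges


def test_pinned_tree_classification():
    graph = loop_pedigree_graph()
    tree = pinned_spanning_tree(graph)
    idx = {lab: i for i, lab in enumerate(graph.ped.labels)}
    local, global_, cycles = classify_nontree_edges(tree)
    lab = graph.edge_label
    assert sorted(lab(e) for e in local) == ["A-H", "E-L", "Q-R"]
    assert [lab(e) for e in global_] == ["B-F"]
    # the A-H fundamental cycle is the sibling square A-H-B-I
    nodes, _ = cycles[graph.edge_id(idx["A"], idx["H"])]
    assert sorted(graph.ped.labels[x] for x in nodes) == ["A", "B", "H", "I"]
    assert len(cycles[graph.edge_id(idx["B"], idx["F"])][0]) == 10


def test_forest_edge_count_matches_components():
    ped = loop_pedigree()
    g = build_graph(ped)
    tree = build_spanning_tree(g)
    assert len(tree.tree_edges) == g.n - tree.n_components


def test_locus_constants(trio):
    g = build_graph(trio)
    # father het, mother hom 1/1, child het
    ld = build_locus_data(g, genotypes([[2], [1], [2]]), 0)
    fe = g.edge_id(0, 2)  # father-child
    me = g.edge_id(1, 2)  # mother-child
    assert ld.d[fe] == 0
    assert ld.d[me] == 1  # mother edge, het child
    assert ld.in_locus_graph[fe] and not ld.in_locus_graph[me]
    # het child with homozygous 1/1 mother: paternal allele is the complement
    assert ld.predetermined[2] and ld.p0[2] == 0
    assert not ld.mendel_errors


@pytest.mark.parametrize(
    "codes, n_errors",
    [
        ([[0], [0], [1]], 1),   # both parents 0/0, child 1/1
        ([[0], [0], [2]], 1),   # both parents 0/0, het child
        ([[0], [2], [1]], 1),   # father 0/0, child 1/1
        ([[2], [2], [0]], 0),   # both het: anything goes
    ],
)
def test_mendel_screen(trio, codes, n_errors):
    ld = build_locus_data(build_graph(trio), genotypes(codes), 0)
    assert len(ld.mendel_errors) == n_errors
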
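"""Cycle, path and tree constraint generation with dedup and conflicts."""

from zrhc.constraint_gen import (
    ConstraintSystem,
    CycleConstraint,
    PathConstraint,
    TreeConstraint,
    add_constraint,
    gen_edge_constraints,
    gen_tree_constraints,
    generate_all,
)
from zrhc.graph_build import build_graph, build_locus_data, build_spanning_tree
from conftest import genotypes, make_pedigree


def build(ped, codes, locus=0):
    g = build_graph(ped)
    tree = build_spanning_tree(g)
    ld = build_locus_data(g, genotypes(codes), locus)
    return g, tree, ld


def test_cycle_constraint_is_d_sum(nuclear2):
    # both parents and both children heterozygous: the sibling cycle survives
    # in the locus graph; d-constants are 0,0 (father edges) and 1,1 (mother
    # edges of het children), so the cycle constraint is 0+1+1+0 = 0
    g, tree, ld = build(nuclear2, [[2], [2], [2], [2]])
    (eid,) = tree.nontree_edges
    (c,) = gen_edge_constraints(tree, ld, eid)
    assert isinstance(c, CycleConstraint)
    assert c.b == 0
    assert sum(int(ld.d[e]) for e in tree.fundamental_cycle(eid)[1]) % 2 == 0


def test_edge_not_in_locus_graph_yields_nothing(nuclear2):
    # non-tree edge's parent endpoint homozygous: no constraint at this locus
    g, tree, ld = build(nuclear2, [[0], [2], [2], [2]])
    (eid,) = tree.nontree_edges
    assert g.edges[eid].parent == 0 and not ld.in_locus_graph[eid]
    assert gen_edge_constraints(tree, ld, eid) == []


def test_path_constraint_value_and_sides(nuclear2):
    # father het, mother hom: the sibling cycle is broken at the mother; the
    # path c1-father-c2 has predetermined children (mother homozygous) and
    # value p(c1) + p(c2) + d-sum, evaluated by hand
    g, tree, ld = build(nuclear2, [[2], [1], [2], [2]])
    (eid,) = tree.nontree_edges
    assert ld.in_locus_graph[eid]
    (c,) = gen_edge_constraints(tree, ld, eid)
    assert isinstance(c, PathConstraint)
    assert {c.a, c.b_node} == {2, 3}
    # both children het with hom 1/1 mother: p = 0 each; d = 0 on the two
    # father edges of the path
    assert c.b == 0


def test_tree_constraints_need_two_predetermined(trio):
    # everyone heterozygous: no predetermined node, no tree constraints
    g, tree, ld = build(trio, [[2], [2], [2]])
    assert gen_tree_constraints(tree, ld) == []
    # exactly one predetermined node: still nothing
    g, tree, ld = build(trio, [[2], [2], [0]])
    assert gen_tree_constraints(tree, ld) == []


def test_tree_constraint_chain_value():
    # three-generation maternal chain 4 - 5 - 7 whose ends are predetermined
    # (p = 0 via homozygous fathers) and whose middle node is not; both
    # mother-child edges carry d = 1, so b_t = 0 + 0 + 1 + 1 = 0
    ped = make_pedigree(
        [
            ("1", "0", "0", 1), ("2", "0", "0", 2),   # g1 hom father, g2 het mother
            ("3", "0", "0", 1),                        # het spouse of 4
            ("4", "1", "2", 2),                        # het, predetermined via 1
            ("5", "3", "4", 2),                        # het, both parents het
            ("6", "0", "0", 1),                        # hom spouse of 5
            ("7", "6", "5", 2),                        # het, predetermined via 6
        ]
    )
    g, tree, ld = build(ped, [[0], [2], [2], [2], [2], [0], [2]])
    assert ld.predetermined[[3, 6]].all() and not ld.predetermined[4]
    out = gen_tree_constraints(tree, ld)
    keyed = {c.key: c.b for c in out}
    assert keyed[(3, 6)] == 0


def test_add_constraint_dedup_and_conflict():
    system = ConstraintSystem()
    t1 = TreeConstraint(1, 2, 0, locus=0)
    assert add_constraint(system, t1) == "added"
    assert add_constraint(system, TreeConstraint(1, 2, 0, locus=1)) == "duplicate"
    # symmetric endpoints are the same key
    assert add_constraint(system, TreeConstraint(2, 1, 0, locus=2)) == "duplicate"
    assert add_constraint(system, TreeConstraint(2, 1, 1, locus=3)) == "conflict"
    assert len(system.conflicts) == 1
    assert add_constraint(system, CycleConstraint(7, 0)) == "added"
    assert add_constraint(system, CycleConstraint(7, 1)) == "conflict"


def test_generate_all_counts_bounded(nuclear2):
    g = build_graph(nuclear2)
    tree = build_spanning_tree(g)
    lds = [build_locus_data(g, genotypes([[2, 2], [2, 1], [2, 2], [2, 2]]), l) for l in (0, 1)]
    system = generate_all(tree, lds)
    assert len(system.cycle) + len(system.path) <= len(tree.nontree_edges) * 2
    assert not system.conflicts
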
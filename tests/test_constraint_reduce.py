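"""Type-1 folding, constraint graph W-assignment, synthetic cycles."""

from zrhc.constraint_gen import (
    ConstraintSystem,
    CycleConstraint,
    PathConstraint,
    TreeConstraint,
    add_constraint,
)
from zrhc.constraint_reduce import (
    build_constraint_graph,
    extend_by_synthetic_cycles,
    transform_type1,
)
from zrhc.examples import (
    loop_pedigree_graph,
    pinned_spanning_tree,
    printed_constraint_system,
)
from zrhc.gf2_core import ZERO


def idx_of(graph):
    return {lab: i for i, lab in enumerate(graph.ped.labels)}


def test_type1_folds_paths_into_tree_constraints():
    graph = loop_pedigree_graph()
    system = printed_constraint_system(graph)
    idx = idx_of(graph)
    transform_type1(system)
    keys = set(system.tree)
    assert tuple(sorted((idx["R"], idx["Q"]))) in keys
    assert tuple(sorted((idx["I"], idx["H"]))) in keys
    assert system.tree[tuple(sorted((idx["R"], idx["Q"])))].b == 0
    # the three path constraints of the global edge survive
    assert len(system.path) == 3
    assert not system.conflicts


def test_type1_value_arithmetic():
    system = ConstraintSystem()
    add_constraint(system, CycleConstraint(5, 1))
    add_constraint(system, PathConstraint(1, 2, 1, 5, a_side=0, b_side=9))
    transform_type1(system)
    assert system.tree[(1, 2)].b == 0  # b_t = b_c + b_p over GF(2)
    assert not system.path


def test_constraint_graph_frames_and_seeds():
    graph = loop_pedigree_graph()
    system = printed_constraint_system(graph)
    idx = idx_of(graph)
    transform_type1(system)
    gstar = build_constraint_graph(system, graph.n)
    # components {H,I,N}, {G,K,L,O}, {Q,R,S} seeded at their smallest ids
    for members, seed in ((("H", "I", "N"), "H"), (("G", "K", "L", "O"), "G"),
                          (("Q", "R", "S"), "Q")):
        for m in members:
            assert gstar.frame[idx[m]] == idx[seed]
            assert gstar.W[idx[m]] == ZERO
    # founders stay singleton frames
    assert gstar.frame[idx["A"]] == idx["A"]


def test_w_conflict_detected_on_inconsistent_triangle():
    system = ConstraintSystem()
    add_constraint(system, TreeConstraint(0, 1, 1))
    add_constraint(system, TreeConstraint(1, 2, 1))
    add_constraint(system, TreeConstraint(0, 2, 1))  # 1+1 != 1: cyclic clash
    gstar = build_constraint_graph(system, 3)
    assert gstar.conflicts


def test_synthetic_cycle_on_worked_example():
    graph = loop_pedigree_graph()
    tree = pinned_spanning_tree(graph)
    system = printed_constraint_system(graph)
    idx = idx_of(graph)
    e_bf = graph.edge_id(idx["B"], idx["F"])
    transform_type1(system)
    gstar = build_constraint_graph(system, graph.n)
    remaining = extend_by_synthetic_cycles(system, gstar, [e_bf])
    assert remaining == []
    assert system.cycle[e_bf].b == 0
    for a, b in (("N", "G"), ("G", "Q"), ("N", "Q")):
        key = tuple(sorted((idx[a], idx[b])))
        assert system.tree[key].b == 0
    # the three frames merged into one
    assert len({gstar.frame[idx[x]] for x in "GHIKLNOQRS"}) == 1
    assert not system.path  # all path constraints of B-F consumed


def test_single_self_loop_path_constraint_synthesises():
    # one path constraint whose endpoints share a frame: the t=0 case
    system = ConstraintSystem()
    add_constraint(system, TreeConstraint(1, 2, 1))
    add_constraint(system, PathConstraint(1, 2, 1, 9, a_side=0, b_side=3))
    gstar = build_constraint_graph(system, 4)
    # endpoints 1 and 2 now share a frame; W[1]+W[2] = 1, b_p = 1 -> b_c = 0
    remaining = extend_by_synthetic_cycles(system, gstar, [9])
    assert remaining == []
    assert system.cycle[9].b == 0


def test_two_parallel_paths_make_no_odd_cycle():
    # two path constraints of one edge between the same two frames close
    # only even cycles in the frame multigraph: no synthesis
    system = ConstraintSystem()
    add_constraint(system, TreeConstraint(1, 3, 0))  # frame {1,3}
    add_constraint(system, TreeConstraint(2, 4, 0))  # frame {2,4}
    add_constraint(system, PathConstraint(1, 2, 0, 9, a_side=0, b_side=5))
    add_constraint(system, PathConstraint(3, 4, 0, 9, a_side=0, b_side=5))
    gstar = build_constraint_graph(system, 6)
    remaining = extend_by_synthetic_cycles(system, gstar, [9])
    assert remaining == [9]
    assert 9 not in system.cycle
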
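"""Haplotype determination: founder attachment, linking, free variables,
p-propagation, verification and enumeration."""

import pytest

from zrhc.examples import solve_worked_example
from zrhc.gf2_core import gf2_eval
from zrhc.oracle import enumerate_valid_configurations
from zrhc.simulate import SimConfig, gene_drop, simulate_pedigree
from zrhc.solver import enumerate_solutions, phase, verify_family
from conftest import genotypes, make_pedigree


def labels_of(hs):
    return hs.graph.ped.labels


class TestWorkedExample:
    def test_founder_attachment_edges(self):
        hs = solve_worked_example()
        lab = labels_of(hs)
        attached = {(lab[a], lab[b]) for a, b in hs.founder_edges}
        # one weight-0 edge per founder, to its smallest tree-child
        assert {a for a, _ in attached} == set("ABCDEJMP")
        assert ("D", "G") in attached and ("J", "N") in attached

    def test_exactly_one_free_variable(self):
        hs = solve_worked_example()
        assert hs.n_free_variables == 1
        assert hs.registry[0][0] == "linker"

    def test_all_h_values_zero_in_particular_solution(self):
        hs = solve_worked_example()
        zeros = {0: 0}
        assert all(gf2_eval(expr, zeros) == 0 for expr in hs.h.values())
        # the free variable enters through exactly one tree edge (and shows
        # up again on the mating-loop edge whose cycle constraint it closes)
        tree_carriers = [
            e for e, expr in hs.h.items() if expr.vars and e in hs.tree.tree_edges
        ]
        assert len(tree_carriers) == 1

    def test_no_link_applies(self):
        # every path constraint of the global edge was consumed by the
        # synthetic cycle, so Step 4 linking finds nothing to do
        hs = solve_worked_example()
        assert hs.links == {}
        assert hs.conflicts == []


class TestFullyHetTrio:
    def test_single_anchor_two_phasings(self, trio):
        geno = genotypes([[2], [2], [2]])
        family, _ = phase(trio, geno)
        assert family.status == "consistent"
        sols = enumerate_solutions(family)
        assert sols == enumerate_valid_configurations(trio, geno)
        assert len(sols) == 2  # exactly the two valid phasings

    def test_m1_verification_runs(self, trio):
        family, _ = phase(trio, genotypes([[2], [2], [2]]))
        assert verify_family(family, _locus_data(trio, [[2], [2], [2]])) == "consistent"


def _locus_data(ped, codes):
    from zrhc.graph_build import build_graph, build_locus_data

    g = build_graph(ped)
    m = len(codes[0])
    return [build_locus_data(g, genotypes(codes), l) for l in range(m)]


def test_no_free_variables_single_configuration(trio):
    # hom father, het mother, het child: fully determined
    family, _ = phase(trio, genotypes([[0], [2], [2]]))
    assert family.status == "consistent"
    assert family.n_free_variables == 0
    assert len(enumerate_solutions(family)) == 1


def test_w_zero_edge_propagates_without_h(trio):
    # mother hom at the locus: the child's maternal allele is forced and the
    # child is predetermined regardless of any inheritance bit
    family, _ = phase(trio, genotypes([[2], [0], [2]]))
    assert family.status == "consistent"
    assert str(family.p[2][0]) == "1"  # paternal = complement of maternal 0


def test_flipped_genotype_reported(nuclear2):
    # het couple; children 1/1 and 0/0 at one locus is fine; flipping a
    # second locus to an impossible transmission must be caught
    bad = genotypes([[0, 2], [0, 2], [1, 2], [0, 2]])  # child 1/1 from 0/0 parents
    family, _ = phase(nuclear2, bad)
    assert family.status == "inconsistent"
    assert any("Mendelian" in c for c in family.conflicts)
    assert not enumerate_valid_configurations(nuclear2, bad)


def test_cross_locus_inconsistency_detected():
    # grandfather hom at both loci pins the father's transmissions; a child
    # genotype demanding opposite transmissions at the two loci cannot be
    # explained without recombination
    ped = make_pedigree(
        [
            ("1", "0", "0", 1), ("2", "0", "0", 2),
            ("3", "1", "2", 1), ("4", "0", "0", 2),
            ("5", "3", "4", 1), ("6", "3", "4", 2),
        ]
    )
    base = [[0, 0], [1, 1], [2, 2], [0, 0], [0, 0], [0, 0]]
    ok_family, _ = phase(ped, genotypes(base))
    assert ok_family.status == "consistent"
    twisted = [[0, 0], [1, 1], [2, 2], [0, 0], [0, 1], [0, 0]]
    fam, _ = phase(ped, genotypes(twisted))
    oracle_says = bool(enumerate_valid_configurations(ped, genotypes(twisted)))
    assert (fam.status == "consistent") == oracle_says


def test_enumeration_sizes_match_free_variables():
    ped = simulate_pedigree(SimConfig(n_target=10, m=2, seed=5))
    geno, _ = gene_drop(ped, 2, seed=6)
    family, _ = phase(ped, geno)
    used = {i for row in family.p for e in row for i in e.vars}
    assert len(enumerate_solutions(family)) <= 2 ** len(used)


def test_enumeration_refuses_large_families(trio):
    family, _ = phase(trio, genotypes([[2], [2], [2]]))
    with pytest.raises(ValueError):
        enumerate_solutions(family, max_vars=0)


def test_deterministic_report():
    cfg = SimConfig(n_target=20, m=4, k_target=1, seed=9)
    runs = []
    for _ in range(2):
        ped = simulate_pedigree(cfg)
        geno, _ = gene_drop(ped, 4, seed=10)
        family, _ = phase(ped, geno)
        runs.append(family.report())
    assert runs[0] == runs[1]
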
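"""Zero-recombinant pedigree and genotype simulation.

Pedigrees grow generation by generation: unmarried members either marry a
fresh founder spouse or -- while mating loops are still owed -- a relative
with whom they share an ancestor (first-cousin-style unions; sibling unions
are opt-in so that tiny looped test pedigrees are reachable).  Every couple
has 1-4 children.  Genotypes come from gene dropping: founders draw two
independent haplotypes, and each child inherits one *complete* haplotype
from each parent -- one transmission bit per parent-child pair, constant
across loci.  That constancy is the zero-recombination model.

The recorded truth lists each founder's haplotype pair in the phasing
convention the solver emits (the haplotype transmitted to the founder's
smallest tree-child first), so a correct solver family contains the truth
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_build import build_graph, build_spanning_tree, classify_nontree_edges
from .pedigree_io import GenotypeMatrix, Pedigree, encode_genotype

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulationError",
    "simulate_pedigree",
    "gene_drop",
    "inject_errors",
]


class SimulationError(RuntimeError):
    """The requested pedigree shape could not be produced."""


@dataclass
class SimConfig:
    """Simulation conditions.

    ``n_target`` is the minimum number of individuals (the generator stops
    growing once reached); ``k_target`` the number of mating loops;
    ``allele_freq`` the probability of allele 1 on founder haplotypes.
    """

    n_target: int = 60
    m: int = 30
    k_target: int = 0
    allele_freq: float = 0.5
    seed: int = 0
    marry_prob: float = 0.75
    allow_sibling_loops: bool = False
    n_errors: int = 0

    def __post_init__(self) -> None:
        if self.n_target < 3:
            raise ValueError("n_target must be at least 3")
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.k_target < 0:
            raise ValueError("k_target must be non-negative")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must lie strictly between 0 and 1")


@dataclass
class TruthRecord:
    """Simulated truth: ordered haplotype pairs and per-edge transmission bits."""

    haplotypes: list[tuple[tuple[int, ...], tuple[int, ...]]]
    transmitted: dict[tuple[int, int], int]  # (parent idx, child idx) -> bit
    k_achieved: int = 0
    corrupted: list[tuple[int, int]] = field(default_factory=list)

    def paternal_matrix(self) -> np.ndarray:
        return np.array([h[0] for h in self.haplotypes], dtype=np.int8)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Grow a pedigree with ~n_target members and exactly k_target mating
    loops; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    father: list[int] = []
    mother: list[int] = []
    sex: list[int] = []
    ancestors: list[frozenset[int]] = []

    def add(f: int = -1, m: int = -1, s: int | None = None) -> int:
        idx = len(father)
        father.append(f)
        mother.append(m)
        sex.append(int(rng.integers(1, 3)) if s is None else s)
        anc = frozenset() if f < 0 else ancestors[f] | ancestors[m] | {f, m}
        ancestors.append(anc)
        return idx

    # a single root couple seeds the population; later spouses marry in as
    # fresh founders, so the pedigree stays connected by construction
    root_f, root_m = add(s=1), add(s=2)
    pool = [add(root_f, root_m) for _ in range(int(rng.integers(2, 5)))]
    loops_made = 0
    hard_cap = config.n_target + 16
    stalls = 0

    while True:
        matings: list[tuple[int, int]] = []
        used: set[int] = set()
        if loops_made < config.k_target:
            for x in pool:
                if loops_made >= config.k_target or x in used:
                    continue
                for y in pool:
                    if y == x or y in used or sex[y] == sex[x]:
                        continue
                    siblings = father[x] >= 0 and (father[x], mother[x]) == (father[y], mother[y])
                    if siblings and not config.allow_sibling_loops:
                        continue
                    related = bool(ancestors[x] & ancestors[y])
                    if related and x not in ancestors[y] and y not in ancestors[x]:
                        matings.append((x, y) if sex[x] == 1 else (y, x))
                        used.update((x, y))
                        loops_made += 1
                        break
        grow_until = max(config.n_target, 5)  # at least one union even for tiny targets
        for x in pool:
            if x in used or len(father) >= grow_until:
                continue
            if rng.random() < config.marry_prob:
                spouse = add(s=2 if sex[x] == 1 else 1)
                matings.append((x, spouse) if sex[x] == 1 else (spouse, x))
                used.add(x)
        next_pool: list[int] = []
        for f, m in matings:
            # consanguineous couples get a single child so each mating loop
            # induces exactly one global cycle under the spanning tree
            related = bool(ancestors[f] & ancestors[m])
            n_children = 1 if related else int(rng.integers(1, 5))
            for _ in range(n_children):
                next_pool.append(add(f, m))
        if len(father) >= config.n_target and loops_made >= config.k_target:
            break
        stalls = stalls + 1 if not matings else 0
        if stalls > 50 or len(father) >= hard_cap:
            raise SimulationError(
                f"could not place {config.k_target} mating loops within "
                f"{config.n_target} individuals; increase n_target"
            )
        pool = next_pool if next_pool else pool

    # drop founders that never married: an isolated individual carries no
    # linkage information and only bloats the free-variable count
    has_child = [False] * len(father)
    for j in range(len(father)):
        if father[j] >= 0:
            has_child[father[j]] = has_child[mother[j]] = True
    keep = [j for j in range(len(father)) if has_child[j] or father[j] >= 0]
    remap = {j: i for i, j in enumerate(keep)}
    rows = [
        (
            "FAM1",
            str(remap[j] + 1),
            str(remap[father[j]] + 1) if father[j] >= 0 else "0",
            str(remap[mother[j]] + 1) if mother[j] >= 0 else "0",
            sex[j],
        )
        for j in keep
    ]
    return Pedigree.from_rows(rows)


def achieved_loops(ped: Pedigree) -> int:
    """Number of global non-tree edges under the deterministic spanning tree."""
    tree = build_spanning_tree(build_graph(ped))
    _local, global_e, _ = classify_nontree_edges(tree)
    return len(global_e)


def gene_drop(
    ped: Pedigree, m: int, seed: int, freq: float = 0.5
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Drop founder haplotypes through the pedigree with zero recombination.

    Founders draw two independent Bernoulli(freq) haplotypes; every child
    draws one transmission bit per parent selecting which parental haplotype
    it receives whole.  Founder haplotype pairs in the returned truth are
    ordered by the solver's convention (transmitted-to-smallest-tree-child
    first)."""
    rng = np.random.default_rng(seed)
    n = ped.n
    haps: list[list[tuple[int, ...]] | None] = [None] * n
    transmitted: dict[tuple[int, int], int] = {}
    order = _topological_order(ped)
    for j in order:
        if ped.father[j] < 0:
            pair = rng.random((2, m)) < freq
            haps[j] = [tuple(int(b) for b in pair[0]), tuple(int(b) for b in pair[1])]
        else:
            received = []
            for parent in (ped.father[j], ped.mother[j]):
                bit = int(rng.integers(0, 2))
                transmitted[(parent, j)] = bit
                received.append(haps[parent][bit])
            haps[j] = received

    # normalise founder phase to the solver's attachment convention
    tree = build_spanning_tree(build_graph(ped))
    for f in sorted(ped.founders):
        children = [c for c, _eid in tree.tree_adj[f]]
        if not children:
            continue
        c = min(children)
        if transmitted[(f, c)] == 1:
            haps[f] = [haps[f][1], haps[f][0]]
            for child in ped.children_of(f):
                transmitted[(f, child)] ^= 1

    g = np.zeros((n, m), dtype=np.int8)
    for j in range(n):
        for l in range(m):
            g[j, l] = encode_genotype(haps[j][0][l], haps[j][1][l])
    truth = TruthRecord(
        [(h[0], h[1]) for h in haps], transmitted, k_achieved=achieved_loops(ped)
    )
    return GenotypeMatrix(g), truth


def _topological_order(ped: Pedigree) -> list[int]:
    order: list[int] = []
    placed = [False] * ped.n
    pending = list(range(ped.n))
    while pending:
        rest = []
        for j in pending:
            fa = ped.father[j]
            if fa < 0 or (placed[fa] and placed[ped.mother[j]]):
                order.append(j)
                placed[j] = True
            else:
                rest.append(j)
        if len(rest) == len(pending):  # pragma: no cover - Pedigree is acyclic
            raise RuntimeError("pedigree is not acyclic")
        pending = rest
    return order


def inject_errors(
    geno: GenotypeMatrix, n_errors: int, seed: int
) -> tuple[GenotypeMatrix, list[tuple[int, int, int, int]]]:
    """Flip ``n_errors`` randomly chosen genotype codes to a different code;
    returns the corrupted matrix and (individual, locus, old, new) records."""
    rng = np.random.default_rng(seed)
    g = geno.g.copy()
    n, m = g.shape
    cells = rng.choice(n * m, size=n_errors, replace=False)
    changed = []
    for cell in sorted(int(c) for c in cells):
        j, l = divmod(cell, m)
        old = int(g[j, l])
        new = int(rng.choice([c for c in (0, 1, 2) if c != old]))
        g[j, l] = new
        changed.append((j, l, old, new))
    return GenotypeMatrix(g), changed
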
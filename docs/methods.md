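# Methods

## Problem and model

Given a pedigree (every non-founder has both parents recorded, no
individual is its own ancestor) and complete bi-allelic genotypes at *m*
loci, the zero-recombinant model states that each child inherits one entire
haplotype from each parent, without mutation. Coding genotypes as
0 (hom 0/0), 1 (hom 1/1), 2 (het), unknowns are the paternal alleles
`p_i[l]` and the per-edge transmission bits `h_{i,j}` (constant over loci —
that constancy *is* the model). All arithmetic is over GF(2); the single
inheritance identity `p_i[l] + w_i[l]·h_{i,j} = p_j[l] + d_{i,j}[l]` covers
father and mother edges uniformly through the edge constant `d`.

A solution is reported as a **general solution**: `h` and `p` as affine
GF(2) expressions over registered free variables, so the full solution set
is recovered by instantiating the variables. Three kinds of freedom occur:

- **linker** — a free constraint-graph edge joining components that no
  constraint relates;
- **edge_h** — a transmission bit on a tree edge that no surviving
  constraint reaches;
- **anchor** — the free phase of a region that is heterozygous throughout
  at one locus (complementing all its `p` values at that locus is a
  symmetry).

## Algorithm

The pipeline follows the four-step constraint-graph design: preprocessing
(pedigree graph, spanning forest, per-locus constants and predetermined
nodes), constraint generation (cycle/path constraints per non-tree edge and
per locus, tree constraints per locus-forest component, all with keyed
deduplication), reduction (folding path constraints of cycle-constrained
edges into tree constraints; breadth-first `W`-labelling of the constraint
graph; synthetic cycles for mating-loop edges assembled from an odd number
of path constraints linking components), and haplotype determination
(founder attachment with weight 0, component linking through path
constraints, free variables for the remainder, then per-locus propagation
of `p` from predetermined nodes).

Deterministic choices are fixed wherever the design leaves them open: the
spanning tree is depth-first from the smallest individual id with neighbors
in ascending order; seeds are always the smallest node index of their
component; the odd cycle used for a synthetic constraint is the first found
(self-loops first, then two-colouring in scan order); free edges form a
star centred on the component containing the smallest node. Identical input
and seed therefore give byte-identical output.

### Residual constraints and variable elimination

The constraint-graph machinery alone leaves two gaps, both hit in practice
by looped pedigrees whose loop edge never acquires a cycle constraint:

1. a path constraint whose endpoints do not pair up inside single
   `W`-components is unusable by the linking formula, yet still carries
   information;
2. a tree edge between components joined only by a link has no
   `W`-derivable `h`, and its transmission bit couples the loci it is
   heterozygous at.

Both are closed by making the residue explicitly symbolic: every tree edge
still lacking an `h` receives a fresh `edge_h` variable, after which *all*
remaining path and cycle constraints evaluate to equations over the free
variables. Two derivations of the same quantity that differ by a
non-constant expression are not an error but a linear relation: the highest
variable in the difference is solved for and substituted out everywhere
(constraint values, `h`, already-derived `p`). A constant-1 difference is a
genuine inconsistency. The same rule resolves meets during per-locus
propagation, so a relation discovered at one locus immediately rewrites the
others. This is a deliberately tiny elimination — it touches only the
residual free variables (usually zero or a handful), never the original
O(mn) system, preserving the near-linear behaviour of the constraint-graph
route while making the enumerated family exactly equal to the brute-force
solution set on every random instance we test.

### Founder-phase convention

"Paternal" versus "maternal" is unobservable for founders, so each founder
with children is attached to its smallest tree-child with `h = 0`: its
reported first haplotype is the one transmitted to that child. The
exhaustive oracle applies the same convention when enumerating (otherwise
every informative founder doubles the raw count with relabelled
duplicates), and the simulator records truth with founder haplotype pairs
ordered the same way, which is why the simulated truth appears verbatim in
the solved family.

## Consistency checking

Findings accumulate rather than abort, so one run reports everything:
(1) a single-locus Mendelian screen per child; (2) value conflicts under
keyed constraint insertion; (3) `W`-label disagreements on revisits during
constraint-graph traversal; (4) contradictory `h` determinations (constant
difference) during linking/refinement; (5) meet conflicts during `p`
propagation; (6) a final audit asserting the inheritance identity
symbolically on every known-`h` edge and locus, and for unknown-`h` edges
that all per-locus implied bits agree — this last check is precisely the
zero-recombination condition. Edges with no heterozygous locus are reported
as unconstrained, not as errors. On tiny instances the checker's verdict
agrees with exhaustive search (flagged iff no valid configuration exists).

## Synthetic data

`simulate_pedigree` grows a single connected family from one root couple:
unmarried members take fresh founder spouses (keeping the pedigree a tree)
or, while mating loops are still owed, a relative sharing an ancestor;
consanguineous couples get exactly one child so each loop contributes one
global cycle; ordinary couples have 1–4 children. Sibling unions are opt-in
(`allow_sibling_loops`) so that looped pedigrees small enough for
exhaustive enumeration exist. `gene_drop` gives founders two independent
Bernoulli(0.5 by default) haplotypes and each child one whole haplotype per
parent; `inject_errors` flips chosen genotype codes.

What the generator does **not** emulate: missing genotypes, genotyping
error models, mutation, recombination, multi-allelic markers, realistic
demographic structure (the achieved individual count overshoots the target
by up to one sibship, and the classification of sibling cycles is relative
to the deterministic spanning tree, so the reported loop count can exceed
the number of consanguineous unions when the tree routes a sibship through
in-laws). Passing tests therefore demonstrate correctness of the
combinatorial solver under the stated model, not robustness to real typing
artefacts — those inputs are rejected or flagged, not handled.

## Parameters and problem sizes

- `allele_freq` (default 0.5) controls founder heterozygosity and hence the
  density of predetermined nodes; lower values make loci less informative.
- `n_target`/`m`/`k_target`: the test and acceptance studies use 200 tiny
  pedigrees (≤14 members, ≤4 loci, ≤1 loop) for exhaustive-oracle
  equivalence, and 100 simulations of ~40–60 members at 30 loci with 0–3
  loops for truth membership; at 30 loci ≳95 % of runs need no free
  variable at all, matching the qualitative expectation that free variables
  only appear when loci are scarce relative to family size.
- `enumerate_solutions` refuses beyond 16 variables actually occurring in
  `p` (the family itself stays symbolic at any size).

## Known limitations

Missing data and recombination are out of scope by design. Multiple
families in one PED file are phased independently as disconnected
components. The spanning-tree-relative local/global cycle classification
can overstate the mating-loop count (harmless: misclassified sibling edges
merely take the synthetic-cycle route). Worst-case elimination cost is
quadratic in the number of residual free variables, which is tiny in all
observed regimes.
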
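# zrhc — zero-recombinant haplotype configuration on general pedigrees

Geneticists working with family data need to know which allele of each
marker an individual inherited from which parent. For a pedigree typed at
tightly linked markers, the standard combinatorial model assumes strict
Mendelian inheritance with **zero recombination**: each child receives one
*complete* haplotype from each parent. The **zero-recombinant haplotype
configuration (ZRHC)** problem asks for all haplotype assignments consistent
with the observed unordered genotypes — including on pedigrees with
**mating loops** (consanguineous unions).

`zrhc` solves ZRHC by constraint propagation over GF(2), producing a
**general solution**: every valid configuration expressed over free binary
variables, not just one arbitrary phasing. It also detects genotype
inconsistencies (Mendelian errors and cross-locus contradictions) and ships
a zero-recombinant gene-dropping simulator.

## Model

Write `p_i[l] ∈ {0,1}` for the paternal allele of individual *i* at locus
*l*, `w_i[l]` for heterozygosity (1 iff genotype code `g_i[l] = 2`), and
`h_{i,j} ∈ {0,1}` for whether parent *i* transmitted its paternal (0) or
maternal (1) haplotype to child *j* — constant across loci under zero
recombination. Inheritance across every parent–child edge satisfies, over
GF(2),

```
p_i[l] + w_i[l]·h_{i,j} = p_j[l] + d_{i,j}[l]
```

with the constant `d = 0` on father–child edges and `d = w_j[l]` on
mother–child edges. Summing this identity along paths and cycles of each
*locus graph* (edges whose parent endpoint is heterozygous) yields linear
constraints on the `h` variables alone. The solver:

1. builds the pedigree graph, a deterministic spanning tree, and per-locus
   constants (Step 1);
2. generates cycle, path and tree constraints with keyed deduplication
   (Step 2);
3. folds redundant constraints, assembles a *constraint graph* whose
   components carry cumulative `W` values, and synthesises missing cycle
   constraints of mating-loop edges from odd sets of path constraints
   (Step 3);
4. attaches founders, links components, introduces explicit free variables
   for whatever remains genuinely undetermined, and back-substitutes to get
   symbolic `h` and `p` expressions (Step 4).

Every quantity is an affine GF(2) expression over registered free variables
(`linker`, `edge_h`, `anchor`), so the returned family *is* the solution
space; instantiating all variables at 0 gives a particular phasing.

## Worked example

```
$ zrhc simulate --n 20 --m 8 --loops 1 --seed 7 --out sim.ped --truth truth.tsv
simulated n=28 m=8 mating-loops=4 errors=0
$ zrhc phase --ped sim.ped --out hap.tsv --report rep.json --mode general
pedigree: n=28 edges=42 local-cycles=11 mating-loops(k)=4 loci=8
constraints: |C^C|=9 |C^P|=12 |C^T|=28
solution: frames=1 free-variables=0
$ head -3 hap.tsv
IID	paternal_hap	maternal_hap
1	10100111	11111101
2	10000111	11110101
```

The log lines report the constraint-set sizes (cycle / path / tree) and the
final number of constraint-graph components and free variables — here the
eight loci pin the solution completely (`free-variables=0`), so the TSV is
the unique phasing up to the founder convention: each founder's reported
"paternal" haplotype is the one transmitted to its smallest tree-child.
With fewer loci, `--mode general` writes a JSON report listing each free
variable, its provenance, and symbolic `h`/`p` expressions.

`zrhc check --ped FILE` runs the same pipeline in checking mode and exits
1 with a conflict list if no zero-recombinant configuration exists (e.g.
after genotyping errors).

The library mirrors the CLI: see `zrhc.phase`, `zrhc.enumerate_solutions`,
`zrhc.simulate_pedigree`, `zrhc.gene_drop`, and `zrhc.examples` for a
bundled 19-member looped pedigree with its constraint sets.

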
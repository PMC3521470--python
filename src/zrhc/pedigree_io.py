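"""Reading and writing pedigree data.

Input is the minimal pre-makeped LINKAGE dialect: whitespace-delimited text
with columns ``FamID IID PAT MAT SEX`` followed by ``2m`` allele columns,
alleles coded ``1``/``2`` (mapped internally to 0/1), parent id ``0`` meaning
"founder".  Genotypes are stored per locus as the usual three-valued code:
0 = homozygous 0/0, 1 = homozygous 1/1, 2 = heterozygous.

Missing alleles and half-specified parent pairs are rejected: the
zero-recombinant model assumes complete bi-allelic data and silently imputing
would hide genotyping problems the consistency checker is meant to expose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PedigreeError",
    "Pedigree",
    "GenotypeMatrix",
    "encode_genotype",
    "read_ped",
    "write_ped",
    "write_outputs",
    "write_truth",
]


class PedigreeError(ValueError):
    """Malformed pedigree file or structurally invalid pedigree."""


def _sort_key(iid: str):
    # numeric ids sort numerically, everything else lexicographically after
    return (0, int(iid), "") if iid.isdigit() else (1, 0, iid)


@dataclass
class Pedigree:
    """Individuals in a canonical deterministic order with parent links.

    ``father`` / ``mother`` hold node indices (-1 for founders).  All
    algorithms address individuals by index; ``labels`` maps back to the
    input ids.  Non-founders always have both parents present and the parent
    relation is acyclic.
    """

    labels: list[str]
    fams: list[str]
    father: list[int]
    mother: list[int]
    sex: list[int]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for j in range(n):
            f, m = self.father[j], self.mother[j]
            if (f < 0) != (m < 0):
                raise PedigreeError(
                    f"individual {self.labels[j]!r} has exactly one parent recorded; "
                    "the model requires both or neither"
                )
            for p in (f, m):
                if p >= n:
                    raise PedigreeError(f"dangling parent index for {self.labels[j]!r}")
            if f >= 0 and f == m:
                raise PedigreeError(f"individual {self.labels[j]!r} lists the same parent twice")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state = [0] * self.n  # 0 unseen, 1 on stack, 2 done
        for start in range(self.n):
            stack = [start]
            path = []
            while stack:
                j = stack[-1]
                if state[j] == 0:
                    state[j] = 1
                    path.append(j)
                    for p in (self.father[j], self.mother[j]):
                        if p >= 0:
                            if state[p] == 1:
                                raise PedigreeError(
                                    f"pedigree cycle: {self.labels[p]!r} is its own ancestor"
                                )
                            if state[p] == 0:
                                stack.append(p)
                else:
                    stack.pop()
                    if path and path[-1] == j:
                        path.pop()
                    state[j] = 2

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def founders(self) -> list[int]:
        return [j for j in range(self.n) if self.father[j] < 0]

    def children_of(self, i: int) -> list[int]:
        return [j for j in range(self.n) if self.father[j] == i or self.mother[j] == i]

    def is_parent_of(self, i: int, j: int) -> bool:
        return self.father[j] == i or self.mother[j] == i

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[str, str, str, str, int]]) -> "Pedigree":
        """Build from (fam, iid, father-iid, mother-iid, sex) tuples."""
        keys = [(fam, iid) for fam, iid, *_ in rows]
        if len(set(keys)) != len(keys):
            raise PedigreeError("duplicate individual id within a family")
        order = sorted(range(len(rows)), key=lambda r: (rows[r][0], _sort_key(rows[r][1])))
        index = {keys[r]: pos for pos, r in enumerate(order)}
        iid_counts: dict[str, int] = {}
        for _, iid, *_ in rows:
            iid_counts[iid] = iid_counts.get(iid, 0) + 1

        labels, fams, fa, mo, sex = [], [], [], [], []
        for r in order:
            fam, iid, pat, mat, sx = rows[r]
            labels.append(iid if iid_counts[iid] == 1 else f"{fam}:{iid}")
            fams.append(fam)
            for name, parent, dest in (("father", pat, fa), ("mother", mat, mo)):
                if parent == "0":
                    dest.append(-1)
                elif (fam, parent) in index:
                    dest.append(index[(fam, parent)])
                else:
                    raise PedigreeError(
                        f"{name} {parent!r} of individual {iid!r} not present in family {fam!r}"
                    )
            sex.append(sx)
        return cls(labels, fams, fa, mo, sex)


@dataclass
class GenotypeMatrix:
    """Per-individual, per-locus genotype codes (0 = hom 0/0, 1 = hom 1/1, 2 = het)."""

    g: np.ndarray  # shape (n, m), dtype int8

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int8)
        if self.g.ndim != 2:
            raise PedigreeError("genotype matrix must be 2-dimensional")
        if not np.isin(self.g, (0, 1, 2)).all():
            raise PedigreeError("genotype codes must be 0, 1 or 2")

    @property
    def m(self) -> int:
        return self.g.shape[1]


def encode_genotype(paternal_allele: int, maternal_allele: int) -> int:
    """Unordered genotype code of an allele pair: (0,0)->0, (1,1)->1, mixed->2."""
    if paternal_allele not in (0, 1) or maternal_allele not in (0, 1):
        raise PedigreeError("alleles must be 0 or 1")
    if paternal_allele != maternal_allele:
        return 2
    return paternal_allele


def _parse_allele(tok: str, where: str) -> int:
    if tok == "0":
        raise PedigreeError(f"missing allele (code 0) at {where}: missing data is unsupported")
    if tok == "1":
        return 0
    if tok == "2":
        return 1
    raise PedigreeError(f"non-bi-allelic symbol {tok!r} at {where}")


def read_ped(path: str | Path) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a LINKAGE-style PED file; returns a validated pedigree + genotypes."""
    rows: list[tuple[str, str, str, str, int]] = []
    codes: list[list[int]] = []
    m: int | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        fieldset = line.split()
        if not fieldset or fieldset[0].startswith("#"):
            continue
        if len(fieldset) < 7 or (len(fieldset) - 5) % 2 != 0:
            raise PedigreeError(f"line {lineno}: expected 5 id columns plus 2m allele columns")
        fam, iid, pat, mat, sx = fieldset[:5]
        alleles = fieldset[5:]
        if m is None:
            m = len(alleles) // 2
        elif len(alleles) // 2 != m:
            raise PedigreeError(f"line {lineno}: ragged row ({len(alleles)//2} loci, expected {m})")
        try:
            sex = int(sx)
        except ValueError as exc:
            raise PedigreeError(f"line {lineno}: bad sex code {sx!r}") from exc
        row_codes = []
        for l in range(m):
            a = _parse_allele(alleles[2 * l], f"line {lineno}, locus {l + 1}")
            b = _parse_allele(alleles[2 * l + 1], f"line {lineno}, locus {l + 1}")
            row_codes.append(encode_genotype(a, b))
        rows.append((fam, iid, pat, mat, sex))
        codes.append(row_codes)
    if not rows:
        raise PedigreeError(f"{path}: no pedigree records found")

    ped = Pedigree.from_rows(rows)
    # reorder genotype rows into the pedigree's canonical order
    key_to_codes = {(fam, iid): c for (fam, iid, *_), c in zip(rows, codes)}
    ordered = [key_to_codes[(ped.fams[j], _strip_fam(ped.labels[j], ped.fams[j]))] for j in range(ped.n)]
    return ped, GenotypeMatrix(np.array(ordered, dtype=np.int8))


def _strip_fam(label: str, fam: str) -> str:
    prefix = f"{fam}:"
    return label[len(prefix):] if label.startswith(prefix) else label


_CODE_TO_ALLELES = {0: ("1", "1"), 1: ("2", "2"), 2: ("1", "2")}


def write_ped(ped: Pedigree, geno: GenotypeMatrix, path: str | Path) -> None:
    """Write pedigree + genotypes back out in the same dialect read_ped accepts."""
    lines = []
    for j in range(ped.n):
        iid = _strip_fam(ped.labels[j], ped.fams[j])
        pat = _strip_fam(ped.labels[ped.father[j]], ped.fams[j]) if ped.father[j] >= 0 else "0"
        mat = _strip_fam(ped.labels[ped.mother[j]], ped.fams[j]) if ped.mother[j] >= 0 else "0"
        cols = [ped.fams[j], iid, pat, mat, str(ped.sex[j])]
        for l in range(geno.m):
            cols.extend(_CODE_TO_ALLELES[int(geno.g[j, l])])
        lines.append(" ".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(ped: Pedigree, truth, path: str | Path) -> None:
    """Write the simulator's true haplotypes and transmission bits as TSV.

    Columns: IID, paternal haplotype, maternal haplotype, transmissions
    (semicolon-joined ``child=bit`` records; ``.`` if the individual has no
    children).
    """
    lines = ["IID\tpaternal_hap\tmaternal_hap\ttransmissions"]
    for j in range(ped.n):
        hap1 = "".join(str(b) for b in truth.haplotypes[j][0])
        hap2 = "".join(str(b) for b in truth.haplotypes[j][1])
        trans = [
            f"{ped.labels[c]}={truth.transmitted[(j, c)]}"
            for c in ped.children_of(j)
        ]
        lines.append("\t".join([ped.labels[j], hap1, hap2, ";".join(trans) or "."]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(family, mode: str, hap_path: str | Path | None = None,
                  report_path: str | Path | None = None) -> None:
    """Write a solved family: TSV haplotypes and/or a JSON general-solution report.

    ``particular`` mode instantiates every free variable at 0; ``general``
    mode additionally requires ``report_path`` and emits the symbolic
    solution.  An unsolved family (no p-expressions) is an error.
    """
    if mode not in ("particular", "general"):
        raise ValueError(f"unknown output mode {mode!r}")
    if family.p is None:
        raise ValueError("family has no solution to write (pipeline did not finish)")
    if hap_path is not None:
        pat, mat = family.particular_haplotypes()
        lines = ["IID\tpaternal_hap\tmaternal_hap"]
        for j, label in enumerate(family.labels):
            lines.append(
                "\t".join([label, "".join(map(str, pat[j])), "".join(map(str, mat[j]))])
            )
        Path(hap_path).write_text("\n".join(lines) + "\n")
    if mode == "general":
        if report_path is None:
            raise ValueError("general mode requires a report path")
        Path(report_path).write_text(json.dumps(family.report(), indent=2) + "\n")
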
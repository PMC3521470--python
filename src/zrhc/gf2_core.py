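"""Symbolic affine arithmetic over GF(2).

Every quantity the solver manipulates -- cycle/path/tree constraint values,
per-node ``W`` values on the constraint graph, per-edge inheritance bits ``h``
and per-locus paternal alleles ``p`` -- is an affine expression over GF(2):
a constant bit plus an XOR of free variables.  Free variables are issued by a
registry so that the final general solution can report where each degree of
freedom came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GF2Expr",
    "FreeVarRegistry",
    "ZERO",
    "ONE",
    "const",
    "var",
    "gf2_add",
    "gf2_scale",
    "gf2_eval",
    "fresh_var",
]


@dataclass(frozen=True)
class GF2Expr:
    """An affine GF(2) expression ``constant + x_i1 + x_i2 + ...``.

    ``vars`` is kept sorted and duplicate-free, so two expressions are equal
    iff they are structurally equal.  An expression with empty ``vars`` is a
    constant.
    """

    constant: int
    vars: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.constant not in (0, 1):
            raise ValueError(f"GF(2) constant must be 0 or 1, got {self.constant!r}")
        v = tuple(sorted(set(self.vars)))
        if v != tuple(self.vars):
            object.__setattr__(self, "vars", v)

    @property
    def is_constant(self) -> bool:
        return not self.vars

    def __add__(self, other: "GF2Expr | int") -> "GF2Expr":
        if isinstance(other, int):
            other = const(other)
        return gf2_add(self, other)

    __xor__ = __add__
    __radd__ = __add__

    def __str__(self) -> str:
        terms = [f"f{i}" for i in self.vars]
        if self.constant or not terms:
            terms = [str(self.constant)] + terms
        return "+".join(terms)


ZERO = GF2Expr(0)
ONE = GF2Expr(1)


def const(bit: int) -> GF2Expr:
    """The constant expression for ``bit`` (0 or 1)."""
    return ZERO if bit % 2 == 0 else ONE


def var(i: int) -> GF2Expr:
    """The bare free variable ``x_i``."""
    return GF2Expr(0, (i,))


def gf2_add(a: GF2Expr, b: GF2Expr) -> GF2Expr:
    """XOR of two affine expressions; variable sets combine symmetrically."""
    return GF2Expr(a.constant ^ b.constant, tuple(set(a.vars) ^ set(b.vars)))


def gf2_sum(exprs: Iterable[GF2Expr]) -> GF2Expr:
    acc = ZERO
    for e in exprs:
        acc = gf2_add(acc, e)
    return acc


def gf2_scale(w: int, a: GF2Expr) -> GF2Expr:
    """Multiply by a constant bit: 0*a = 0, 1*a = a."""
    if w not in (0, 1):
        raise ValueError(f"scale factor must be 0 or 1, got {w!r}")
    return a if w else ZERO


def gf2_eval(a: GF2Expr, assignment: Mapping[int, int]) -> int:
    """Evaluate under a {var id: bit} assignment covering all of ``a.vars``."""
    bit = a.constant
    for i in a.vars:
        if i not in assignment:
            raise KeyError(f"no assignment for free variable {i}")
        bit ^= assignment[i] & 1
    return bit


# Free-variable bookkeeping ------------------------------------------------

#: kinds of free variables the solver can introduce
KINDS = ("linker", "edge_h", "anchor")


@dataclass
class FreeVarRegistry:
    """Issues consecutive integer ids and remembers why each was created.

    kind is one of ``linker`` (a free constraint-graph edge joining two
    otherwise unrelated components), ``edge_h`` (an inheritance bit nothing
    constrains), or ``anchor`` (the free phase of an all-heterozygous region
    at one locus).
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    def fresh(self, kind: str, provenance: str) -> int:
        if kind not in KINDS:
            raise ValueError(f"unknown free-variable kind {kind!r}")
        self.entries.append((kind, provenance))
        return len(self.entries) - 1

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> tuple[str, str]:
        return self.entries[i]

    def __iter__(self):
        return iter(self.entries)


def fresh_var(registry: FreeVarRegistry, kind: str, provenance: str) -> int:
    """Issue a new free-variable id (strictly increasing)."""
    return registry.fresh(kind, provenance)
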
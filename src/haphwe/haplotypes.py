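"""Haplotypes, unphased genotypes and compatible haplotype pairs.

All loci are biallelic with alleles coded 1 and 2.  A haplotype over ``L``
tightly linked SNPs is an ordered vector of allele codes; it is stored
compactly as an integer in ``[0, 2**L)`` by reading the alleles as binary
digits (allele 1 -> bit 0, allele 2 -> bit 1, SNP 1 most significant).

An unphased genotype records, per SNP, the unordered pair of alleles an
individual carries but not which allele sits on which chromosome.  When
``s`` SNPs are heterozygous, the genotype is compatible with
``max(1, 2**(s-1))`` unordered haplotype pairs; :func:`enumerate_compatible_pairs`
lists them all in a deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Haplotype",
    "UnphasedGenotype",
    "HaplotypePair",
    "enumerate_compatible_pairs",
    "induced_genotype",
    "MissingGenotypeError",
]


class MissingGenotypeError(ValueError):
    """Raised when an operation requires a fully observed genotype."""


@dataclass(frozen=True, order=True)
class Haplotype:
    """An ordered vector of allele codes (each 1 or 2) across L SNPs."""

    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.alleles or any(a not in (1, 2) for a in self.alleles):
            raise ValueError(f"allele codes must be 1 or 2, got {self.alleles}")

    @cached_property
    def code(self) -> int:
        """Integer encoding: allele 1 -> 0, allele 2 -> 1, SNP 1 most significant."""
        c = 0
        for a in self.alleles:
            c = (c << 1) | (a - 1)
        return c

    @property
    def n_snps(self) -> int:
        return len(self.alleles)

    @classmethod
    def from_code(cls, code: int, n_snps: int) -> "Haplotype":
        if not 0 <= code < (1 << n_snps):
            raise ValueError(f"code {code} out of range for {n_snps} SNPs")
        bits = ((code >> (n_snps - 1 - j)) & 1 for j in range(n_snps))
        return cls(tuple(b + 1 for b in bits))

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        """Parse a label like ``"221"`` into a haplotype."""
        return cls(tuple(int(ch) for ch in s))

    def __str__(self) -> str:
        return "".join(str(a) for a in self.alleles)


@dataclass(frozen=True)
class UnphasedGenotype:
    """Per-SNP unordered allele pairs for one individual; phase unknown.

    ``pairs[j]`` is a sorted 2-tuple of allele codes at SNP j, or ``None``
    when the genotype is missing at that SNP.
    """

    pairs: tuple[tuple[int, int] | None, ...]

    def __post_init__(self) -> None:
        for pr in self.pairs:
            if pr is None:
                continue
            if len(pr) != 2 or any(a not in (1, 2) for a in pr):
                raise ValueError(f"invalid allele pair {pr}")
            if pr[0] > pr[1]:
                raise ValueError(f"allele pair {pr} not sorted")

    @classmethod
    def from_allele_pairs(
        cls, pairs: Iterable[tuple[int, int] | None]
    ) -> "UnphasedGenotype":
        norm: list[tuple[int, int] | None] = []
        for pr in pairs:
            norm.append(None if pr is None else tuple(sorted(pr)))  # type: ignore[arg-type]
        return cls(tuple(norm))

    @classmethod
    def from_dosage(cls, dosage: Sequence[int]) -> "UnphasedGenotype":
        """Build from per-SNP allele-2 dosage (0, 1 or 2; negative = missing)."""
        table = {0: (1, 1), 1: (1, 2), 2: (2, 2)}
        return cls(tuple(None if d < 0 else table[int(d)] for d in dosage))

    def to_dosage(self) -> np.ndarray:
        """Per-SNP count of allele 2 (missing -> -1)."""
        return np.array(
            [-1 if pr is None else (pr[0] - 1) + (pr[1] - 1) for pr in self.pairs],
            dtype=np.int64,
        )

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    @property
    def has_missing(self) -> bool:
        return any(pr is None for pr in self.pairs)

    @property
    def n_heterozygous(self) -> int:
        """Number of SNPs with alleles {1, 2}."""
        return sum(1 for pr in self.pairs if pr == (1, 2))


@dataclass(frozen=True)
class HaplotypePair:
    """An unordered pair of haplotypes stored in canonical (code) order."""

    first: Haplotype
    second: Haplotype

    def __post_init__(self) -> None:
        if self.first.n_snps != self.second.n_snps:
            raise ValueError("haplotype length mismatch")
        if self.first.code > self.second.code:
            # enforce canonical order so pair(a, b) == pair(b, a)
            a, b = self.second, self.first
            object.__setattr__(self, "first", a)
            object.__setattr__(self, "second", b)

    @property
    def is_homozygous(self) -> bool:
        return self.first == self.second


def enumerate_compatible_pairs(genotype: UnphasedGenotype) -> list[HaplotypePair]:
    """All unordered haplotype pairs whose allele multisets match ``genotype``.

    For ``s`` heterozygous SNPs there are exactly ``max(1, 2**(s-1))`` such
    pairs; they are returned sorted by ``(first.code, second.code)``.

    Raises
    ------
    MissingGenotypeError
        If any SNP is missing.  Callers must filter or impute beforehand;
        this function never guesses.
    """
    if genotype.has_missing:
        raise MissingGenotypeError(
            "genotype has missing SNPs; exclude the individual or impute first"
        )
    L = genotype.n_snps
    dosage = genotype.to_dosage()
    k_codes, l_codes = _compatible_pair_codes(dosage, L)
    pairs = [
        HaplotypePair(Haplotype.from_code(int(k), L), Haplotype.from_code(int(l), L))
        for k, l in zip(k_codes, l_codes)
    ]
    pairs.sort(key=lambda p: (p.first.code, p.second.code))
    return pairs


def _compatible_pair_codes(dosage: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer-code version of pair enumeration used by the numeric engine.

    ``dosage`` is the per-SNP allele-2 count (no missing values).  Returns
    two equal-length arrays of haplotype codes with k <= l, each unordered
    pair exactly once, sorted lexicographically by (k, l).
    """
    het = np.flatnonzero(dosage == 1)
    base = 0
    for j in np.flatnonzero(dosage == 2):
        base |= 1 << (L - 1 - j)
    s = len(het)
    if s == 0:
        return np.array([base]), np.array([base])
    het_bits = np.array([1 << (L - 1 - j) for j in het], dtype=np.int64)
    all_het = int(het_bits.sum())
    # fix the first heterozygous SNP to allele 1 on haplotype k: each
    # unordered pair (complementary on het sites) is produced exactly once
    n_pairs = 1 << (s - 1)
    ks = np.empty(n_pairs, dtype=np.int64)
    ls = np.empty(n_pairs, dtype=np.int64)
    for m in range(n_pairs):
        bits = 0
        for t in range(s - 1):
            if (m >> t) & 1:
                bits |= int(het_bits[s - 1 - t])
        k = base | bits
        l = base | (all_het ^ bits)
        ks[m], ls[m] = (k, l) if k <= l else (l, k)
    order = np.lexsort((ls, ks))
    return ks[order], ls[order]


def induced_genotype(pair: HaplotypePair) -> UnphasedGenotype:
    """The unphased genotype obtained by merging the pair's alleles per SNP."""
    return UnphasedGenotype.from_allele_pairs(
        tuple(sorted((a, b)))
        for a, b in zip(pair.first.alleles, pair.second.alleles)
    )
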
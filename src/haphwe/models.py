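"""Haplotype-pair probability models: HWE, Niu's model and the inbreeding model.

Let ``p_h`` be the population frequency of haplotype ``h``.  Under
Hardy-Weinberg equilibrium (HWE) the probability of the unordered pair
``{h_k, h_l}`` is ``p_k**2`` when k == l and ``2 p_k p_l`` otherwise.

Two one-parameter departures from HWE are modelled:

* **Niu's model (NM)** up-weights every homozygous pair by a factor
  ``theta > 0`` and renormalizes: P{k,k} = theta p_k^2 / C,
  P{k,l} = 2 p_k p_l / C with C = 1 + (theta - 1) S, S = sum_h p_h^2.
  theta = 1 recovers HWE.

* **Inbreeding model (IM)**: with probability ``f`` (the inbreeding
  coefficient) an individual's two haplotypes are identical by descent
  (a single draw from the frequencies), otherwise two independent draws:
  P{k,k} = f p_k + (1 - f) p_k^2, P{k,l} = (1 - f) 2 p_k p_l.
  f = 0 recovers HWE.

Both models inflate total homozygosity, which is the signature the
likelihood-ratio tests in :mod:`haphwe.hwe_tests` exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

import numpy as np

from .haplotypes import Haplotype, HaplotypePair

__all__ = [
    "HaplotypeFrequencies",
    "NiuModel",
    "InbreedingModel",
    "hwe_pair_prob",
    "niu_normalizer",
    "niu_pair_prob",
    "inbreeding_pair_prob",
    "pair_prob",
]

_SUM_TOL = 1e-10

HaplotypeKey = Union[Haplotype, str]


def _as_haplotype(h: HaplotypeKey) -> Haplotype:
    return h if isinstance(h, Haplotype) else Haplotype.from_string(h)


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """A haplotype frequency table: mapping haplotype -> p_h, summing to 1."""

    _freqs: dict[Haplotype, float] = field(default_factory=dict)

    def __init__(self, freqs: Mapping[HaplotypeKey, float]) -> None:
        d = {_as_haplotype(h): float(p) for h, p in freqs.items()}
        if not d:
            raise ValueError("empty frequency table")
        lengths = {h.n_snps for h in d}
        if len(lengths) != 1:
            raise ValueError("haplotypes have differing lengths")
        if any(p < 0 for p in d.values()):
            raise ValueError("negative haplotype frequency")
        total = sum(d.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if abs(total - 1.0) > _SUM_TOL:  # renormalize tiny rounding slack
            d = {h: p / total for h, p in d.items()}
        object.__setattr__(self, "_freqs", d)

    def __getitem__(self, h: HaplotypeKey) -> float:
        return self._freqs.get(_as_haplotype(h), 0.0)

    def get(self, h: HaplotypeKey, default: float = 0.0) -> float:
        v = self._freqs.get(_as_haplotype(h))
        return default if v is None else v

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(sorted(self._freqs, key=lambda h: h.code))

    def __len__(self) -> int:
        return len(self._freqs)

    def items(self) -> list[tuple[Haplotype, float]]:
        return [(h, self._freqs[h]) for h in self]

    @property
    def n_snps(self) -> int:
        return next(iter(self._freqs)).n_snps

    @property
    def homozygosity(self) -> float:
        """S = sum_h p_h**2, the probability two random haplotypes coincide."""
        return float(sum(p * p for p in self._freqs.values()))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, probs) sorted by integer haplotype code."""
        hs = sorted(self._freqs, key=lambda h: h.code)
        return (
            np.array([h.code for h in hs], dtype=np.int64),
            np.array([self._freqs[h] for h in hs], dtype=float),
        )

    def to_dict(self) -> dict[str, float]:
        return {str(h): p for h, p in self.items()}


@dataclass(frozen=True)
class NiuModel:
    """Niu's disequilibrium model: homozygous pairs up-weighted by theta."""

    freqs: HaplotypeFrequencies
    theta: float

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")

    @property
    def normalizer(self) -> float:
        return niu_normalizer(self.freqs, self.theta)


@dataclass(frozen=True)
class InbreedingModel:
    """Inbreeding model: IBD with probability f, else two independent draws."""

    freqs: HaplotypeFrequencies
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"inbreeding coefficient must be in [0, 1), got {self.f}")


def hwe_pair_prob(freqs: HaplotypeFrequencies, pair: HaplotypePair) -> float:
    """P{h_k, h_l} under HWE: p_k**2 if homozygous else 2 p_k p_l."""
    pk = freqs.get(pair.first)
    if pair.is_homozygous:
        return pk * pk
    return 2.0 * pk * freqs.get(pair.second)


def niu_normalizer(freqs: HaplotypeFrequencies, theta: float) -> float:
    """The constant C = 1 + (theta - 1) S that renormalizes Niu's model.

    Equals the sum of theta p_k^2 (homozygous) and 2 p_k p_l (heterozygous)
    over all unordered haplotype pairs.
    """
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    return 1.0 + (theta - 1.0) * freqs.homozygosity


def niu_pair_prob(model: NiuModel, pair: HaplotypePair) -> float:
    """P{h_k, h_l} under Niu's model: theta p_k^2 / C or 2 p_k p_l / C."""
    base = hwe_pair_prob(model.freqs, pair)
    if pair.is_homozygous:
        base *= model.theta
    return base / model.normalizer


def inbreeding_pair_prob(model: InbreedingModel, pair: HaplotypePair) -> float:
    """P{h_k, h_l} under the inbreeding model."""
    pk = model.freqs.get(pair.first)
    if pair.is_homozygous:
        return model.f * pk + (1.0 - model.f) * pk * pk
    return (1.0 - model.f) * 2.0 * pk * model.freqs.get(pair.second)


def pair_prob(
    model: HaplotypeFrequencies | NiuModel | InbreedingModel, pair: HaplotypePair
) -> float:
    """Dispatch to the pair probability of whichever model is given."""
    if isinstance(model, HaplotypeFrequencies):
        return hwe_pair_prob(model, pair)
    if isinstance(model, NiuModel):
        return niu_pair_prob(model, pair)
    if isinstance(model, InbreedingModel):
        return inbreeding_pair_prob(model, pair)
    raise TypeError(f"unsupported model type {type(model).__name__}")
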
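import numpy as np
import pytest

from haphwe.models import HaplotypeFrequencies
from haphwe.simulate import STUDY_FREQS


@pytest.fixture(scope="session")
def study_freqs() -> HaplotypeFrequencies:
    """The 5-haplotype, 3-SNP generating distribution of the study."""
    return HaplotypeFrequencies(STUDY_FREQS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20131022)


def random_freqs(rng: np.random.Generator, n_snps: int) -> np.ndarray:
    """A random point on the simplex over all 2**n_snps haplotypes."""
    p = rng.dirichlet(np.ones(2**n_snps))
    return p


def random_dataset(
    rng: np.random.Generator, n_snps: int, n: int
) -> np.ndarray:
    """Random unphased genotypes: two independent haplotype draws per
    individual from a random frequency vector (so every genotype arises)."""
    p = random_freqs(rng, n_snps)
    codes = rng.choice(2**n_snps, size=(n, 2), p=p)
    shifts = np.arange(n_snps - 1, -1, -1)
    bits = ((codes[:, :, None] >> shifts) & 1).sum(axis=1)
    return bits.astype(np.int64)
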
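"""Maximum-likelihood fitting of haplotype-pair models to unphased genotypes.

Three scikit-learn style estimators fit the models of :mod:`haphwe.models`
to an ``(n_individuals, n_snps)`` allele-2 dosage matrix (entries 0, 1, 2):

* :class:`HardyWeinbergEM` — haplotype frequencies under HWE via the
  gene-counting EM of Excoffier & Slatkin;
* :class:`NiuECM` — frequencies plus the homozygote-excess parameter theta
  of Niu's model via expectation-conditional-maximization;
* :class:`InbreedingIEM` — frequencies plus the inbreeding coefficient f
  via EM with a latent identity-by-descent indicator.

All iterate until the observed-data log-likelihood changes by less than
``tol`` and start from a uniform distribution over the haplotypes that are
compatible with at least one observed genotype (theta starts at 1, f at
0.01).  The estimators compose with sklearn pipelines and model selection;
the module-level functions :func:`fit_hwe`, :func:`fit_niu` and
:func:`fit_inbreeding` are thin wrappers returning a :class:`FitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._engine import ClassData, CoreFit, SupportCollapseError, fit_hwe_core, fit_im_core, fit_niu_core
from .haplotypes import Haplotype, UnphasedGenotype, enumerate_compatible_pairs
from .models import HaplotypeFrequencies, InbreedingModel, NiuModel, pair_prob

__all__ = [
    "HardyWeinbergEM",
    "NiuECM",
    "InbreedingIEM",
    "FitResult",
    "fit_hwe",
    "fit_niu",
    "fit_inbreeding",
    "observed_loglik",
    "e_step",
    "SupportCollapseError",
]


@dataclass
class FitResult:
    """Converged estimates from one of the fitters.

    ``loglik_trace`` holds the observed-data log-likelihood at each
    iteration; it is nondecreasing (up to numerical slack) by the EM/ECM
    ascent property.
    """

    model_kind: str  # "HWE" | "NM" | "IM"
    freqs: HaplotypeFrequencies
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    theta_hat: float | None = None
    f_hat: float | None = None
    flags: list[str] = field(default_factory=list)

    @classmethod
    def _from_core(cls, core: CoreFit, n_snps: int) -> "FitResult":
        freqs = HaplotypeFrequencies(
            {
                Haplotype.from_code(int(c), n_snps): float(p)
                for c, p in zip(core.support, core.freqs)
            }
        )
        return cls(
            model_kind=core.model_kind,
            freqs=freqs,
            loglik=core.loglik,
            n_iter=core.n_iter,
            converged=core.converged,
            loglik_trace=core.loglik_trace,
            theta_hat=core.theta,
            f_hat=core.f,
            flags=core.flags,
        )


class _BaseHaplotypeEM(BaseEstimator):
    """Shared fit plumbing for the three haplotype-model estimators."""

    _model_kind = ""

    def __init__(self, tol: float = 1e-6, max_iter: int = 1000) -> None:
        self.tol = tol
        self.max_iter = max_iter

    def _run(self, cd: ClassData) -> CoreFit:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        """Fit to an (n_individuals, n_snps) dosage matrix (entries 0/1/2)."""
        cd = ClassData.from_dosage(np.asarray(X))
        core = self._run(cd)
        self.n_features_in_ = cd.n_snps
        self._core_ = core
        self.haplotype_codes_ = core.support.copy()
        self.freq_ = core.freqs.copy()
        self.frequencies_ = HaplotypeFrequencies(
            {
                Haplotype.from_code(int(c), cd.n_snps): float(p)
                for c, p in zip(core.support, core.freqs)
            }
        )
        self.loglik_ = core.loglik
        self.n_iter_ = core.n_iter
        self.converged_ = core.converged
        self.loglik_trace_ = core.loglik_trace
        return self

    def _fitted_model(self):
        raise NotImplementedError

    def score(self, X, y=None) -> float:
        """Mean per-individual observed-data log-likelihood under the fit."""
        check_is_fitted(self, "loglik_")
        X = np.asarray(X)
        return observed_loglik(self._fitted_model(), X) / X.shape[0]

    def result_(self) -> FitResult:
        """The fit packaged as a :class:`FitResult`."""
        check_is_fitted(self, "loglik_")
        return FitResult._from_core(self._core_, self.n_features_in_)


class HardyWeinbergEM(_BaseHaplotypeEM):
    """Haplotype-frequency estimation under HWE (Excoffier-Slatkin EM).

    Parameters
    ----------
    tol : stop when the observed log-likelihood changes by less than this.
    max_iter : iteration cap; non-convergence is flagged, not raised.

    Attributes
    ----------
    frequencies_ : HaplotypeFrequencies
        Estimated haplotype frequencies over the sample-compatible support.
    loglik_, n_iter_, converged_, loglik_trace_ : fit diagnostics.
    """

    _model_kind = "HWE"

    def _run(self, cd: ClassData) -> CoreFit:
        return fit_hwe_core(cd, self.tol, self.max_iter)

    def _fitted_model(self):
        return self.frequencies_


class NiuECM(_BaseHaplotypeEM):
    """Niu's-model fit by ECM: one E-step then conditional maximizations.

    The first CM-step updates theta in closed form; the remaining ones
    update each free haplotype frequency as the admissible root of a cubic,
    with the initially most frequent haplotype absorbing the simplex
    constraint.

    Attributes
    ----------
    theta_ : float
        Estimated homozygote-excess parameter (1 = HWE).
    """

    _model_kind = "NM"

    def __init__(
        self,
        tol: float = 1e-6,
        max_iter: int = 1000,
        theta0: float = 1.0,
        theta_max: float = 1e3,
    ) -> None:
        super().__init__(tol=tol, max_iter=max_iter)
        self.theta0 = theta0
        self.theta_max = theta_max

    def _run(self, cd: ClassData) -> CoreFit:
        return fit_niu_core(
            cd, self.tol, self.max_iter, theta0=self.theta0, theta_max=self.theta_max
        )

    def fit(self, X, y=None):
        super().fit(X)
        self.theta_ = self._core_.theta
        return self

    def _fitted_model(self):
        return NiuModel(self.frequencies_, self.theta_)


class InbreedingIEM(_BaseHaplotypeEM):
    """Inbreeding-model fit by EM over pair + identity-by-descent latents.

    Attributes
    ----------
    f_ : float
        Estimated inbreeding coefficient, clipped to [0, 1).
    """

    _model_kind = "IM"

    def __init__(self, tol: float = 1e-6, max_iter: int = 1000, f0: float = 0.01) -> None:
        super().__init__(tol=tol, max_iter=max_iter)
        self.f0 = f0

    def _run(self, cd: ClassData) -> CoreFit:
        return fit_im_core(cd, self.tol, self.max_iter, f0=self.f0)

    def fit(self, X, y=None):
        super().fit(X)
        self.f_ = self._core_.f
        return self

    def _fitted_model(self):
        return InbreedingModel(self.frequencies_, self.f_)


def fit_hwe(X, tol: float = 1e-6, max_iter: int = 1000) -> FitResult:
    """EM fit of haplotype frequencies under HWE."""
    return HardyWeinbergEM(tol=tol, max_iter=max_iter).fit(X).result_()


def fit_niu(X, tol: float = 1e-6, max_iter: int = 1000, **kwargs) -> FitResult:
    """ECM fit of Niu's model (frequencies and theta)."""
    return NiuECM(tol=tol, max_iter=max_iter, **kwargs).fit(X).result_()


def fit_inbreeding(X, tol: float = 1e-6, max_iter: int = 1000, **kwargs) -> FitResult:
    """IEM fit of the inbreeding model (frequencies and f)."""
    return InbreedingIEM(tol=tol, max_iter=max_iter, **kwargs).fit(X).result_()


def _individual_pair_probs(model, X: np.ndarray) -> list[np.ndarray]:
    X = np.asarray(X)
    out = []
    for i, row in enumerate(X):
        pairs = enumerate_compatible_pairs(UnphasedGenotype.from_dosage(row))
        probs = np.array([pair_prob(model, pr) for pr in pairs])
        if probs.sum() <= 0.0:
            raise SupportCollapseError(
                f"all compatible haplotype pairs of individual {i} have "
                "probability 0 under the given model"
            )
        out.append(probs)
    return out


def observed_loglik(
    model: HaplotypeFrequencies | NiuModel | InbreedingModel, X
) -> float:
    """Observed-data log-likelihood sum_i log sum_j P(pair_ij | model).

    ``X`` is the (n, n_snps) dosage matrix; pair enumeration follows
    :func:`haphwe.haplotypes.enumerate_compatible_pairs`.
    """
    return float(
        sum(np.log(probs.sum()) for probs in _individual_pair_probs(model, X))
    )


def e_step(
    model: HaplotypeFrequencies | NiuModel | InbreedingModel, X
) -> list[np.ndarray]:
    """Posterior weights over each individual's compatible pairs.

    Returns one array per individual, aligned with the deterministic order
    of :func:`enumerate_compatible_pairs`; each array sums to 1.
    """
    return [probs / probs.sum() for probs in _individual_pair_probs(model, X)]
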
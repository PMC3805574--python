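"""Likelihood-ratio tests for haplotype-based Hardy-Weinberg equilibrium.

Each test compares the HWE null fit against a one-parameter disequilibrium
alternative fitted on the same unphased genotypes:

* ``LRT_NM``: alternative is Niu's model (homozygote excess theta),
* ``LRT_IM``: alternative is the inbreeding model (coefficient f).

The statistic 2 (l_alt - l_null) is referred to a chi-square distribution
with 1 degree of freedom.  For ``LRT_IM`` the null value f = 0 sits on the
parameter boundary, which makes the plain chi-square reference
conservative; the more accurate half-half mixture of chi-square(0) and
chi-square(1) is available via ``mixture=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .estimators import FitResult, fit_hwe, fit_inbreeding, fit_niu

__all__ = ["TestResult", "lrt_nm", "lrt_im", "lrt_from_fits"]


@dataclass
class TestResult:
    """Outcome of one haplotype-based HWE likelihood-ratio test."""

    test_kind: str  # "LRT_NM" | "LRT_IM"
    statistic: float
    df: int
    p_value: float
    null_fit: FitResult
    alt_fit: FitResult

    @property
    def converged(self) -> bool:
        return self.null_fit.converged and self.alt_fit.converged


def _pvalue(stat: float, mixture: bool) -> float:
    p = float(chi2.sf(stat, df=1))
    if mixture:
        # boundary null: 0.5 chi2_0 + 0.5 chi2_1
        p = 1.0 if stat <= 0.0 else 0.5 * p
    return p


def lrt_from_fits(
    null_fit: FitResult, alt_fit: FitResult, mixture: bool = False
) -> TestResult:
    """Assemble a test result from pre-computed null and alternative fits."""
    stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    # near the f = 0 / theta = 1 boundary the alternative fitter may stop a
    # few stopping-tolerances short of the null's log-likelihood; that is a
    # zero statistic, not a failure
    if stat < -1e-2:
        raise ValueError(
            f"alternative log-likelihood fell below the null by {-stat / 2:.3g}; "
            "the alternative fit did not reach its optimum"
        )
    stat = max(stat, 0.0)
    kind = "LRT_NM" if alt_fit.model_kind == "NM" else "LRT_IM"
    return TestResult(
        test_kind=kind,
        statistic=stat,
        df=1,
        p_value=_pvalue(stat, mixture),
        null_fit=null_fit,
        alt_fit=alt_fit,
    )


def lrt_nm(X, tol: float = 1e-6, max_iter: int = 1000, **kwargs) -> TestResult:
    """Test HWE against Niu's model on a dosage matrix ``X``."""
    null_fit = fit_hwe(X, tol=tol, max_iter=max_iter)
    alt_fit = fit_niu(X, tol=tol, max_iter=max_iter, **kwargs)
    return lrt_from_fits(null_fit, alt_fit)


def lrt_im(
    X, tol: float = 1e-6, max_iter: int = 1000, mixture: bool = False, **kwargs
) -> TestResult:
    """Test HWE against the inbreeding model on a dosage matrix ``X``."""
    null_fit = fit_hwe(X, tol=tol, max_iter=max_iter)
    alt_fit = fit_inbreeding(X, tol=tol, max_iter=max_iter, **kwargs)
    return lrt_from_fits(null_fit, alt_fit, mixture=mixture)
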
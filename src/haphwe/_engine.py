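"""Vectorized EM / ECM / IEM fitting engine.

Genotype data enter as an ``(n, L)`` allele-2 dosage matrix.  Individuals
are collapsed into distinct genotype classes with multiplicities (at most
``3**L`` classes), which preserves every expectation sum exactly while
making each EM iteration a handful of vectorized operations over the pooled
list of (class, haplotype pair) entries.

The three fitters share the same E-step machinery and differ only in the
pair-probability model and the M-step:

* EM (HWE): gene-counting update of Excoffier & Slatkin.
* ECM (Niu's model): one E-step, then a closed-form conditional update of
  theta followed by one conditional update per free haplotype frequency,
  each the root of a cubic (the absorbing haplotype soaks up the simplex
  constraint).
* IEM (inbreeding model): EM with an extra latent identity-by-descent
  indicator per individual; its posterior drives the update of f and
  re-weights the haplotype draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["ClassData", "CoreFit", "fit_hwe_core", "fit_niu_core", "fit_im_core"]

_LL_SLACK = 1e-9  # tolerated numeric dip in the likelihood trace


class SupportCollapseError(ValueError):
    """Every compatible pair of some genotype has probability zero."""


@dataclass
class ClassData:
    """Genotype classes with multiplicities and their compatible pairs.

    Attributes
    ----------
    support : (H,) int array of haplotype codes occurring in at least one
        compatible pair of the sample, sorted.
    pair_k, pair_l : support indices of each pooled pair, k <= l.
    pair_class : class index of each pooled pair.
    hom : boolean, pair is haplotype-homozygous.
    class_counts : multiplicity of each class.
    class_rep : index of one individual per class (for error messages).
    """

    n: int
    n_snps: int
    support: np.ndarray
    pair_k: np.ndarray
    pair_l: np.ndarray
    pair_class: np.ndarray
    hom: np.ndarray
    class_counts: np.ndarray
    class_rep: np.ndarray
    n_classes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_classes = len(self.class_counts)

    @classmethod
    def from_dosage(cls, X: np.ndarray) -> "ClassData":
        from .haplotypes import _compatible_pair_codes

        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError(f"expected a 2-D genotype matrix, got shape {X.shape}")
        if np.issubdtype(X.dtype, np.floating) and np.isnan(X).any():
            bad = int(np.flatnonzero(np.isnan(X).any(axis=1))[0])
            raise ValueError(f"missing genotype for individual {bad}; filter first")
        X = X.astype(np.int64, copy=False)
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("empty genotype matrix")
        if ((X < 0) | (X > 2)).any():
            bad = int(np.flatnonzero(((X < 0) | (X > 2)).any(axis=1))[0])
            raise ValueError(
                f"invalid or missing dosage for individual {bad}; "
                "entries must be 0, 1 or 2"
            )
        n, L = X.shape
        uniq, first_idx, counts = np.unique(
            X, axis=0, return_index=True, return_counts=True
        )
        ks, ls, cls_idx = [], [], []
        for c, row in enumerate(uniq):
            k, l = _compatible_pair_codes(row, L)
            ks.append(k)
            ls.append(l)
            cls_idx.append(np.full(len(k), c, dtype=np.int64))
        pair_k_codes = np.concatenate(ks)
        pair_l_codes = np.concatenate(ls)
        support = np.unique(np.concatenate([pair_k_codes, pair_l_codes]))
        pair_k = np.searchsorted(support, pair_k_codes)
        pair_l = np.searchsorted(support, pair_l_codes)
        return cls(
            n=n,
            n_snps=L,
            support=support,
            pair_k=pair_k,
            pair_l=pair_l,
            pair_class=np.concatenate(cls_idx),
            hom=pair_k == pair_l,
            class_counts=counts.astype(float),
            class_rep=first_idx,
        )

    @property
    def n_support(self) -> int:
        return len(self.support)


@dataclass
class CoreFit:
    """Converged parameter estimates from one of the fitters."""

    model_kind: str  # "HWE" | "NM" | "IM"
    support: np.ndarray  # haplotype codes
    freqs: np.ndarray  # estimated frequencies over `support`
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    theta: float | None = None
    f: float | None = None
    flags: list[str] = field(default_factory=list)


def _estep(cd: ClassData, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior pair weights scaled by class multiplicity, and the loglik."""
    denom = np.bincount(cd.pair_class, weights=q, minlength=cd.n_classes)
    if (denom <= 0.0).any():
        bad = int(cd.class_rep[np.flatnonzero(denom <= 0.0)[0]])
        raise SupportCollapseError(
            f"all compatible haplotype pairs of individual {bad} have "
            "probability 0 under the current model"
        )
    w = q / denom[cd.pair_class]
    W = w * cd.class_counts[cd.pair_class]
    loglik = float(cd.class_counts @ np.log(denom))
    return W, loglik


def _expected_counts(cd: ClassData, W: np.ndarray) -> np.ndarray:
    """Expected number of copies of each support haplotype (sums to 2n)."""
    contrib_k = W * np.where(cd.hom, 2.0, 1.0)
    contrib_l = W * np.where(cd.hom, 0.0, 1.0)
    return np.bincount(
        cd.pair_k, weights=contrib_k, minlength=cd.n_support
    ) + np.bincount(cd.pair_l, weights=contrib_l, minlength=cd.n_support)


def _q_hwe(cd: ClassData, p: np.ndarray) -> np.ndarray:
    return p[cd.pair_k] * p[cd.pair_l] * np.where(cd.hom, 1.0, 2.0)


def _q_niu(cd: ClassData, p: np.ndarray, theta: float) -> np.ndarray:
    C = 1.0 + (theta - 1.0) * float(p @ p)
    return _q_hwe(cd, p) * np.where(cd.hom, theta, 1.0) / C


def _q_im(cd: ClassData, p: np.ndarray, f: float) -> np.ndarray:
    hwe = _q_hwe(cd, p)
    return np.where(cd.hom, f * p[cd.pair_k] + (1.0 - f) * hwe, (1.0 - f) * hwe)


def _init_freqs(cd: ClassData, p0: np.ndarray | None) -> np.ndarray:
    if p0 is None:
        return np.full(cd.n_support, 1.0 / cd.n_support)
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (cd.n_support,) or (p0 < 0).any() or p0.sum() <= 0:
        raise ValueError("p0 must be a nonnegative vector over the support")
    return p0 / p0.sum()


def fit_hwe_core(
    cd: ClassData, tol: float, max_iter: int, p0: np.ndarray | None = None
) -> CoreFit:
    """Excoffier-Slatkin EM for haplotype frequencies under HWE."""
    p = _init_freqs(cd, p0)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        W, ll = _estep(cd, _q_hwe(cd, p))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        p = _expected_counts(cd, W) / (2.0 * cd.n)
    return CoreFit(
        "HWE", cd.support, p, trace[-1], len(trace), converged, np.array(trace)
    )


def _theta_cm_step(m: float, n: int, S: float, theta_max: float, flags: list[str]) -> float:
    """Closed-form conditional maximizer of Q in theta.

    dQ/dtheta = m/theta - n S / (1 + (theta - 1) S) = 0 gives
    theta = m (1 - S) / (S (n - m)) with m the expected number of
    haplotype-homozygous individuals and S = sum p_h^2.
    """
    if m <= 0.0:
        flags.append("theta_floor")
        return 1e-6
    if m >= n - 1e-12:
        flags.append("theta_cap")
        return theta_max
    theta = m * (1.0 - S) / (S * (n - m))
    if theta > theta_max:
        flags.append("theta_cap")
        return theta_max
    return max(theta, 1e-6)


def _q_slice(x: float, A: float, B: float, r: float, n: int, D: float, K: float) -> float:
    """Q-function restricted to one free frequency x (absorbing one gets r - x)."""
    val = 0.0
    if A > 0.0:
        if x <= 0.0:
            return -np.inf
        val += A * np.log(x)
    if B > 0.0:
        if x >= r:
            return -np.inf
        val += B * np.log(r - x)
    C = K + 2.0 * D * x * x - 2.0 * D * r * x
    if C <= 0.0:
        return -np.inf
    return val - n * np.log(C)


def _freq_cm_step(
    x_prev: float,
    A: float,
    B: float,
    r: float,
    n: int,
    theta: float,
    S_rest: float,
    flags: list[str],
) -> float:
    """Conditional maximizer of Q over one haplotype frequency in [0, r].

    With D = theta - 1 and K = 1 + D (r^2 + S_rest), setting dQ/dx = 0 and
    clearing denominators yields the cubic
        a x^3 + b x^2 + c x + d = 0,
        a = 2 D (2n - A - B),      b = 2 D r (2A + B - 3n),
        c = -K (A + B) + 2 D r^2 (n - A),   d = A r K,
    whose admissible root maximizing Q is returned (ties broken toward the
    previous value).  Falls back to bounded numeric maximization if the
    root set fails to improve Q.
    """
    if r <= 0.0:
        return 0.0
    D = theta - 1.0
    K = 1.0 + D * (r * r + S_rest)
    if abs(D) < 1e-12:
        # theta = 1: plain gene-counting split of the mass r
        return x_prev if A + B <= 0.0 else r * A / (A + B)
    coeffs = np.array(
        [
            2.0 * D * (2.0 * n - A - B),
            2.0 * D * r * (2.0 * A + B - 3.0 * n),
            -K * (A + B) + 2.0 * D * r * r * (n - A),
            A * r * K,
        ]
    )
    nz = np.flatnonzero(np.abs(coeffs) > 1e-300)
    candidates: list[float] = []
    if len(nz) and nz[0] < 3:
        roots = np.roots(coeffs[nz[0] :])
        for z in roots:
            if abs(z.imag) < 1e-8 * max(1.0, abs(z)):
                x = float(np.clip(z.real, 0.0, r))
                candidates.append(x)
    # boundaries are admissible only when the matching log term is absent
    if A <= 0.0:
        candidates.append(0.0)
    if B <= 0.0:
        candidates.append(r)
    q_prev = _q_slice(x_prev, A, B, r, n, D, K)
    q_vals = [_q_slice(x, A, B, r, n, D, K) for x in candidates]
    best = max(q_vals, default=-np.inf)
    if not np.isfinite(best) or best < q_prev - 1e-9:
        res = minimize_scalar(
            lambda x: -_q_slice(x, A, B, r, n, D, K),
            bounds=(0.0, r),
            method="bounded",
            options={"xatol": 1e-12},
        )
        flags.append("freq_cm_numeric")
        x_num = float(res.x)
        if _q_slice(x_num, A, B, r, n, D, K) >= q_prev:
            return x_num
        flags.append("freq_cm_kept_previous")
        return x_prev
    # among near-ties pick the root closest to the previous value
    close = [x for x, q in zip(candidates, q_vals) if q >= best - 1e-12]
    return min(close, key=lambda x: abs(x - x_prev))


def fit_niu_core(
    cd: ClassData,
    tol: float,
    max_iter: int,
    theta0: float = 1.0,
    theta_max: float = 1e3,
    p0: np.ndarray | None = None,
) -> CoreFit:
    """ECM for Niu's model: E-step, theta CM-step, then one CM-step per
    free haplotype frequency with the absorbing haplotype holding the
    simplex constraint."""
    H = cd.n_support
    p = _init_freqs(cd, p0)
    theta = theta0
    flags: list[str] = []
    trace: list[float] = []
    converged = False
    absorbing: int | None = None
    for _ in range(max_iter):
        W, ll = _estep(cd, _q_niu(cd, p, theta))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        counts = _expected_counts(cd, W)  # A_h, fixed within the iteration
        if absorbing is None:
            # highest expected frequency at initialization (first tie wins)
            absorbing = int(np.argmax(counts))
        m = float(W[cd.hom].sum())
        S = float(p @ p)
        theta = _theta_cm_step(m, cd.n, S, theta_max, flags)
        B = float(counts[absorbing])
        for h in range(H):
            if h == absorbing:
                continue
            r = p[h] + p[absorbing]
            S_rest = float(p @ p) - p[h] ** 2 - p[absorbing] ** 2
            x = _freq_cm_step(
                float(p[h]), float(counts[h]), B, float(r), cd.n, theta, S_rest, flags
            )
            p[h] = x
            p[absorbing] = r - x
    return CoreFit(
        "NM",
        cd.support,
        p,
        trace[-1],
        len(trace),
        converged,
        np.array(trace),
        theta=theta,
        flags=sorted(set(flags)),
    )


def fit_im_core(
    cd: ClassData,
    tol: float,
    max_iter: int,
    f0: float = 0.01,
    p0: np.ndarray | None = None,
) -> CoreFit:
    """IEM for the inbreeding model.

    E-step adds, for each haplotype-homozygous pair (k, k), the posterior
    identity-by-descent probability b = f / (f + (1 - f) p_k).  M-step:
    f <- (1/n) sum w b; haplotype counts weight IBD individuals as a single
    draw of their shared haplotype, so p_h <- counts_h / (2n - sum w b).
    """
    p = _init_freqs(cd, p0)
    f = f0
    trace: list[float] = []
    flags: list[str] = []
    converged = False
    for _ in range(max_iter):
        W, ll = _estep(cd, _q_im(cd, p, f))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        pk = p[cd.pair_k]
        denom_b = f + (1.0 - f) * pk
        b = np.where(cd.hom & (denom_b > 0.0), f / np.maximum(denom_b, 1e-300), 0.0)
        Wb = W * b
        sum_wb = float(Wb[cd.hom].sum())
        contrib_k = W * np.where(cd.hom, 2.0, 1.0) - Wb * cd.hom
        contrib_l = W * np.where(cd.hom, 0.0, 1.0)
        counts = np.bincount(
            cd.pair_k, weights=contrib_k, minlength=cd.n_support
        ) + np.bincount(cd.pair_l, weights=contrib_l, minlength=cd.n_support)
        f = float(np.clip(sum_wb / cd.n, 0.0, 1.0 - 1e-9))
        if f >= 1.0 - 2e-9:
            flags.append("f_cap")
        p = counts / (2.0 * cd.n - sum_wb)
    return CoreFit(
        "IM",
        cd.support,
        p,
        trace[-1],
        len(trace),
        converged,
        np.array(trace),
        f=f,
        flags=sorted(set(flags)),
    )
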
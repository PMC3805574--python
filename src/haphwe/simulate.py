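"""Simulation engine: genotype samplers and the size/power/accuracy study.

Samples of unrelated individuals at three tightly linked SNPs (no
recombination) are generated under four population models:

* ``HWE`` — two independent haplotype draws per individual;
* ``NM`` — unordered pairs drawn from Niu's disequilibrium distribution;
* ``IM`` — pairs drawn from the inbreeding-model distribution;
* ``PS`` — a two-subpopulation mixture, HWE within each subpopulation.

The NM/IM generating haplotype distribution (:data:`STUDY_FREQS`) and the
two subpopulation distributions (:data:`STRATIFIED_FREQS_I` / ``_II``)
are the study conditions used throughout; samplers draw the unordered
haplotype pair of each individual exactly from the model's pair
distribution and emit the induced unphased genotype.

:func:`run_study` repeats sample -> fit (EM/ECM/IEM) -> test (LRT_NM,
LRT_IM) over replicates and aggregates parameter estimates, estimation
accuracy (sum of absolute differences, SAD) and rejection rates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._engine import ClassData, fit_hwe_core, fit_im_core, fit_niu_core
from .models import HaplotypeFrequencies

__all__ = [
    "STUDY_FREQS",
    "STRATIFIED_FREQS_I",
    "STRATIFIED_FREQS_II",
    "GeneratingModel",
    "SettingResult",
    "StudyResult",
    "sample_individuals",
    "sad",
    "simulate_setting",
    "run_study",
]

#: Generating haplotype distribution for the NM and IM study conditions.
STUDY_FREQS: dict[str, float] = {
    "122": 0.082,
    "221": 0.525,
    "121": 0.283,
    "211": 0.004,
    "111": 0.106,
}

#: Subpopulation I haplotype distribution for the stratified (PS) model.
STRATIFIED_FREQS_I: dict[str, float] = {
    "122": 0.082,
    "212": 0.000,
    "112": 0.000,
    "221": 0.525,
    "121": 0.283,
    "211": 0.004,
    "111": 0.106,
}

#: Subpopulation II haplotype distribution for the stratified (PS) model.
STRATIFIED_FREQS_II: dict[str, float] = {
    "122": 0.030,
    "212": 0.170,
    "112": 0.050,
    "221": 0.470,
    "121": 0.100,
    "211": 0.150,
    "111": 0.030,
}


@dataclass(frozen=True)
class GeneratingModel:
    """A population model genotype samples are drawn from.

    ``kind`` selects the model; ``freqs`` is the haplotype distribution
    (for PS, subpopulation I; ``freqs_ii`` is subpopulation II and
    ``lam`` the proportion of subpopulation I).
    """

    kind: str  # "HWE" | "NM" | "IM" | "PS"
    freqs: Mapping[str, float] = field(default_factory=lambda: dict(STUDY_FREQS))
    theta: float = 1.0
    f: float = 0.0
    freqs_ii: Mapping[str, float] | None = None
    lam: float = 0.6

    def __post_init__(self) -> None:
        if self.kind not in ("HWE", "NM", "IM", "PS"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "NM" and not self.theta > 0:
            raise ValueError("theta must be positive")
        if self.kind == "IM" and not 0.0 <= self.f < 1.0:
            raise ValueError("f must be in [0, 1)")
        if self.kind == "PS":
            if self.freqs_ii is None:
                raise ValueError("PS model needs freqs_ii")
            if not 0.0 < self.lam < 1.0:
                raise ValueError("lam must be in (0, 1)")

    @classmethod
    def stratified(cls, lam: float) -> "GeneratingModel":
        """The two-subpopulation study condition with proportion ``lam``."""
        return cls(
            kind="PS",
            freqs=dict(STRATIFIED_FREQS_I),
            freqs_ii=dict(STRATIFIED_FREQS_II),
            lam=lam,
        )

    @property
    def parameter(self) -> float:
        """The scalar the study grid varies (theta, f or lam; 1/0 for HWE)."""
        return {"HWE": 1.0, "NM": self.theta, "IM": self.f, "PS": self.lam}[self.kind]


def _pair_table(freqs: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(codes, p, L): haplotype codes and probabilities, sorted by code."""
    hf = HaplotypeFrequencies(freqs)
    codes, p = hf.as_arrays()
    return codes, p, hf.n_snps


def _hwe_pair_probs(p: np.ndarray, iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    i, j = iu
    q = p[i] * p[j] * np.where(i == j, 1.0, 2.0)
    return q


def pair_distribution(model: GeneratingModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Exact unordered-pair distribution (codes_k, codes_l, prob, n_snps)."""
    if model.kind == "PS":
        # mixture over the union support of the two subpopulations
        union = sorted(set(model.freqs) | set(model.freqs_ii or {}))
        fa = {h: model.freqs.get(h, 0.0) for h in union}
        fb = {h: (model.freqs_ii or {}).get(h, 0.0) for h in union}
        codes, pa, L = _pair_table(fa)
        _, pb, _ = _pair_table(fb)
        iu = np.triu_indices(len(codes))
        prob = model.lam * _hwe_pair_probs(pa, iu) + (1.0 - model.lam) * _hwe_pair_probs(pb, iu)
    else:
        codes, p, L = _pair_table(model.freqs)
        iu = np.triu_indices(len(codes))
        hom = iu[0] == iu[1]
        prob = _hwe_pair_probs(p, iu)
        if model.kind == "NM":
            S = float(p @ p)
            prob = prob * np.where(hom, model.theta, 1.0) / (1.0 + (model.theta - 1.0) * S)
        elif model.kind == "IM":
            prob = np.where(
                hom, model.f * p[iu[0]] + (1.0 - model.f) * prob, (1.0 - model.f) * prob
            )
    keep = prob > 0.0
    return codes[iu[0]][keep], codes[iu[1]][keep], prob[keep], L


def _codes_to_dosage(k: np.ndarray, l: np.ndarray, L: int) -> np.ndarray:
    """Per-SNP allele-2 dosage of the genotype induced by each pair."""
    shifts = np.arange(L - 1, -1, -1)
    bits_k = (k[:, None] >> shifts) & 1
    bits_l = (l[:, None] >> shifts) & 1
    return (bits_k + bits_l).astype(np.int64)


def sample_individuals(
    model: GeneratingModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` unphased genotypes (dosage matrix) under ``model``.

    Each individual's unordered haplotype pair is drawn exactly from the
    model's pair distribution, then collapsed to its induced genotype.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ks, ls, prob, L = pair_distribution(model)
    idx = rng.choice(len(prob), size=n, p=prob / prob.sum())
    return _codes_to_dosage(ks[idx], ls[idx], L)


def sad(true_freqs: Mapping[str, float], est_freqs: Mapping[str, float]) -> float:
    """Sum of absolute differences between two haplotype frequency tables.

    Taken over the union of the two supports (absent entries count as 0);
    0 means perfect estimation, the maximum is 2.
    """
    universe = set(true_freqs) | set(est_freqs)
    return float(
        sum(abs(true_freqs.get(h, 0.0) - est_freqs.get(h, 0.0)) for h in universe)
    )


def _sad_arrays(
    true_codes: np.ndarray, true_p: np.ndarray, est_codes: np.ndarray, est_p: np.ndarray
) -> float:
    universe = np.union1d(true_codes, est_codes)
    t = np.zeros(len(universe))
    e = np.zeros(len(universe))
    t[np.searchsorted(universe, true_codes)] = true_p
    e[np.searchsorted(universe, est_codes)] = est_p
    return float(np.abs(t - e).sum())


@dataclass
class SettingResult:
    """Aggregates over replicates at one (model, parameter, n) setting."""

    kind: str
    parameter: float
    n: int
    n_replicates: int
    alpha: float
    seed: int
    theta_mean: float
    theta_sd: float
    f_mean: float
    f_sd: float
    sad_em: float
    sad_ecm: float
    sad_iem: float
    sad_em_sd: float
    sad_ecm_sd: float
    sad_iem_sd: float
    reject_nm: float
    reject_im: float
    n_nonconverged: int

    def as_row(self) -> dict:
        return dict(self.__dict__)


@dataclass
class StudyResult:
    """Tidy per-setting table mirroring the simulation-study layout."""

    table: pd.DataFrame
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def simulate_setting(
    model: GeneratingModel,
    n: int,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SettingResult:
    """Run one grid cell: sample, fit all three models, test, aggregate."""
    crit = float(chi2.isf(alpha, df=1))
    true_codes, true_p, L = _pair_table(model.freqs)
    if model.kind == "PS":
        # marginal haplotype distribution of the mixture is the SAD truth
        union = sorted(set(model.freqs) | set(model.freqs_ii or {}))
        mix = {
            h: model.lam * model.freqs.get(h, 0.0)
            + (1.0 - model.lam) * (model.freqs_ii or {}).get(h, 0.0)
            for h in union
        }
        true_codes, true_p, L = _pair_table(mix)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    thetas = np.empty(n_replicates)
    fs = np.empty(n_replicates)
    sads = np.empty((n_replicates, 3))
    rej = np.zeros((n_replicates, 2), dtype=bool)
    n_nonconv = 0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        X = sample_individuals(model, n, rng)
        cd = ClassData.from_dosage(X)
        hwe = fit_hwe_core(cd, tol, max_iter)
        nm = fit_niu_core(cd, tol, max_iter)
        im = fit_im_core(cd, tol, max_iter)
        if not (hwe.converged and nm.converged and im.converged):
            n_nonconv += 1
        thetas[r] = nm.theta
        fs[r] = im.f
        sads[r, 0] = _sad_arrays(true_codes, true_p, hwe.support, hwe.freqs)
        sads[r, 1] = _sad_arrays(true_codes, true_p, nm.support, nm.freqs)
        sads[r, 2] = _sad_arrays(true_codes, true_p, im.support, im.freqs)
        rej[r, 0] = max(2.0 * (nm.loglik - hwe.loglik), 0.0) > crit
        rej[r, 1] = max(2.0 * (im.loglik - hwe.loglik), 0.0) > crit
    return SettingResult(
        kind=model.kind,
        parameter=model.parameter,
        n=n,
        n_replicates=n_replicates,
        alpha=alpha,
        seed=seed,
        theta_mean=float(thetas.mean()),
        theta_sd=float(thetas.std(ddof=1)) if n_replicates > 1 else 0.0,
        f_mean=float(fs.mean()),
        f_sd=float(fs.std(ddof=1)) if n_replicates > 1 else 0.0,
        sad_em=float(sads[:, 0].mean()),
        sad_ecm=float(sads[:, 1].mean()),
        sad_iem=float(sads[:, 2].mean()),
        sad_em_sd=float(sads[:, 0].std(ddof=1)) if n_replicates > 1 else 0.0,
        sad_ecm_sd=float(sads[:, 1].std(ddof=1)) if n_replicates > 1 else 0.0,
        sad_iem_sd=float(sads[:, 2].std(ddof=1)) if n_replicates > 1 else 0.0,
        reject_nm=float(rej[:, 0].mean()),
        reject_im=float(rej[:, 1].mean()),
        n_nonconverged=n_nonconv,
    )


def run_study(config: Mapping) -> StudyResult:
    """Run a grid of settings described by a flat configuration mapping.

    Keys: ``kind`` ("HWE"/"NM"/"IM"/"PS"), ``parameters`` (list of theta,
    f or lambda values; ignored for HWE), ``sample_sizes``, ``replicates``,
    ``alpha``, ``seed`` and optionally ``tol`` / ``max_iter``.  Every cell
    gets a deterministic per-cell seed derived from the master seed.
    """
    kind = config["kind"]
    params = list(config.get("parameters", [1.0 if kind != "IM" else 0.0]))
    sizes = [int(s) for s in config.get("sample_sizes", [1000])]
    reps = int(config.get("replicates", 1000))
    alpha = float(config.get("alpha", 0.05))
    seed = int(config.get("seed", 0))
    tol = float(config.get("tol", 1e-6))
    max_iter = int(config.get("max_iter", 1000))
    rows = []
    for cell, (n, par) in enumerate(itertools.product(sizes, params)):
        if kind == "HWE":
            model = GeneratingModel(kind="HWE")
        elif kind == "NM":
            model = GeneratingModel(kind="NM", theta=float(par))
        elif kind == "IM":
            model = GeneratingModel(kind="IM", f=float(par))
        else:
            model = GeneratingModel.stratified(float(par))
        cell_seed = int(
            np.random.SeedSequence(seed, spawn_key=(cell,)).generate_state(1)[0]
            % (2**31)
        )
        rows.append(
            simulate_setting(
                model, n, reps, alpha=alpha, seed=cell_seed, tol=tol, max_iter=max_iter
            ).as_row()
        )
    return StudyResult(table=pd.DataFrame(rows), seed=seed)
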
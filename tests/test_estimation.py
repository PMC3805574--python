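"""EM / ECM / IEM fitting: likelihood values, CM-step oracles, recovery."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import clone

from haphwe._engine import (
    ClassData,
    _freq_cm_step,
    _q_slice,
    _theta_cm_step,
    fit_hwe_core,
    fit_im_core,
    fit_niu_core,
)
from haphwe.estimators import (
    HardyWeinbergEM,
    InbreedingIEM,
    NiuECM,
    SupportCollapseError,
    e_step,
    fit_hwe,
    fit_inbreeding,
    fit_niu,
    observed_loglik,
)
from haphwe.models import HaplotypeFrequencies, NiuModel

from conftest import random_dataset


def _uniform8() -> HaplotypeFrequencies:
    """Uniform distribution over all 8 haplotypes at 3 SNPs."""
    labels = ["".join("12"[(c >> (2 - j)) & 1] for j in range(3)) for c in range(8)]
    return HaplotypeFrequencies({lab: 1 / 8 for lab in labels})


class TestObservedLoglik:
    def test_single_homozygote(self, study_freqs):
        # genotype (1/1, 2/2, 1/1) is exactly the 121/121 pair
        X = np.array([[0, 2, 0]])
        assert observed_loglik(study_freqs, X) == pytest.approx(
            np.log(0.283**2), abs=1e-9
        )

    def test_niu_theta_one_equals_hwe(self, rng):
        X = random_dataset(rng, 3, 40)
        freqs = _uniform8()
        assert observed_loglik(NiuModel(freqs, 1.0), X) == pytest.approx(
            observed_loglik(freqs, X), abs=1e-12
        )

    def test_support_collapse_names_individual(self, study_freqs):
        # both pairs of (1/2, 1/1, 1/2) need haplotypes 212 or 112,
        # which have frequency 0 in the study table
        X = np.array([[0, 2, 0], [1, 0, 1]])
        with pytest.raises(SupportCollapseError, match="individual 1"):
            observed_loglik(study_freqs, X)


class TestEStep:
    def test_homozygote_single_weight(self, study_freqs):
        (w,) = e_step(study_freqs, np.array([[0, 2, 0]]))
        assert w.tolist() == [1.0]

    def test_uniform_freqs_symmetric_weights(self):
        (w,) = e_step(_uniform8(), np.array([[1, 0, 1]]))
        assert w == pytest.approx([0.5, 0.5])

    def test_rows_sum_to_one(self, rng):
        X = random_dataset(rng, 3, 30)
        for w in e_step(_uniform8(), X):
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()


class TestHweEM:
    def test_homozygous_data_is_direct_counting(self):
        # all individuals fully homozygous: no phase ambiguity at all
        X = np.array([[0, 0], [0, 0], [2, 2], [0, 0], [2, 2], [0, 2]])
        res = fit_hwe(X)
        assert res.converged
        # 2n = 12 chromosomes: 11 x6, 22 x4, 12 x2
        assert res.freqs["11"] == pytest.approx(6 / 12)
        assert res.freqs["22"] == pytest.approx(4 / 12)
        assert res.freqs["12"] == pytest.approx(2 / 12)

    def test_double_heterozygote_resolution(self):
        """{11x11, 22x22, 12 double het}: the MLE puts all mass on
        haplotypes 11 and 22 and resolves the double heterozygote."""
        X = np.array([[0, 0], [2, 2], [1, 1]])
        res = fit_hwe(X, tol=1e-12)
        assert res.freqs["11"] == pytest.approx(0.5, abs=1e-4)
        assert res.freqs["22"] == pytest.approx(0.5, abs=1e-4)
        assert res.freqs["12"] + res.freqs["21"] < 1e-4
        # brute-force check over the frequency simplex (codes 00,01,10,11)
        grid = np.linspace(0, 1, 101)
        best = -np.inf
        for p11 in grid:
            for p22 in grid:
                if p11 + p22 > 1:
                    continue
                rest = (1 - p11 - p22) / 2  # split evenly across 12, 21
                ll = (
                    2 * np.log(max(p11, 1e-300))
                    + 2 * np.log(max(p22, 1e-300))
                    + np.log(max(2 * p11 * p22 + 2 * rest * rest, 1e-300))
                )
                best = max(best, ll)
        assert res.loglik >= best - 1e-6


class TestThetaCMStep:
    def test_hwe_expectation_gives_one(self):
        S = 0.373690
        n = 200
        assert _theta_cm_step(n * S, n, S, 1e3, []) == pytest.approx(1.0)

    def test_worked_value(self):
        assert _theta_cm_step(50.0, 100, 0.373690, 1e3, []) == pytest.approx(
            50 * (1 - 0.373690) / (0.373690 * 50), abs=1e-12
        )
        assert _theta_cm_step(50.0, 100, 0.373690, 1e3, []) == pytest.approx(
            1.676015, abs=1e-6
        )

    def test_matches_numeric_maximizer(self, rng):
        """Closed form agrees with bounded 1-D maximization of
        Q(theta) = m log theta - n log(1 + (theta-1) S)."""
        for _ in range(25):
            n = int(rng.integers(20, 500))
            S = float(rng.uniform(0.05, 0.9))
            m = float(rng.uniform(0.05, 0.95)) * n

            def neg_q(theta):
                return -(m * np.log(theta) - n * np.log1p((theta - 1) * S))

            res = minimize_scalar(
                neg_q, bounds=(1e-6, 1e3), method="bounded",
                options={"xatol": 1e-10},
            )
            assert _theta_cm_step(m, n, S, 1e3, []) == pytest.approx(
                res.x, rel=1e-6
            )

    def test_all_homozygous_caps(self):
        flags = []
        assert _theta_cm_step(100.0, 100, 0.4, 1e3, flags) == 1e3
        assert "theta_cap" in flags

    def test_q_grid_dominance(self, rng):
        """Q at the closed-form theta dominates a log-grid in [0.01, 100]."""
        for _ in range(10):
            n = int(rng.integers(20, 300))
            S = float(rng.uniform(0.1, 0.8))
            m = float(rng.uniform(0.1, 0.9)) * n
            theta_hat = _theta_cm_step(m, n, S, 1e3, [])
            q = lambda t: m * np.log(t) - n * np.log1p((t - 1) * S)
            grid = np.logspace(-2, 2, 2001)
            assert q(theta_hat) >= q(grid).max() - 1e-9


class TestFreqCMStep:
    @staticmethod
    def _random_instance(rng):
        n = int(rng.integers(20, 200))
        r = float(rng.uniform(0.05, 0.9))
        S_rest = float(rng.uniform(0.0, (1 - r) ** 2 * 0.9))
        A = float(rng.uniform(0.0, 1.2 * n))
        B = float(rng.uniform(0.0, 1.2 * n))
        theta = float(rng.uniform(0.3, 3.0))
        x_prev = float(rng.uniform(0.0, 1.0)) * r
        return x_prev, A, B, r, n, theta, S_rest

    def test_matches_independent_grid_oracle(self, rng):
        """The cubic-root CM step matches two-stage dense grid search of Q."""
        for _ in range(30):
            x_prev, A, B, r, n, theta, S_rest = self._random_instance(rng)
            D, K = theta - 1.0, 1.0 + (theta - 1.0) * (r * r + S_rest)
            x_hat = _freq_cm_step(x_prev, A, B, r, n, theta, S_rest, [])
            grid = np.linspace(0.0, r, 20001)
            qs = np.array([_q_slice(x, A, B, r, n, D, K) for x in grid])
            j = int(np.nanargmax(qs))
            lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
            fine = np.linspace(lo, hi, 20001)
            qf = np.array([_q_slice(x, A, B, r, n, D, K) for x in fine])
            x_star = float(fine[np.nanargmax(qf)])
            assert _q_slice(x_hat, A, B, r, n, D, K) >= np.nanmax(qf) - 1e-9
            assert x_hat == pytest.approx(x_star, abs=max(1e-6, 1e-6 * r))

    def test_theta_one_reduces_to_gene_counting(self, rng):
        for _ in range(20):
            x_prev, A, B, r, n, _, S_rest = self._random_instance(rng)
            x = _freq_cm_step(x_prev, A, B, r, n, 1.0, S_rest, [])
            if A + B > 0:
                assert x == pytest.approx(r * A / (A + B), abs=1e-12)

    def test_q_never_decreases(self, rng):
        for _ in range(50):
            x_prev, A, B, r, n, theta, S_rest = self._random_instance(rng)
            D, K = theta - 1.0, 1.0 + (theta - 1.0) * (r * r + S_rest)
            x = _freq_cm_step(x_prev, A, B, r, n, theta, S_rest, [])
            assert 0.0 <= x <= r
            assert _q_slice(x, A, B, r, n, D, K) >= (
                _q_slice(x_prev, A, B, r, n, D, K) - 1e-10
            )


class TestEcmFit:
    def test_nested_likelihood(self, rng):
        X = random_dataset(rng, 3, 200)
        assert fit_niu(X).loglik >= fit_hwe(X).loglik - 1e-6

    def test_toy_grid_maximization(self):
        """ECM optimum dominates a coarse (p, theta) grid for 1-SNP data."""
        X = np.array([[0], [1], [1], [2], [0]])
        res = fit_niu(X, tol=1e-12)
        best = -np.inf
        for p in np.linspace(0.01, 0.99, 99):
            for theta in np.linspace(0.2, 5.0, 97):
                C = 1 + (theta - 1) * (p**2 + (1 - p) ** 2)
                probs = {
                    0: theta * p**2 / C,
                    1: 2 * p * (1 - p) / C,
                    2: theta * (1 - p) ** 2 / C,
                }
                best = max(best, sum(np.log(probs[int(x)]) for x in X[:, 0]))
        assert res.loglik >= best - 1e-6

    def test_theta_at_hwe_data_near_one(self, rng):
        # large HWE-ish sample: theta-hat should sit near 1
        from haphwe.simulate import GeneratingModel, sample_individuals

        X = sample_individuals(GeneratingModel(kind="HWE"), 3000, rng)
        res = fit_niu(X)
        assert res.theta_hat == pytest.approx(1.0, abs=0.25)


class TestIemFit:
    def test_f_zero_start_is_em_fixed_point(self, rng):
        X = random_dataset(rng, 3, 100)
        em = fit_hwe(X, tol=1e-10)
        iem = fit_inbreeding(X, tol=1e-10, f0=0.0)
        assert iem.f_hat == 0.0
        for h, p in em.freqs.items():
            assert iem.freqs.get(h) == pytest.approx(p, abs=1e-6)

    def test_two_haplotype_grid_oracle(self, rng):
        """(f, p) from IEM matches direct maximization of the observed
        likelihood written in closed form for one SNP."""
        from haphwe.simulate import GeneratingModel, sample_individuals

        freqs = {"1": 0.7, "2": 0.3}
        model = GeneratingModel(kind="IM", freqs=freqs, f=0.15)
        X = sample_individuals(model, 400, rng)
        n0 = int((X[:, 0] == 0).sum())
        n1 = int((X[:, 0] == 1).sum())
        n2 = int((X[:, 0] == 2).sum())

        def nll(params):
            f, p = params
            if not (0 <= f < 1 and 0 < p < 1):
                return np.inf
            return -(
                n0 * np.log(f * p + (1 - f) * p * p)
                + n1 * np.log((1 - f) * 2 * p * (1 - p))
                + n2 * np.log(f * (1 - p) + (1 - f) * (1 - p) ** 2)
            )

        # independent route: coarse grid then Nelder-Mead polish
        fs = np.linspace(0.0, 0.5, 51)
        ps = np.linspace(0.05, 0.95, 91)
        f0, p0 = min(((f, p) for f in fs for p in ps), key=nll)
        opt = minimize(nll, [f0, p0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        res = fit_inbreeding(X, tol=1e-12)
        assert res.f_hat == pytest.approx(opt.x[0], abs=1e-4)
        assert res.freqs["1"] == pytest.approx(opt.x[1], abs=1e-4)


class TestMonotonicityAndRobustness:
    def test_loglik_traces_nondecreasing(self, rng):
        """All three fitters ascend the observed likelihood on 100 random
        small datasets."""
        for _ in range(100):
            L = int(rng.integers(1, 5))
            n = int(rng.integers(5, 51))
            X = random_dataset(rng, L, n)
            cd = ClassData.from_dosage(X)
            for fitter in (fit_hwe_core, fit_niu_core, fit_im_core):
                trace = fitter(cd, 1e-8, 300).loglik_trace
                assert (np.diff(trace) >= -1e-9).all()

    def test_initialization_robustness(self, rng):
        """Final log-likelihood is the same from 5 random starting points."""
        from haphwe.simulate import GeneratingModel, sample_individuals

        X = sample_individuals(GeneratingModel(kind="NM", theta=1.3), 300, rng)
        cd = ClassData.from_dosage(X)
        for fitter in (fit_hwe_core, fit_niu_core, fit_im_core):
            ref = fitter(cd, 1e-10, 5000).loglik
            for _ in range(5):
                p0 = rng.dirichlet(np.ones(cd.n_support))
                alt = fitter(cd, 1e-10, 5000, p0=p0).loglik
                assert alt == pytest.approx(ref, abs=1e-4)


class TestSklearnInterface:
    def test_estimator_contract(self, rng):
        X = random_dataset(rng, 3, 80)
        for cls in (HardyWeinbergEM, NiuECM, InbreedingIEM):
            est = cls(tol=1e-8)
            assert clone(est).get_params()["tol"] == 1e-8
            est.set_params(max_iter=500)
            est.fit(X)
            assert est.n_features_in_ == 3
            assert est.converged_
            assert np.isfinite(est.score(X))
            total = sum(p for _, p in est.frequencies_.items())
            assert total == pytest.approx(1.0, abs=1e-8)
        nm = NiuECM().fit(X)
        im = InbreedingIEM().fit(X)
        assert nm.theta_ > 0
        assert 0 <= im.f_ < 1

    def test_missing_data_rejected(self):
        with pytest.raises(ValueError, match="individual 1"):
            HardyWeinbergEM().fit(np.array([[0, 1], [0, -1]]))
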
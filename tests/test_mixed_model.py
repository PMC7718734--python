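import numpy as np
import pytest
from scipy import optimize

import omniblup as ob
from omniblup.kernels import Kernel, KernelSet
from conftest import random_psd_kernel


def kernel_set(mats, labels=None):
    n = mats[0].shape[0]
    ids = [f"L{i}" for i in range(n)]
    labels = labels or [f"K{i}" for i in range(len(mats))]
    return KernelSet([Kernel(m, ids, 1, lab) for m, lab in zip(mats, labels)])


def dense_reml_loglik(y, mats, theta):
    """Independent dense evaluation of the restricted log-likelihood."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], mats):
        V = V + t * K
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    xvx = ones @ Vi @ ones
    P = Vi - np.outer(Vi @ ones, Vi @ ones) / xvx
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + np.log(xvx) + y @ P @ y)


def simulate_from_kernels(rng, mats, sigma2, sigma2_e, mu=0.0):
    n = mats[0].shape[0]
    cov = sigma2_e * np.eye(n)
    for s, K in zip(sigma2, mats):
        cov = cov + s * K
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return mu + L @ rng.standard_normal(n)


class TestRemlFit:
    def test_identity_kernel_total_equals_sample_variance(self, rng):
        n = 40
        y = rng.normal(3.0, 2.0, size=n)
        fit = ob.reml_fit(y, kernel_set([np.eye(n)]))
        total = fit.sigma2[0] + fit.sigma2_e
        assert total == pytest.approx(np.var(y, ddof=1), rel=1e-6)

    def test_heritability_recovery_single_kernel(self):
        props = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            K = random_psd_kernel(rng, 200, 400)
            y = simulate_from_kernels(rng, [K], [1.0], 1.0)
            fit = ob.reml_fit(y, kernel_set([K]))
            props.append(fit.sigma2[0] / (fit.sigma2[0] + fit.sigma2_e))
        assert abs(np.mean(props) - 0.5) < 0.05

    def test_two_kernel_optimum_matches_derivative_free_search(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            mats = [random_psd_kernel(rng, 40), random_psd_kernel(rng, 40)]
            y = simulate_from_kernels(rng, mats, [1.0, 0.5], 0.8)
            fit = ob.reml_fit(y, kernel_set(mats))
            vary = np.var(y, ddof=1)
            grid = vary * np.array([0.05, 0.3, 0.6, 1.0, 1.5])
            best = max(
                (dense_reml_loglik(y, mats, np.array([a, b, c])), (a, b, c))
                for a in grid
                for b in grid
                for c in grid
            )
            # theta = x**2 keeps the search smooth across the zero boundary;
            # the residual floor avoids the numerically noisy region where
            # centered kernels make V near-singular along the ones vector
            floor = 1e-9 * vary
            res = optimize.minimize(
                lambda x: -dense_reml_loglik(y, mats, np.maximum(x**2, [0, 0, floor])),
                x0=np.sqrt(np.array(best[1])),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000, "maxfev": 8000},
            )
            assert abs(fit.restricted_loglik - (-res.fun)) < 1e-4

    def test_nested_model_loglik_never_lower(self, rng):
        K1 = random_psd_kernel(rng, 60)
        K2 = random_psd_kernel(rng, 60)
        y = simulate_from_kernels(rng, [K1], [1.0], 1.0)
        small = ob.reml_fit(y, kernel_set([K1]))
        large = ob.reml_fit(y, kernel_set([K1, K2]))
        assert large.restricted_loglik >= small.restricted_loglik - 1e-6

    def test_requires_minimum_training_size(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="at least 20"):
            ob.reml_fit(y, kernel_set([np.eye(10)]))


class TestVarianceProportions:
    def make_fit(self, sigma2, sigma2_e, labels):
        return ob.VarianceComponentFit(
            sigma2=np.array(sigma2, dtype=float),
            sigma2_e=sigma2_e,
            mu_hat=0.0,
            restricted_loglik=0.0,
            converged=True,
            n_iter=1,
            boundary_flags=[False] * len(sigma2),
            labels=labels,
        )

    def test_gblup_arithmetic(self):
        props = ob.variance_proportions(self.make_fit([3.0], 1.0, ["GRM"]))
        assert props.proportions["GRM"] == pytest.approx(0.75)

    def test_zero_component(self):
        props = ob.variance_proportions(self.make_fit([0.0], 1.0, ["GRM"]))
        assert props.proportions["GRM"] == 0.0

    def test_gtiblup_equal_components(self):
        props = ob.variance_proportions(
            self.make_fit([1.0, 1.0, 1.0], 1.0, ["GRM", "TRM", "IRM"])
        )
        assert all(v == pytest.approx(0.25) for v in props.proportions.values())
        assert sum(props.proportions.values()) == pytest.approx(1.0)


class TestBlupPredict:
    def make_fit(self, sigma2, sigma2_e, labels=None):
        labels = labels or [f"K{i}" for i in range(len(sigma2))]
        return ob.VarianceComponentFit(
            sigma2=np.array(sigma2, dtype=float),
            sigma2_e=sigma2_e,
            mu_hat=0.0,
            restricted_loglik=0.0,
            converged=True,
            n_iter=1,
            boundary_flags=[False] * len(sigma2),
            labels=labels,
        )

    def test_all_zero_components_predict_training_mean(self, rng):
        K = random_psd_kernel(rng, 12)
        kset = kernel_set([K])
        y = rng.normal(5.0, 1.0, size=12)
        fit = self.make_fit([0.0], 1.0)
        pred = ob.blup_predict(fit, kset, np.arange(9), np.array([9, 10, 11]), y[:9])
        np.testing.assert_allclose(pred, y[:9].mean())

    def test_duplicate_line_low_noise_limit(self):
        # 3-line toy kernel where the test line duplicates training line 1
        K = np.array(
            [
                [1.0, 0.2, 1.0],
                [0.2, 1.0, 0.2],
                [1.0, 0.2, 1.0],
            ]
        )
        kset = kernel_set([K])
        y_train = np.array([2.0, -1.0])
        fit = self.make_fit([1.0], 1e-10)
        pred = ob.blup_predict(fit, kset, np.array([0, 1]), np.array([2]), y_train)
        assert pred[0] == pytest.approx(2.0, abs=1e-4)

    def test_matches_partitioned_normal_conditional_mean(self, rng):
        for _ in range(5):
            n = int(rng.integers(12, 30))
            n_k = int(rng.integers(1, 4))
            mats = [random_psd_kernel(rng, n) for _ in range(n_k)]
            sigma2 = rng.uniform(0.2, 2.0, size=n_k)
            sigma2_e = rng.uniform(0.3, 1.5)
            perm = rng.permutation(n)
            test_idx = perm[: n // 4 + 1]
            train_idx = np.sort(perm[n // 4 + 1 :])
            y = simulate_from_kernels(rng, mats, sigma2, sigma2_e, mu=1.3)
            fit = self.make_fit(sigma2, sigma2_e)
            pred = ob.blup_predict(fit, kernel_set(mats), train_idx, test_idx, y[train_idx])

            # independent oracle: assemble the joint covariance directly
            cov = sigma2_e * np.eye(n)
            for s, K in zip(sigma2, mats):
                cov = cov + s * K
            cov_nores = cov - sigma2_e * np.eye(n)
            Vtt = cov[np.ix_(train_idx, train_idx)]
            Vi = np.linalg.inv(Vtt)
            ones = np.ones(len(train_idx))
            mu = (ones @ Vi @ y[train_idx]) / (ones @ Vi @ ones)
            cond = mu + cov_nores[np.ix_(test_idx, train_idx)] @ Vi @ (y[train_idx] - mu)
            np.testing.assert_allclose(pred, cond, atol=1e-8)

    def test_shift_and_scale_equivariance(self, rng):
        K = random_psd_kernel(rng, 30)
        kset = kernel_set([K])
        y = simulate_from_kernels(rng, [K], [1.0], 0.5)
        train, test = np.arange(24), np.arange(24, 30)
        fit = ob.reml_fit(y[train], kernel_set([K[np.ix_(train, train)]]))
        base = ob.blup_predict(fit, kset, train, test, y[train])
        shifted = ob.blup_predict(fit, kset, train, test, y[train] + 7.0)
        np.testing.assert_allclose(shifted, base + 7.0, atol=1e-9)
        fit2 = ob.VarianceComponentFit(
            sigma2=fit.sigma2 * 4.0,
            sigma2_e=fit.sigma2_e * 4.0,
            mu_hat=fit.mu_hat * 2.0,
            restricted_loglik=0.0,
            converged=True,
            n_iter=1,
            boundary_flags=[False],
            labels=["K0"],
        )
        scaled = ob.blup_predict(fit2, kset, train, test, 2.0 * y[train])
        np.testing.assert_allclose(scaled, 2.0 * base, atol=1e-9)

    def test_overlapping_train_test_rejected(self, rng):
        K = random_psd_kernel(rng, 10)
        fit = self.make_fit([1.0], 1.0)
        with pytest.raises(ValueError, match="overlap"):
            ob.blup_predict(fit, kernel_set([K]), np.arange(6), np.array([5, 7]), np.zeros(6))
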
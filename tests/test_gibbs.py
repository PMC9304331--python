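"""Gibbs samplers versus closed-form ridge/BLUP oracles and model properties."""

import numpy as np
import pytest

from jointgp.genodata import minmax_normalize
from jointgp.gibbs import GPModelSpec, fit_brr, fit_kernel_model, predict_masked
from jointgp.kernels import gaussian_kernel

SG, SE = 0.09, 0.09
LAM = SE / SG


@pytest.fixture(scope="module")
def ridge_problem():
    rng = np.random.default_rng(42)
    n, p = 60, 40
    Z = rng.random((n, p))
    gamma = rng.normal(0, 0.3, p)
    y = Z @ gamma + rng.normal(0, 0.3, n)
    return Z, y


class TestBRR:
    def test_fixed_variance_matches_ridge(self, ridge_problem):
        """With variances frozen, the posterior mean is the ridge estimator."""
        Z, y = ridge_problem
        spec = GPModelSpec(kind="brr", n_iter=20_000, burn_in=2_000, seed=1, fixed_variances=(SG, SE))
        fit = fit_brr(y, Z, spec)
        ridge = np.linalg.solve(Z.T @ Z + LAM * np.eye(Z.shape[1]), Z.T @ (y - y.mean()))
        assert np.abs(fit.marker_effects - ridge).max() / y.std() < 0.02

    def test_constant_response_gives_null_effects(self, rng):
        Z = rng.random((30, 10))
        y = np.full(30, 3.7)
        fit = fit_brr(y, Z, GPModelSpec(kind="brr", n_iter=2_000, burn_in=500, seed=0))
        assert fit.mu == pytest.approx(3.7, abs=0.05)
        assert np.abs(fit.marker_effects).max() < 0.05

    def test_parameter_recovery_high_heritability(self):
        """Simulated h2 = 0.8: fitted values track the true genetic signal."""
        rng = np.random.default_rng(3)
        n, p = 200, 100
        Z = rng.random((n, p))
        gamma = rng.normal(0, 1.0, p)
        g = Z @ gamma
        g = (g - g.mean()) / g.std() * np.sqrt(0.8)
        y = g + rng.normal(0, np.sqrt(0.2), n)
        fit = fit_brr(y, Z, GPModelSpec(kind="brr", n_iter=4_000, burn_in=500, seed=5))
        assert np.corrcoef(fit.fitted, g)[0, 1] > 0.8

    def test_reproducible_given_seed(self, ridge_problem):
        Z, y = ridge_problem
        spec = GPModelSpec(kind="brr", n_iter=1_000, burn_in=200, seed=11)
        f1 = fit_brr(y, Z, spec)
        f2 = fit_brr(y, Z, spec)
        np.testing.assert_array_equal(f1.marker_effects, f2.marker_effects)

    def test_rejects_nonfinite_response(self, ridge_problem):
        Z, y = ridge_problem
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_brr(y, Z, GPModelSpec(kind="brr", n_iter=100, burn_in=10))


class TestKernelModels:
    def test_fixed_variance_matches_blup(self, ridge_problem):
        Z, y = ridge_problem
        K = gaussian_kernel(Z, h=1.0)
        spec = GPModelSpec(kind="smgk", n_iter=20_000, burn_in=2_000, seed=2, fixed_variances=(SG, SE))
        fit = fit_kernel_model(y, [K], spec)
        blup = K @ np.linalg.solve(K + LAM * np.eye(len(y)), y - y.mean())
        assert np.abs(fit.genetic_values - blup).max() / y.std() < 0.02

    def test_three_identical_kernels_equal_single(self, ridge_problem):
        """Kernel averaging over identical kernels is the single-kernel model."""
        Z, y = ridge_problem
        K = gaussian_kernel(Z, h=1.0)
        blup = K @ np.linalg.solve(K + LAM * np.eye(len(y)), y - y.mean())
        spec = GPModelSpec(kind="rkhs-ka", n_iter=8_000, burn_in=1_000, seed=3, fixed_variances=(SG, SE))
        fit = fit_kernel_model(y, [K, K, K], spec)
        assert np.abs(fit.genetic_values - blup).max() / y.std() < 0.02

    def test_identical_genotypes_identical_predictions(self, rng):
        Z = rng.random((20, 15))
        Z[1] = Z[0]
        y = rng.random(20)
        y[1] = y[0]
        K = gaussian_kernel(Z, h=1.0)
        fit = fit_kernel_model(y, [K], GPModelSpec(kind="smgk", n_iter=3_000, burn_in=500, seed=4))
        assert fit.genetic_values[0] == pytest.approx(fit.genetic_values[1], abs=1e-6)

    def test_variance_partition_on_model_data(self):
        """Variance components are recovered on data simulated under the model.

        A moderately local kernel (h = 5) keeps the genetic variance
        identifiable from the intercept; with a near-constant kernel the
        common mode is absorbed by mu and sigma2_g is biased down.
        """
        rng = np.random.default_rng(8)
        n = 500
        Z = rng.random((n, 80))
        K = gaussian_kernel(Z, h=5.0)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n) * np.sqrt(0.6)
        y = 1.0 + u + rng.normal(0, np.sqrt(0.4), n)
        fit = fit_kernel_model(y, [K], GPModelSpec(kind="smgk", n_iter=4_000, burn_in=500, seed=9))
        assert fit.var_genetic.sum() == pytest.approx(0.6, abs=0.15)
        assert fit.var_residual == pytest.approx(0.4, abs=0.15)

    def test_rejects_bad_kernel(self, rng):
        y = rng.random(4)
        K = np.array([[1, 2, 0, 0], [2, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        with pytest.raises(ValueError):
            fit_kernel_model(y, [K], GPModelSpec(kind="smgk", n_iter=100, burn_in=10))

    def test_collinear_fixed_effects_named(self, ridge_problem):
        Z, y = ridge_problem
        K = gaussian_kernel(Z, h=1.0)
        X = np.column_stack([Z[:, 0], Z[:, 0] * 2.0, Z[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            fit_kernel_model(y, [K], GPModelSpec(kind="smgk", n_iter=100, burn_in=10), X=X)


class TestMaskedPrediction:
    def test_duplicated_individual_limit(self, rng):
        """A masked copy of a training line converges to that line's fit as noise vanishes."""
        Z = rng.random((25, 20))
        Z[-1] = Z[0]  # test individual duplicates a training one
        y = rng.random(25)
        K = gaussian_kernel(Z, h=1.0)
        spec = GPModelSpec(
            kind="smgk", n_iter=6_000, burn_in=1_000, seed=6, fixed_variances=(0.2, 1e-4)
        )
        fit = fit_kernel_model(y, [K], spec, mask=[24])
        assert fit.predictions[0] == pytest.approx(fit.fitted[0], abs=0.02)

    def test_empty_and_full_masks_rejected(self, rng):
        Z = rng.random((10, 5))
        y = rng.random(10)
        K = gaussian_kernel(Z, h=1.0)
        spec = GPModelSpec(kind="smgk", n_iter=100, burn_in=10)
        with pytest.raises(ValueError, match="empty mask"):
            predict_masked(y, [K], mask=np.array([], dtype=int), spec=spec)
        with pytest.raises(ValueError, match="masked"):
            predict_masked(y, [K], mask=np.arange(10), spec=spec)

    def test_masked_prediction_recovers_signal(self):
        """Held-out predictions correlate with the simulated genetic signal."""
        rng = np.random.default_rng(10)
        n = 120
        Z = rng.random((n, 60))
        K = gaussian_kernel(Z, h=1.0)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n)
        y = minmax_normalize(u + rng.normal(0, 0.3, n))
        test = np.arange(0, n, 5)
        preds = predict_masked(
            y, [K], mask=test, spec=GPModelSpec(kind="smgk", n_iter=3_000, burn_in=500, seed=2)
        )
        assert np.corrcoef(preds, y[test])[0, 1] > 0.5
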
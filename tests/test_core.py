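"""Unit and property tests of the single-window smoother and its tuner."""

import numpy as np
import pytest

from hrbayes import (
    ARNoiseModel,
    build_ar_whitening_matrix,
    build_second_difference_matrix,
    criterion_residual,
    degrees_of_freedom,
    error_confidence,
    estimate_gamma,
    smooth_window,
)
from hrbayes.core import DegenerateGammaError, GammaBoundaryWarning, _WindowSystem

from conftest import simulate_ar, simulate_irw_plus_ar


class TestSecondDifferenceMatrix:
    def test_n3_stencil(self):
        F = build_second_difference_matrix(3)
        assert F.tolist() == [[1, 0, 0], [-2, 1, 0], [1, -2, 1]]

    def test_n1_truncates_stencil(self):
        assert build_second_difference_matrix(1).tolist() == [[1.0]]

    def test_annihilates_ramp_after_startup(self):
        # second differences of a straight line vanish beyond the two startup rows
        F = build_second_difference_matrix(5)
        assert (F @ np.arange(5.0)).tolist() == [0, 1, 0, 0, 0]

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            build_second_difference_matrix(0)


class TestWhiteningMatrix:
    def test_white_noise_gives_identity(self):
        A = build_ar_whitening_matrix(ARNoiseModel.white(), 4)
        assert np.array_equal(A, np.eye(4))

    def test_ar1_first_column(self):
        A = build_ar_whitening_matrix(ARNoiseModel(coefficients=[-0.5]), 3)
        assert A.tolist() == [[1, 0, 0], [-0.5, 1, 0], [0, -0.5, 1]]

    def test_whitens_simulated_ar2(self):
        # simulate the monic recursion from rest; A w must return the innovations
        coeffs = np.array([-1.2, 0.4])
        rng = np.random.default_rng(3)
        eps = rng.standard_normal(6)
        w = np.zeros(6)
        for k in range(6):
            w[k] = eps[k]
            for i in (1, 2):
                if k - i >= 0:
                    w[k] -= coeffs[i - 1] * w[k - i]
        A = build_ar_whitening_matrix(ARNoiseModel(coefficients=coeffs), 6)
        np.testing.assert_allclose(A @ w, eps, atol=1e-12)

    def test_truncation_when_order_exceeds_window(self):
        model = ARNoiseModel(coefficients=[-0.5, 0.2, -0.05])
        A = build_ar_whitening_matrix(model, 2)
        assert A.tolist() == [[1, 0], [-0.5, 1]]


class TestSmoothWindow:
    def test_gamma_zero_is_identity(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        out = smooth_window(y, ARNoiseModel.white(), 0.0)
        assert np.array_equal(out, y)

    def test_matches_dense_solve_oracle(self):
        # expected value frozen from a direct dense solve of (I + F^T F) u = y
        y = np.array([1.0, 2.0, 2.0, 1.0])
        F = build_second_difference_matrix(4)
        expected = np.linalg.solve(np.eye(4) + F.T @ F, y)
        out = smooth_window(y, ARNoiseModel.white(), 1.0)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_large_gamma_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        out = smooth_window(y, ARNoiseModel.white(), 1e8)
        assert np.linalg.norm(out) < 1e-2 * np.linalg.norm(y)

    def test_first_sample_anchoring_restores_level(self):
        # with the start anchored, heavy smoothing collapses to the anchor
        y = 70.0 + np.sin(np.linspace(0, 3, 50))
        out = smooth_window(y, ARNoiseModel.white(), 1e8, baseline="first")
        np.testing.assert_allclose(out, y[0], atol=0.05)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_window(np.array([1.0, 2.0]), ARNoiseModel.white(), 1.0)


class TestEstimatorEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_regularized_form_equals_bayes_covariance_form(self, seed):
        """The penalized solve equals the dense MMSE formula
        (Sigma_w^{-1} + Sigma_u^{-1})^{-1} Sigma_w^{-1} y with
        Sigma_u = lambda2 (F^T F)^{-1}, Sigma_w = sigma2 (A^T A)^{-1}."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        order = int(rng.integers(0, 3))
        coeffs = rng.uniform(-0.4, 0.4, size=order)
        model = ARNoiseModel(coefficients=coeffs)
        sigma2 = float(rng.uniform(0.5, 2.0))
        lambda2 = float(rng.uniform(0.01, 1.0))
        y = rng.normal(70.0, 5.0, size=n)
        gamma = sigma2 / lambda2

        F = build_second_difference_matrix(n)
        A = build_ar_whitening_matrix(model, n)
        sigma_u = lambda2 * np.linalg.inv(F.T @ F)
        sigma_w = sigma2 * np.linalg.inv(A.T @ A)
        dense = np.linalg.solve(
            np.linalg.inv(sigma_w) + np.linalg.inv(sigma_u),
            np.linalg.inv(sigma_w) @ y,
        )
        fast = smooth_window(y, model, gamma)
        np.testing.assert_allclose(fast, dense, rtol=1e-8, atol=1e-10)


class TestDegreesOfFreedom:
    def test_zero_gamma_gives_full_dof(self):
        assert degrees_of_freedom(ARNoiseModel.white(), 17, 0.0) == 17.0

    def test_large_gamma_dof_below_one(self):
        assert degrees_of_freedom(ARNoiseModel.white(), 50, 1e8) < 1.0

    def test_matches_dense_trace_oracle(self):
        F = build_second_difference_matrix(3)
        expected = np.trace(np.linalg.solve(np.eye(3) + F.T @ F, np.eye(3)))
        assert degrees_of_freedom(ARNoiseModel.white(), 3, 1.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_strictly_decreasing_in_gamma(self, ar2_model):
        gammas = np.logspace(-4, 6, 20)
        q = [degrees_of_freedom(ar2_model, 40, g) for g in gammas]
        assert np.all(np.diff(q) < 0)


class TestCriterion:
    def test_wrss_wess_monotone_in_gamma(self, ar2_model):
        rng = np.random.default_rng(5)
        y = rng.normal(0.0, 2.0, size=60)
        sys = _WindowSystem(ar2_model, 60)
        wrss, wess = [], []
        for g in np.logspace(-4, 6, 20):
            _, _, r, e = sys.fit_at(y, g)
            wrss.append(r)
            wess.append(e)
        assert np.all(np.diff(wrss) >= 0)
        assert np.all(np.diff(wess) <= 0)

    def test_sign_change_on_model_draw(self):
        _, y, model = simulate_irw_plus_ar(seed=2)
        lo = criterion_residual(y, model, 1e-6)
        hi = criterion_residual(y, model, 1e8)
        assert np.sign(lo) != np.sign(hi)

    def test_degenerate_at_gamma_zero(self):
        y = np.random.default_rng(0).standard_normal(30)
        with pytest.raises(DegenerateGammaError):
            criterion_residual(y, ARNoiseModel.white(), 0.0)

    def test_flat_truth_selects_strong_smoothing(self):
        # white noise around a constant: nearly all variance is noise, so
        # the tuner should push gamma well above 1 (strong smoothing)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 70.0 + rng.standard_normal(200)
            fit = estimate_gamma(y, ARNoiseModel.white())
            hits += fit.gamma > 1.0
        assert hits >= 18


class TestEstimateGamma:
    def test_root_verified_by_independent_reevaluation(self):
        _, y, model = simulate_irw_plus_ar(seed=4)
        fit = estimate_gamma(y, model)
        assert fit.status == "ok"
        g = criterion_residual(y, model, fit.gamma)
        # root localized to the bisection tolerance on log10(gamma)
        lo = criterion_residual(y, model, fit.gamma * 10 ** (-2e-4))
        hi = criterion_residual(y, model, fit.gamma * 10 ** (2e-4))
        assert abs(g) <= 1e-6 * fit.sigma2_hat or np.sign(lo) != np.sign(hi)

    def test_sigma2_and_lambda2_consistent_with_root(self):
        _, y, model = simulate_irw_plus_ar(seed=6)
        fit = estimate_gamma(y, model)
        assert fit.sigma2_hat == pytest.approx(fit.wrss / (200 - fit.dof))
        assert fit.lambda2_hat == pytest.approx(fit.sigma2_hat / fit.gamma)
        assert 0 < fit.dof < 200

    def test_scale_invariance(self):
        _, y, model = simulate_irw_plus_ar(seed=8)
        g1 = estimate_gamma(y, model).gamma
        g2 = estimate_gamma(3.7 * y, model).gamma
        assert np.log10(g2) == pytest.approx(np.log10(g1), abs=1e-3)

    def test_noiseless_polynomial_hits_bracket_boundary(self):
        k = np.arange(50, dtype=float)
        y = 60.0 + 0.05 * k + 0.002 * k**2
        with pytest.warns(GammaBoundaryWarning):
            fit = estimate_gamma(y, ARNoiseModel.white())
        assert fit.status == "boundary"

    def test_short_window_degenerates_to_identity(self):
        y = np.array([70.0, 71, 72, 70, 69, 70, 71])
        fit = estimate_gamma(y, ARNoiseModel.white())
        assert fit.status == "degenerate"
        assert np.array_equal(fit.u_hat, y)
        assert np.all(fit.ci_halfwidth == 0)

    def test_constant_window_degenerates(self):
        fit = estimate_gamma(np.full(100, 65.0), ARNoiseModel.white())
        assert fit.status == "degenerate"

    def test_recovery_light(self):
        # desk-scale check that gamma* = sigma2/lambda2 is recovered within
        # an order of magnitude (the full 50-replicate version runs in the
        # acceptance suite)
        logs = []
        for seed in range(10):
            _, y, model = simulate_irw_plus_ar(seed, lambda2=0.01, sigma2=1.0)
            logs.append(np.log10(estimate_gamma(y, model).gamma / 100.0))
        assert abs(np.median(logs)) <= 1.0


class TestErrorConfidence:
    def test_small_gamma_white_noise_halfwidth_is_sigma(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(40)
        fit = estimate_gamma(y, ARNoiseModel.white())
        fit.gamma = 1e-9
        hw = error_confidence(fit, ARNoiseModel.white())
        np.testing.assert_allclose(hw, np.sqrt(fit.sigma2_hat), rtol=1e-6)

    def test_matches_dense_inverse_oracle(self, ar2_model):
        _, y, _ = simulate_irw_plus_ar(seed=9, coefficients=(-1.0, 0.3))
        fit = estimate_gamma(y, ar2_model)
        A = build_ar_whitening_matrix(ar2_model, 200)
        F = build_second_difference_matrix(200)
        cov = fit.sigma2_hat * np.linalg.inv(A.T @ A + fit.gamma * F.T @ F)
        np.testing.assert_allclose(
            fit.ci_halfwidth, np.sqrt(np.diag(cov)), rtol=1e-8
        )
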
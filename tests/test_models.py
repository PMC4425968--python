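"""Regression-layer tests: inverse/linear fits, F-tests, model selection."""

import numpy as np
import pytest

from rctime import models
from rctime.errors import ContractError, DomainError
from rctime.models import (
    InverseComplianceModel,
    LinearFit,
    candidate_models,
    f_test_group_difference,
    fit_inverse_model,
    fit_linear,
    fit_linear_grouped,
    select_model,
)
from rctime.synthetic import generate_regression_fixture

PVR_LINK_PARAMS = [{"a": 10.4, "b": 0.5}, {"a": 10.4, "b": 0.8}]
TPR_LINK_PARAMS = [{"a": 22.1, "b": 1.4}, {"a": 13.5, "b": 0.1}]
GROUP_RANGES = [(0.5, 4.0), (1.0, 20.0)]


class TestInverseModel:
    def test_noiseless_single_group_exact_recovery(self):
        x = np.arange(0.5, 5.01, 0.5)
        fit = fit_inverse_model(x, 10.4 / (0.5 + x))
        assert fit.params["a"] == pytest.approx(10.4, abs=1e-6)
        assert fit.params["b"] == pytest.approx(0.5, abs=1e-6)
        assert fit.residual_standard_error == pytest.approx(0.0, abs=1e-7)

    def test_noiseless_two_group_shared_numerator(self):
        x, y, g = generate_regression_fixture(
            "inverse", PVR_LINK_PARAMS, 0.0, [60, 60], seed=11, x_range=GROUP_RANGES
        )
        fit = fit_inverse_model(x, y, group=g, share_numerator=True)
        assert fit.params["a"] == pytest.approx(10.4, abs=1e-6)
        assert fit.params["b_g0"] == pytest.approx(0.5, abs=1e-6)
        assert fit.params["b_g1"] == pytest.approx(0.8, abs=1e-6)
        assert fit.n_params == 3

    def test_noiseless_two_group_free_numerator(self):
        x, y, g = generate_regression_fixture(
            "inverse", TPR_LINK_PARAMS, 0.0, [60, 60], seed=12, x_range=GROUP_RANGES
        )
        fit = fit_inverse_model(x, y, group=g, share_numerator=False)
        assert fit.params["a_g0"] == pytest.approx(22.1, abs=1e-5)
        assert fit.params["b_g0"] == pytest.approx(1.4, abs=1e-5)
        assert fit.params["a_g1"] == pytest.approx(13.5, abs=1e-5)
        assert fit.params["b_g1"] == pytest.approx(0.1, abs=1e-5)
        assert fit.n_params == 4

    def test_simulation_mean_estimate_unbiased(self):
        # replicate fits on noisy draws: the mean estimate of the shared
        # numerator stays within 2 Monte-Carlo SE of truth
        n_rep = 60
        a_hat = np.empty(n_rep)
        for r in range(n_rep):
            x, y, g = generate_regression_fixture(
                "inverse", PVR_LINK_PARAMS, 0.3, [150, 700], seed=300 + r,
                x_range=GROUP_RANGES,
            )
            a_hat[r] = fit_inverse_model(x, y, group=g).params["a"]
        mc_se = a_hat.std(ddof=1) / np.sqrt(n_rep)
        assert abs(a_hat.mean() - 10.4) < 2 * mc_se

    def test_rse_definition_and_wald_inference(self):
        x, y, g = generate_regression_fixture(
            "inverse", PVR_LINK_PARAMS, 0.3, [100, 100], seed=13, x_range=GROUP_RANGES
        )
        fit = fit_inverse_model(x, y, group=g)
        assert fit.residual_standard_error == pytest.approx(
            np.sqrt(fit.rss / (fit.n - fit.n_params))
        )
        assert 0 < fit.pvalues["a"] < 1e-6  # strong signal
        assert all(se > 0 for se in fit.se.values())

    def test_nls_stationarity_rss_not_above_brute_force_grid(self):
        x = np.linspace(0.5, 10, 80)
        rng = np.random.default_rng(4)
        y = 10.4 / (0.5 + x) + rng.normal(0, 0.3, x.size)
        fit = fit_inverse_model(x, y)
        # independent coarse grid search cannot beat the NLS solution
        grid_rss = min(
            float(np.sum((a / (b + x) - y) ** 2))
            for a in np.linspace(5, 15, 41)
            for b in np.linspace(0.05, 2.0, 40)
        )
        assert fit.rss <= grid_rss + 1e-9

    def test_too_few_points_per_group_rejected(self):
        with pytest.raises(DomainError):
            fit_inverse_model([1.0, 2.0, 3.0, 4.0], [3, 2, 1.5, 1.2],
                              group=[0, 0, 0, 1])

    def test_estimator_sklearn_surface(self):
        est = InverseComplianceModel(share_numerator=True)
        params = est.get_params()
        assert params["share_numerator"] is True
        x = np.arange(0.5, 6, 0.5)
        est.fit(x, 10.4 / (0.5 + x))
        pred = est.predict(np.array([1.5]))
        assert pred[0] == pytest.approx(10.4 / 2.0, abs=1e-6)
        cloned = est.set_params(share_numerator=False)
        assert cloned.share_numerator is False


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_generated_line_recovers_reported_coefficients(self):
        x, y, _ = generate_regression_fixture(
            "linear", {"slope": 0.0041, "intercept": 0.39}, 0.0, 100, seed=21,
            x_range=(10.0, 80.0),
        )
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(0.0041, abs=1e-10)
        assert fit.intercept == pytest.approx(0.39, abs=1e-8)

    def test_null_slope_pvalue_calibration(self):
        # with y independent of x the slope test rarely rejects
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(100):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            if fit_linear(x, y).slope_pvalue <= 0.05:
                rejections += 1
        assert rejections <= 10

    def test_constant_x_rejected(self):
        with pytest.raises(DomainError, match="constant"):
            fit_linear(np.ones(10), np.arange(10.0))

    def test_ols_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        fit = fit_linear(x, y)
        resid = y - fit.intercept - fit.slope * x
        assert abs(resid.sum()) < 1e-8
        assert abs((resid * x).sum()) < 1e-8


class TestFTest:
    def test_no_group_effect_noiseless_gives_f_zero_p_one(self):
        x = np.linspace(1, 10, 40)
        y = 2.0 * x + 1.0
        group = np.repeat([0, 1], 20)
        pooled = fit_linear(x, y)
        grouped = fit_linear_grouped(x, y, group)
        res = f_test_group_difference(pooled, grouped)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_group_difference_detected_in_replicates(self):
        # distinct offsets per group, realistic noise and group sizes:
        # the nested F-test should reject essentially always
        rejections = 0
        n_rep = 50
        for r in range(n_rep):
            x, y, g = generate_regression_fixture(
                "inverse", PVR_LINK_PARAMS, 0.3, [150, 700], seed=1000 + r,
                x_range=GROUP_RANGES,
            )
            pooled = fit_inverse_model(x, y, group=None)
            grouped = fit_inverse_model(x, y, group=g)
            if f_test_group_difference(pooled, grouped).pvalue < 0.05:
                rejections += 1
        assert rejections >= int(0.95 * n_rep)

    def test_rss_matches_independent_residual_summation(self):
        x, y, g = generate_regression_fixture(
            "inverse", PVR_LINK_PARAMS, 0.3, [25, 25], seed=17, x_range=GROUP_RANGES
        )
        fit = fit_inverse_model(x, y, group=g)
        a = fit.params["a"]
        b = np.where(g == 0, fit.params["b_g0"], fit.params["b_g1"])
        rss_brute = float(np.sum((y - a / (b + x)) ** 2))
        assert fit.rss == pytest.approx(rss_brute, abs=1e-10)

    def test_non_nested_inputs_rejected(self):
        x = np.linspace(1, 10, 30)
        y = 2 * x + np.sin(x)
        fit_a = fit_linear(x, y)
        fit_b = fit_linear(x[:20], y[:20])
        with pytest.raises(ContractError):
            f_test_group_difference(fit_a, fit_b)
        with pytest.raises(ContractError):
            f_test_group_difference(fit_a, fit_a)  # equal parameter counts


class TestModelSelection:
    def test_smaller_rse_wins(self):
        y = np.zeros(10)
        f1 = LinearFit(0, 0, 0, 0.697, 10, 1.0, rss=1.0, y=y)
        f2 = LinearFit(0, 0, 0, 0.696, 10, 1.0, rss=1.0, y=y)
        assert select_model([f1, f2]) is f2

    def test_exact_tie_prefers_fewer_parameters(self):
        y = np.zeros(10)
        f1 = LinearFit(0, 0, 0, 0.5, 10, 1.0, rss=1.0, n_params=4, y=y)
        f2 = LinearFit(0, 0, 0, 0.5, 10, 1.0, rss=1.0, n_params=3, y=y)
        assert select_model([f1, f2]) is f2

    def test_single_candidate_returned_unchanged(self):
        f1 = LinearFit(0, 0, 0, 0.5, 10, 1.0, rss=1.0, y=np.zeros(10))
        assert select_model([f1]) is f1

    def test_candidates_on_different_data_rejected(self):
        f1 = LinearFit(0, 0, 0, 0.5, 10, 1.0, rss=1.0, y=np.zeros(10))
        f2 = LinearFit(0, 0, 0, 0.4, 12, 1.0, rss=1.0, y=np.zeros(12))
        with pytest.raises(ContractError):
            select_model([f1, f2])

    def test_zoo_selects_true_form_on_generated_data(self):
        x, y, g = generate_regression_fixture(
            "inverse", PVR_LINK_PARAMS, 0.3, [200, 200], seed=5, x_range=GROUP_RANGES
        )
        fits = []
        for est in candidate_models():
            est.fit(x, y, groups=g)
            fits.append(est.fit_result_)
        chosen = select_model(fits)
        assert chosen.model in ("inverse",)  # the generating family wins


class TestParameterRecoveryAcrossNoiseLevels:
    def test_bias_shrinks_as_noise_vanishes(self):
        biases = []
        for noise in (0.6, 0.2, 0.0):
            x, y, g = generate_regression_fixture(
                "inverse", PVR_LINK_PARAMS, noise, [400, 400], seed=31,
                x_range=GROUP_RANGES,
            )
            fit = fit_inverse_model(x, y, group=g)
            biases.append(abs(fit.params["b_g1"] - 0.8))
        assert biases[2] < 1e-6
        assert biases[2] <= biases[1] <= biases[0] + 0.05
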
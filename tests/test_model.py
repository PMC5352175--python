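"""Univariate screening, multinomial fitting, stepwise selection, VIF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dectgrade import (
    InvalidConfigError,
    anova_bonferroni,
    fit_multinomial,
    predict_proba,
    sample_size,
    stepwise_select,
    vif_screen,
)


def _simulate_multinomial(n, beta2, beta3, rng, intercept2=0.0, intercept3=0.0):
    """Draw (x, y) from a 3-class baseline-category logit with one covariate."""
    x = rng.standard_normal(n)
    eta2 = intercept2 + beta2 * x
    eta3 = intercept3 + beta3 * x
    denom = 1.0 + np.exp(eta2) + np.exp(eta3)
    p = np.column_stack([1.0 / denom, np.exp(eta2) / denom, np.exp(eta3) / denom])
    u = rng.uniform(size=n)
    y = 1 + (u > p[:, 0]).astype(int) + (u > p[:, 0] + p[:, 1]).astype(int)
    return x.reshape(-1, 1), y


class TestAnova:
    def test_identical_groups_give_null_result(self):
        x = np.tile(np.arange(5.0), 3)
        g = np.repeat([1, 2, 3], 5)
        out = anova_bonferroni(x, g)
        assert out["F"] == pytest.approx(0.0)
        assert out["omnibus_p"] == pytest.approx(1.0)

    def test_planted_separation_is_detected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(m, 1.0, 30) for m in (0.0, 5.0, 10.0)])
        g = np.repeat([1, 2, 3], 30)
        out = anova_bonferroni(x, g)
        assert out["omnibus_p"] < 1e-6
        assert all(p < 1e-4 for p in out["pairwise_adjusted_p"].values())

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)])
        g = np.repeat([1, 2], [20, 25])
        out = anova_bonferroni(x, g)
        t = stats.ttest_ind(x[g == 1], x[g == 2], equal_var=True)
        assert out["F"] == pytest.approx(t.statistic**2, rel=1e-10)

    def test_degenerate_group_rejected(self):
        with pytest.raises(InvalidConfigError):
            anova_bonferroni(np.arange(4.0), np.array([1, 1, 1, 2]))


class TestMultinomialFit:
    def test_intercept_only_equals_log_count_ratios(self):
        y = np.repeat([1, 2, 3], [19, 65, 7])
        fit = fit_multinomial(np.empty((91, 0)), y)
        assert fit.coef[0, 0] == pytest.approx(np.log(65 / 19), abs=1e-8)
        assert fit.coef[1, 0] == pytest.approx(np.log(7 / 19), abs=1e-8)

    def test_null_coefficient_gives_unit_odds_ratio(self):
        rng = np.random.default_rng(2)
        x, y = _simulate_multinomial(800, 0.0, 0.0, rng)
        fit = fit_multinomial(x, y)
        summary = fit.summary()
        slopes = summary[summary["term"] != "(intercept)"]
        assert np.allclose(slopes["odds_ratio"], 1.0, atol=0.25)
        assert ((slopes["or_ci_low"] < 1.0) & (slopes["or_ci_high"] > 1.0)).all()

    def test_probabilities_sum_to_one_and_loglik_monotone(self):
        rng = np.random.default_rng(3)
        x, y = _simulate_multinomial(300, 1.0, -0.5, rng)
        fit = fit_multinomial(x, y)
        probs = predict_proba(fit, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(fit.loglik_history) >= -1e-9)

    def test_matches_statsmodels_mnlogit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x, y = _simulate_multinomial(400, 0.8, 1.5, rng)
        fit = fit_multinomial(x, y)
        ref = sm.MNLogit(pd.get_dummies(y).to_numpy().argmax(axis=1),
                         sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params.T, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_coefficients_reported_on_original_scale(self):
        rng = np.random.default_rng(5)
        x, y = _simulate_multinomial(500, 1.0, 2.0, rng)
        x_scaled = 100.0 * x  # e.g. HU-scale covariate
        fit = fit_multinomial(x, y)
        fit_scaled = fit_multinomial(x_scaled, y)
        np.testing.assert_allclose(
            fit_scaled.coef[:, 1], fit.coef[:, 1] / 100.0, rtol=1e-6
        )

    def test_separation_is_detected_and_flagged(self):
        x = np.concatenate([np.zeros(10), np.ones(10), 2 * np.ones(10)])
        y = np.repeat([1, 2, 3], 10)
        fit = fit_multinomial(x.reshape(-1, 1), y, raise_on_nonconvergence=False)
        assert fit.separation

    def test_too_few_observations_rejected(self):
        with pytest.raises(InvalidConfigError):
            fit_multinomial(np.zeros((4, 2)), np.array([1, 2, 3, 1]))


class TestStepwise:
    def test_alpha_zero_selects_nothing(self):
        rng = np.random.default_rng(6)
        x, y = _simulate_multinomial(200, 2.0, 2.0, rng)
        selected, trace = stepwise_select(x, y, alpha_enter=0.0)
        assert selected == [] and trace.steps == []

    def test_alpha_one_selects_everything(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((120, 3)), columns=list("abc"))
        y = np.repeat([1, 2, 3], 40)
        selected, _ = stepwise_select(X, y, alpha_enter=1.01, alpha_remove=1.01)
        assert sorted(selected) == list("abc")

    def test_strong_feature_is_selected_noise_is_not(self):
        rng = np.random.default_rng(8)
        x, y = _simulate_multinomial(400, 2.0, 2.0, rng)
        X = pd.DataFrame(
            np.column_stack([x, rng.standard_normal((400, 3))]),
            columns=["signal", "n1", "n2", "n3"],
        )
        selected, trace = stepwise_select(X, y)
        assert "signal" in selected
        assert trace.steps[0][1] == "add" and trace.steps[0][2] == "signal"
        assert all(0.0 <= s[3] <= 1.0 for s in trace.steps)


class TestVif:
    def test_orthogonal_features_have_unit_vif(self):
        n = 64
        X = pd.DataFrame({
            "a": np.tile([1.0, -1.0], n // 2),
            "b": np.repeat([1.0, -1.0], n // 2),
        })
        vifs, flagged = vif_screen(X)
        assert vifs["a"] == pytest.approx(1.0, abs=1e-10)
        assert flagged == []

    def test_duplicated_feature_is_infinite_and_flagged(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        vifs, flagged = vif_screen(X)
        assert np.isinf(vifs["a"]) and "a" in flagged and "b" in flagged

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(9)
        n = 200_000
        x = rng.standard_normal(n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        vifs, _ = vif_screen(pd.DataFrame({"x": x, "y": y}))
        assert vifs["x"] == pytest.approx(1.0 / (1.0 - 0.81), rel=0.02)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        X["b"] += 0.7 * X["a"]
        vifs, _ = vif_screen(X)
        design = sm.add_constant(X.to_numpy())
        for j, name in enumerate(X.columns):
            ref = variance_inflation_factor(design, j + 1)
            assert vifs[name] == pytest.approx(ref, rel=1e-8)


class TestSampleSize:
    def test_round_numbers(self):
        assert sample_size(0.5, z_crit=2.0, ci_width=1.0) == 4

    def test_published_inputs_give_88(self):
        # p=0.65, z=1.960, D=0.20 under N = 4 z^2 p (1-p) / D^2
        assert sample_size(0.65, z_crit=1.960, ci_width=0.20) == 88

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidConfigError):
            sample_size(0.0)
        with pytest.raises(InvalidConfigError):
            sample_size(0.5, ci_width=0.0)
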
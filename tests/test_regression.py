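import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tetradscreen.contingency import TwoByTwo, odds_ratio
from tetradscreen.regression import (
    Covariate, DesignSpec, LogisticFit, fit_logistic, four_way_interaction_term,
    hosmer_lemeshow, tjur_r2, vif,
)


def toy_fit(fitted, y):
    fitted = np.asarray(fitted, float)
    y = np.asarray(y, float)
    return LogisticFit(
        terms={}, converged=True, separated=False, n_used=len(y),
        n_events=int(y.sum()), log_likelihood=0.0, log_likelihood_path=[0.0],
        fitted=fitted, y=y, X=np.ones((len(y), 1)), term_names=["intercept"],
    )


def simulate_logistic(rng, n, beta0, beta1):
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
    return pd.DataFrame({"y": rng.binomial(1, p), "x": x})


class TestFitLogistic:
    def test_intercept_only_mle_is_log_odds(self, fixture_report):
        """With no covariates the MLE intercept is the sample log-odds:
        ln(112/46) on the fixture cohort."""
        y = np.array([1] * 112 + [0] * 46, float)
        fit = fit_logistic(pd.DataFrame({"y": y}), DesignSpec("y", ()))
        assert fit.terms["intercept"].estimate == pytest.approx(math.log(112 / 46), abs=1e-8)
        assert fit.terms["intercept"].estimate == pytest.approx(0.890, abs=0.001)

    def test_single_binary_covariate_or_equals_sample_or(self):
        """Saturated-model equivalence, cross-checked against the
        contingency module on the same 2x2 data."""
        a, b, c, d = 42, 5, 70, 41  # flagged/abn, flagged/norm, unflagged/abn, unflagged/norm
        df = pd.DataFrame({
            "y": [1] * a + [0] * b + [1] * c + [0] * d,
            "flag": [1] * (a + b) + [0] * (c + d),
        })
        fit = fit_logistic(df, DesignSpec("y", (Covariate("flag", "binary"),)))
        t = TwoByTwo(a, b, c, d)
        assert fit.terms["flag"].odds_ratio == pytest.approx(
            odds_ratio(t, correct_zero=False), rel=1e-6)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(42)
        beta0, beta1 = -0.4, 0.8
        df = simulate_logistic(rng, 5000, beta0, beta1)
        fit = fit_logistic(df, DesignSpec("y", (Covariate("x", "continuous"),)))
        assert abs(fit.terms["intercept"].estimate - beta0) < 3 * fit.terms["intercept"].se
        assert abs(fit.terms["x"].estimate - beta1) < 3 * fit.terms["x"].se

    def test_matches_statsmodels_mle(self):
        rng = np.random.default_rng(7)
        df = simulate_logistic(rng, 400, 0.2, -0.6)
        fit = fit_logistic(df, DesignSpec("y", (Covariate("x", "continuous"),)))
        sm_fit = sm.Logit(df["y"], sm.add_constant(df["x"])).fit(disp=0)
        assert fit.terms["intercept"].estimate == pytest.approx(sm_fit.params["const"], abs=1e-6)
        assert fit.terms["x"].estimate == pytest.approx(sm_fit.params["x"], abs=1e-6)
        assert fit.terms["x"].se == pytest.approx(sm_fit.bse["x"], rel=1e-4)

    def test_log_likelihood_nondecreasing_over_iterations(self):
        rng = np.random.default_rng(1)
        df = simulate_logistic(rng, 300, -0.2, 1.1)
        fit = fit_logistic(df, DesignSpec("y", (Covariate("x", "continuous"),)))
        path = np.array(fit.log_likelihood_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_complete_separation_flagged_with_unbounded_ci(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": [0.0] * 20 + [1.0] * 20})
        fit = fit_logistic(df, DesignSpec("y", (Covariate("x", "binary"),)))
        assert fit.separated
        assert math.isinf(fit.terms["x"].ci_hi) or fit.terms["x"].ci_hi > 1e6

    def test_degenerate_outcome_rejected(self):
        df = pd.DataFrame({"y": [1.0] * 10, "x": range(10)})
        with pytest.raises(ValueError, match="event"):
            fit_logistic(df, DesignSpec("y", (Covariate("x", "continuous"),)))

    def test_complete_case_analysis_counts(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1, 1, 0], "x": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]})
        fit = fit_logistic(df, DesignSpec("y", (Covariate("x", "continuous"),)))
        assert fit.n_used == 5


class TestTjurR2:
    def test_constant_fit_scores_zero(self):
        assert tjur_r2(toy_fit([0.5] * 6, [1, 1, 1, 0, 0, 0])) == pytest.approx(0.0)

    def test_perfect_separation_scores_one(self):
        assert tjur_r2(toy_fit([1, 1, 0, 0], [1, 1, 0, 0])) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        fit = toy_fit([0.8, 0.6, 0.3, 0.3], [1, 1, 0, 0])
        assert tjur_r2(fit) == pytest.approx(0.4)


class TestHosmerLemeshow:
    def test_too_few_groups_rejected(self):
        fit = toy_fit(np.linspace(0.1, 0.9, 50), np.tile([0, 1], 25))
        with pytest.raises(ValueError):
            hosmer_lemeshow(fit, g=2)

    def test_near_constant_fitted_probabilities_skipped(self):
        fit = toy_fit([0.5] * 40, np.tile([0, 1], 20))
        with pytest.raises(ValueError, match="distinct"):
            hosmer_lemeshow(fit)

    def test_grouping_conserves_event_totals(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 200)
        y = rng.binomial(1, p)
        res = hosmer_lemeshow(toy_fit(p, y))
        assert res["df"] == res["groups"] - 2
        assert res["statistic"] >= 0

    def test_calibrated_model_rejects_near_alpha(self):
        """Under a perfectly calibrated model the HL p-value should be
        roughly uniform: rejection rate near 5% at alpha = 0.05."""
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 300
        for _ in range(reps):
            p = rng.uniform(0.1, 0.9, 400)
            y = rng.binomial(1, p)
            if hosmer_lemeshow(toy_fit(p, y))["p"] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.12


class TestVif:
    def test_orthogonal_covariates_give_unit_vif(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        spec = DesignSpec("y", (Covariate("a"), Covariate("b")))
        got = vif(df, spec)
        assert got["a"] == pytest.approx(1.0, abs=1e-9)
        assert got["b"] == pytest.approx(1.0, abs=1e-9)

    def test_correlation_08_gives_278(self):
        # x2 = 0.8*x1 + 0.6*v with x1 orthogonal to v and equal norms:
        # sample correlation exactly 0.8, so VIF = 1/(1 - 0.64) = 2.778
        x1 = np.array([1, 1, -1, -1.0])
        v = np.array([1, -1, 1, -1.0])
        df = pd.DataFrame({"a": x1, "b": 0.8 * x1 + 0.6 * v})
        got = vif(df, DesignSpec("y", (Covariate("a"), Covariate("b"))))
        assert got["a"] == pytest.approx(1 / (1 - 0.64), abs=1e-9)
        assert got["b"] == pytest.approx(1 / (1 - 0.64), abs=1e-9)

    def test_duplicated_covariate_rank_deficiency(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinear"):
            vif(df, DesignSpec("y", (Covariate("a"), Covariate("b"))))

    def test_needs_two_covariates(self):
        df = pd.DataFrame({"a": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            vif(df, DesignSpec("y", (Covariate("a"),)))


class TestFourWayInteraction:
    def test_product_rule(self):
        assert four_way_interaction_term([1], [1], [1], [1])[0] == 1
        assert four_way_interaction_term([1], [0], [1], [1])[0] == 0

    def test_equals_tetrad_flag_on_fixture(self, fixture_records, curves, cutoffs):
        from tetradscreen.pipeline import cohort_centiles, cohort_flags

        cent = cohort_centiles(fixture_records, curves)
        flags = cohort_flags(fixture_records, cent, cutoffs)
        product = four_way_interaction_term(
            flags["gsmd_small"], flags["ysmd_large"], flags["crl_short"], flags["bradycardia"])
        assert np.array_equal(product, flags["tetrad"].to_numpy())
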
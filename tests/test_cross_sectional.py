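"""Group comparisons, regression battery, Bonferroni family, moderation."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from persnet.cross_sectional import (
    bonferroni_threshold,
    compare_groups,
    feature_outcome_regression,
    moderation_analysis,
    printed_threshold,
)
from persnet.longitudinal import _battery_pvalues


def _feature_frame(x1, x2, name="size"):
    return pd.DataFrame(
        {
            "group": ["pwMS"] * len(x1) + ["control"] * len(x2),
            name: np.concatenate([x1, x2]),
        }
    )


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(_feature_frame(vals, vals), feature_names=["size"])[0]
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_one_sd_shift_detected_under_bonferroni_18(self, rng):
        x1 = rng.normal(0.0, 1.0, 200)
        x2 = rng.normal(1.0, 1.0, 200)
        res = compare_groups(
            _feature_frame(x1, x2), feature_names=["size"], alpha=0.05, m=18
        )[0]
        assert res.p < 0.05 / 18
        assert res.significant

    def test_zero_variance_flagged(self):
        res = compare_groups(
            _feature_frame(np.ones(5), np.full(5, 2.0)), feature_names=["size"]
        )[0]
        assert math.isnan(res.t)
        assert "undefined" in res.note

    def test_welch_equals_pooled_for_equal_variance_equal_n(self):
        x1 = np.array([0.0, 1.0, 2.0, 5.0])
        x2 = x1 + 3.0  # identical sample variance, equal n
        welch = stats.ttest_ind(x1, x2, equal_var=False)
        pooled = stats.ttest_ind(x1, x2, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, abs=1e-9)
        assert welch.pvalue == pytest.approx(pooled.pvalue, abs=1e-9)
        res = compare_groups(_feature_frame(x1, x2), feature_names=["size"])[0]
        assert res.t == pytest.approx(pooled.statistic, abs=1e-9)


class TestBonferroni:
    def test_table_footnote_thresholds(self):
        assert printed_threshold(0.05, 54) == 0.00092
        assert bonferroni_threshold(0.05, 18) == pytest.approx(0.05 / 18)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_family_size_zero_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_family_wise_error_controlled_at_54(self, rng):
        """Null battery of 18 features x 3 outcomes on a shared design:
        the Bonferroni family keeps the FWER near alpha."""
        n, k, reps = 60, 18, 400
        base = rng.normal(size=(n, 4))
        designs = []
        for _ in range(k):
            f = base @ (rng.normal(size=4) * 0.5) + rng.normal(size=n)
            designs.append(np.column_stack([np.ones(n), f, rng.normal(size=n)]))
        Y = rng.normal(size=(n, reps * 3))
        p = _battery_pvalues(designs, Y).reshape(k, reps, 3)
        fwer = float((p.min(axis=(0, 2)) < 0.05 / 54).mean())
        assert fwer <= 0.09
        assert fwer >= 0.005  # the battery is actually testing something


def _regression_frame(n, rng, beta=2.0, noise=0.0):
    age = rng.normal(50, 10, n)
    duration = rng.gamma(4, 4, n)
    employed = (rng.random(n) < 0.5).astype(float)
    income = rng.integers(1, 10, n).astype(float)
    feat = rng.random(n)
    y = beta * feat + 0.1 * age + 0.2 * duration - 1.0 * employed + 0.3 * income
    if noise:
        y = y + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "pct_negative_influence": feat,
            "msrs_r": y,
            "age": age,
            "disease_duration": duration,
            "employed": employed,
            "income": income,
        }
    )


class TestFeatureOutcomeRegression:
    def test_noise_free_outcome_recovers_beta_exactly(self, rng):
        data = _regression_frame(80, rng, beta=2.0, noise=0.0)
        res = feature_outcome_regression(
            data, "pct_negative_influence", "msrs_r",
            ("age", "disease_duration", "employed", "income"),
        )
        assert res.beta == pytest.approx(2.0, abs=1e-8)
        assert res.ci_low <= res.beta <= res.ci_high
        assert res.n == 80

    def test_agrees_with_normal_equations(self, rng):
        data = _regression_frame(50, rng, beta=1.3, noise=2.0)
        res = feature_outcome_regression(
            data, "pct_negative_influence", "msrs_r",
            ("age", "disease_duration", "employed", "income"),
        )
        X = np.column_stack(
            [
                np.ones(50),
                data["pct_negative_influence"],
                data[["age", "disease_duration", "employed", "income"]],
            ]
        )
        closed = np.linalg.solve(X.T @ X, X.T @ data["msrs_r"].to_numpy())
        assert res.beta == pytest.approx(closed[1], abs=1e-8)

    def test_permuted_outcome_gives_nominal_type_one_error(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            data = _regression_frame(40, rng, beta=0.8, noise=2.0)
            data["msrs_r"] = rng.permutation(data["msrs_r"].to_numpy())
            res = feature_outcome_regression(
                data, "pct_negative_influence", "msrs_r", ("age", "income")
            )
            rejections += res.p < 0.05
        # binomial(400, .05): central 99% range
        assert 7 <= rejections <= 36

    def test_rank_deficient_design_names_collinear_columns(self, rng):
        data = _regression_frame(40, rng)
        data["income"] = 2 * data["age"]  # exact collinearity
        with pytest.raises(ValueError, match="rank deficient"):
            feature_outcome_regression(
                data, "pct_negative_influence", "msrs_r", ("age", "income")
            )

    def test_too_few_complete_cases_rejected(self, rng):
        data = _regression_frame(8, rng)
        with pytest.raises(ValueError, match="complete cases"):
            feature_outcome_regression(
                data, "pct_negative_influence", "msrs_r",
                ("age", "disease_duration", "employed", "income"),
            )


def _moderation_frame(n, rng, slope_ms, slope_ctl, noise=0.0, covariates=True):
    half = n // 2
    group = np.array(["pwMS"] * half + ["control"] * (n - half))
    feat = rng.random(n)
    age = rng.normal(50, 10, n)
    employed = (rng.random(n) < 0.5).astype(float)
    income = rng.integers(1, 10, n).astype(float)
    slope = np.where(group == "pwMS", slope_ms, slope_ctl)
    y = slope * feat + (0.1 * age + 1.0 * employed + 0.2 * income if covariates else 0.0)
    y = y - 2.0 * (group == "pwMS")
    if noise:
        y = y + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "group": group,
            "pct_drink": feat,
            "promis_pf": y,
            "age": age,
            "employed": employed,
            "income": income,
        }
    )


class TestModeration:
    def test_equal_slopes_give_zero_interaction(self, rng):
        data = _moderation_frame(120, rng, slope_ms=1.5, slope_ctl=1.5)
        res = moderation_analysis(data, "pct_drink")
        assert res.interaction_beta == pytest.approx(0.0, abs=1e-8)

    def test_opposite_slopes_recovered(self, rng):
        data = _moderation_frame(200, rng, slope_ms=-1.0, slope_ctl=1.0, noise=0.3)
        res = moderation_analysis(data, "pct_drink")
        assert res.interaction_beta == pytest.approx(-2.0, abs=0.4)
        assert res.slope_pwms < 0 < res.slope_control
        assert res.interaction_p < 0.001

    def test_slope_identity_and_anchors(self, rng):
        data = _moderation_frame(150, rng, slope_ms=0.7, slope_ctl=-0.4, noise=1.0)
        res = moderation_analysis(data, "pct_drink")
        # fit again to extract raw coefficients for the identity check
        df = data.copy()
        df["ms"] = (df["group"] == "pwMS").astype(float)
        df["fx"] = df["pct_drink"] * df["ms"]
        X = sm.add_constant(df[["pct_drink", "ms", "fx", "age", "employed", "income"]])
        fit = sm.OLS(df["promis_pf"], X).fit()
        assert res.slope_pwms == pytest.approx(
            fit.params["pct_drink"] + fit.params["fx"], abs=1e-9
        )
        assert res.slope_control == pytest.approx(fit.params["pct_drink"], abs=1e-9)
        q = data["pct_drink"].quantile([0.25, 0.5, 0.75]).to_numpy()
        assert np.allclose(res.percentile_anchors, q)

    def test_slopes_match_stratified_fits_without_covariates(self, rng):
        data = _moderation_frame(160, rng, slope_ms=0.9, slope_ctl=0.2, noise=1.0,
                                 covariates=False)
        res = moderation_analysis(data, "pct_drink", covariates=())
        for grp, slope in (("pwMS", res.slope_pwms), ("control", res.slope_control)):
            sub = data[data["group"] == grp]
            fit = sm.OLS(sub["promis_pf"], sm.add_constant(sub[["pct_drink"]])).fit()
            assert slope == pytest.approx(fit.params["pct_drink"], abs=1e-9)

    def test_single_group_rejected(self, rng):
        data = _moderation_frame(60, rng, 1.0, 1.0)
        with pytest.raises(ValueError, match="both groups"):
            moderation_analysis(data[data["group"] == "pwMS"], "pct_drink")
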
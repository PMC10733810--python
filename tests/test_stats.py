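"""Tests of the mixed-model, FP1 and correlation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from csfclear import stats as cs


def _longitudinal(rng, n_subj=28, n_dep=7, per_day=4, between=5.0, within=3.0,
                  interaction=0.0, day_effect=0.0, overnight_sd=0.0):
    rows = []
    for i in range(n_subj):
        group = "sleep_deprivation" if i < n_dep else "sleep"
        b = rng.normal(0.0, between)
        d = rng.normal(0.0, overnight_sd)
        for day in (1, 2):
            shift = day_effect * (day == 2)
            if group == "sleep_deprivation" and day == 2:
                shift += interaction
            for _ in range(per_day):
                rows.append(dict(
                    subject_id=f"S{i:02d}", group=group, day=day,
                    conc=90.0 + b + shift + d * (day == 2)
                    + rng.normal(0.0, within)))
    return pd.DataFrame(rows)


class TestOvernightChange:
    def test_difference_of_day_means(self):
        df = pd.DataFrame({
            "subject_id": ["A"] * 4, "biomarker": ["AB40"] * 4,
            "day": [1, 1, 2, 2], "conc": [90.0, 92.0, 80.0, 82.0]})
        out = cs.overnight_change(df)
        assert out.loc[0, "delta"] == pytest.approx(-10.0)

    def test_identical_days_give_zero(self):
        df = pd.DataFrame({
            "subject_id": ["A"] * 2, "biomarker": ["NFL"] * 2,
            "day": [1, 2], "conc": [8.5, 8.5]})
        assert cs.overnight_change(df).loc[0, "delta"] == 0.0

    def test_missing_day_omitted_not_raised(self, caplog):
        df = pd.DataFrame({
            "subject_id": ["A", "A", "B"], "biomarker": ["AB40"] * 3,
            "day": [1, 2, 1], "conc": [90.0, 85.0, 70.0]})
        with caplog.at_level("WARNING", logger="csfclear.stats"):
            out = cs.overnight_change(df)
        assert list(out["subject_id"]) == ["A"]
        assert any("skipped" in r.message for r in caplog.records)


class TestRandomInterceptLMM:
    def test_reduces_to_ols_without_between_subject_variance(self):
        rng = np.random.default_rng(0)
        df = _longitudinal(rng, between=0.0, interaction=-12.0)
        df["day2"] = (df["day"] == 2).astype(float)
        df["dep"] = (df["group"] == "sleep_deprivation").astype(float)
        df["dep_day2"] = df["day2"] * df["dep"]
        res = cs.fit_random_intercept_lmm(
            df, "conc", ["dep", "day2", "dep_day2"], heteroscedastic_by=None)
        X = np.column_stack([np.ones(len(df)), df["dep"], df["day2"],
                             df["dep_day2"]])
        beta_ols = np.linalg.lstsq(X, df["conc"].to_numpy(), rcond=None)[0]
        beta = [v[0] for v in res.fixed_effects.values()]
        np.testing.assert_allclose(beta, beta_ols, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(1)
        df = _longitudinal(rng, interaction=-12.0)
        res = cs.group_day_interaction(df, heteroscedastic_by=None)
        d2 = df.copy()
        d2["day"] = d2["day"].astype(str)
        mm = smf.mixedlm("conc ~ group*day", d2,
                         groups=d2["subject_id"]).fit(reml=False)
        assert res.loglik == pytest.approx(mm.llf, abs=1e-4)
        ours = res.fixed_effects["group[sleep_deprivation]:day[2]"][0]
        theirs = mm.params["group[T.sleep_deprivation]:day[T.2]"]
        assert ours == pytest.approx(theirs, abs=1e-5)

    def test_interaction_recovery_within_ci(self):
        rng = np.random.default_rng(7)
        df = _longitudinal(rng, interaction=-12.0)
        res = cs.group_day_interaction(df)
        est, se, p = res.contrast()
        assert est - 1.96 * se <= -12.0 <= est + 1.96 * se
        assert p < 0.05

    def test_rank_deficiency_names_terms(self):
        rng = np.random.default_rng(2)
        df = _longitudinal(rng)
        df["day"] = 1  # day constant -> interaction collinear
        df["day"] = df["day"].astype(str)
        df["group"] = df["group"].astype(str)
        with pytest.raises(cs.RankDeficientError, match="collinear"):
            cs.fit_random_intercept_lmm(df, "conc", ["group", "day"])

    def test_single_observation_rejected(self):
        df = pd.DataFrame({"subject_id": ["A"], "conc": [1.0],
                           "group": ["sleep"], "day": [1]})
        with pytest.raises(ValueError):
            cs.fit_random_intercept_lmm(df, "conc", ["group"])

    def test_heteroscedastic_residuals_estimated_per_day(self):
        rng = np.random.default_rng(3)
        df = _longitudinal(rng, n_subj=40, within=1.0)
        bump = rng.normal(0.0, 5.0, size=(df["day"] == 2).sum())
        df.loc[df["day"] == 2, "conc"] += bump  # Day-2 noise much larger
        res = cs.fit_random_intercept_lmm(df, "conc", ["day"],
                                          heteroscedastic_by="day")
        assert res.residual_var["2"] > 4 * res.residual_var["1"]


class TestDay2Comparison:
    def test_recovers_programmed_contrast(self):
        rng = np.random.default_rng(11)
        df = _longitudinal(rng, interaction=-12.0)
        res = cs.day2_group_comparison(df)
        est, se, _ = res.contrast()
        assert est - 2.5 * se <= -12.0 <= est + 2.5 * se

    def test_single_group_rejected(self):
        rng = np.random.default_rng(4)
        df = _longitudinal(rng)
        with pytest.raises(ValueError, match="group"):
            cs.day2_group_comparison(df[df.group == "sleep"])

    def test_group_missing_day_rejected(self):
        rng = np.random.default_rng(4)
        df = _longitudinal(rng)
        broken = df[~((df.group == "sleep_deprivation") & (df.day == 2))]
        with pytest.raises(ValueError, match="day"):
            cs.day2_group_comparison(broken)


class TestFP1:
    def test_linear_data_selects_power_one_and_ols_slope(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(7.0, 21.0, 112)
        y = 2.0 + 3.0 * t + rng.normal(0.0, 1.0, 112)
        res = cs.fp1_regression(t, y, np.repeat(np.arange(28), 4))
        assert res.power == 1.0
        slope_ols = np.polyfit(t, y, 1)[0]
        assert res.coefficients["slope"] == pytest.approx(slope_ols, rel=1e-8)

    def test_log_generated_data_selects_log(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(1.0, 24.0, 112)
        y = 90.0 + 10.0 * np.log(t) + rng.normal(0.0, 2.0, 112)
        res = cs.fp1_regression(t, y, np.repeat(np.arange(28), 4))
        assert res.power == 0.0

    def test_constant_outcome_flat_band(self):
        t = np.linspace(1.0, 24.0, 20)
        res = cs.fp1_regression(t, np.full(20, 5.0), np.arange(20))
        assert res.coefficients["slope"] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.prediction["mean"], 5.0)
        assert (res.prediction["hi95"] >= res.prediction["lo95"]).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10"):
            cs.fp1_regression([1, 2, 3], [1, 2, 3], [1, 2, 3])

    def test_nonpositive_times_shifted(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 12.0, 0.5)
        y = 1.0 + t + rng.normal(0.0, 0.1, len(t))
        res = cs.fp1_regression(t, y, np.arange(len(t)))
        assert res.shift > 0


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(7, dtype=float)
        res = cs.pearson_panel(x, 2 * x + 1, ["g"] * 7)["g"]
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_perfect_anticorrelation(self):
        res = cs.pearson_panel([1, 2, 3], [3, 2, 1], ["g"] * 3)["g"]
        assert res.r == pytest.approx(-1.0)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance_and_sign_flip(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = cs.pearson_panel(x, y, ["g"] * 12)["g"].r
        scaled = cs.pearson_panel(a * x + b, y, ["g"] * 12)["g"].r
        flipped = cs.pearson_panel(-a * x + b, y, ["g"] * 12)["g"].r
        assert scaled == pytest.approx(base, abs=1e-10)
        assert flipped == pytest.approx(-base, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cs.pearson_panel([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], ["g"] * 3)

    def test_computed_per_group(self):
        x = np.r_[np.arange(5.0), np.arange(5.0)]
        y = np.r_[np.arange(5.0), -np.arange(5.0)]
        g = ["sleep"] * 5 + ["dep"] * 5
        res = cs.pearson_panel(x, y, g)
        assert res["sleep"].r == pytest.approx(1.0)
        assert res["dep"].r == pytest.approx(-1.0)

    def test_t_based_p_matches_permutation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        res = cs.pearson_panel(x, y, ["g"] * 10)["g"]
        n_perm = 20000
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        perm = np.array([np.abs(xs @ rng.permutation(ys)) / 10
                         for _ in range(n_perm)])
        p_perm = float(np.mean(perm >= abs(res.r) - 1e-12))
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) <= 3 * mc_se + 1e-12


class TestAbRatio:
    def test_reported_day2_sleep_means(self):
        # ratio of the reported Day-2 sleep-group means rounds to 0.069
        assert round(cs.ab_ratio(6.3, 91.6), 3) == 0.069

    def test_equal_inputs_give_one(self):
        assert cs.ab_ratio(5.0, 5.0) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            cs.ab_ratio(1.0, 0.0)
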
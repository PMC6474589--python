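"""Deviation summaries, stratified regressions and slope comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methclock as mc
from methclock.clock_core import ClockAgeResult, SampleAnnotation
from methclock.comparison_stats import RegressionFit


def _results(values, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return [
        ClockAgeResult(sample_id=s, dnam_age=float(v), transformed_score=float(v),
                       n_probes_used=1, n_probes_imputed=0, clock_name="c",
                       imputation_policy="none")
        for s, v in zip(ids, values)
    ]


def closed_form_ols(x, y):
    """Textbook normal-equation OLS: (X'X)^-1 X'y with analytic SEs."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(x) - 2
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, resid


class TestPairedDeviationSummary:
    def test_identical_runs(self):
        vals = [10.0, 20.0, 30.0]
        rep = mc.paired_deviation_summary(_results(vals), _results(vals))
        assert rep.deviation_mean == 0.0
        assert rep.deviation_sd == 0.0
        assert rep.corr_full_reduced == 1.0
        assert rep.paired_p == 1.0

    def test_hand_computed_mean_and_sd(self):
        rep = mc.paired_deviation_summary(_results([10, 20, 30]),
                                          _results([8, 17, 27]))
        assert rep.deviation_mean == pytest.approx(2.6667, abs=1e-4)
        assert rep.deviation_sd == pytest.approx(0.5774, abs=1e-4)
        # paired t on (2,3,3)
        t, p = stats.ttest_1samp([2.0, 3.0, 3.0], 0.0)
        assert rep.paired_t == pytest.approx(t)
        assert rep.paired_p == pytest.approx(p)

    def test_age_bins_are_closed_open(self):
        ids = ["a", "b", "c", "d"]
        ann = SampleAnnotation(pd.DataFrame(
            {"age": [0.0, 4.99, 5.0, 9.0], "dataset": "d"}, index=ids))
        rep = mc.paired_deviation_summary(
            _results([1, 2, 3, 4], ids), _results([0, 0, 0, 0], ids),
            annotation=ann, bin_width=5.0)
        assert rep.by_age_bin.loc["[0,5)", "n"] == 2
        assert rep.by_age_bin.loc["[5,10)", "n"] == 2
        assert rep.by_age_bin.loc["[0,5)", "mean"] == pytest.approx(1.5)

    def test_samples_without_age_kept_overall_excluded_from_bins(self):
        ids = ["a", "b", "c"]
        ann = SampleAnnotation(pd.DataFrame(
            {"age": [10.0, np.nan, 30.0]}, index=ids))
        rep = mc.paired_deviation_summary(
            _results([5, 6, 7], ids), _results([4, 4, 4], ids), annotation=ann)
        assert rep.n == 3
        assert rep.by_age_bin["n"].sum() == 2

    def test_sample_mismatch_is_error(self):
        with pytest.raises(ValueError, match="different samples"):
            mc.paired_deviation_summary(_results([1, 2], ["a", "b"]),
                                        _results([1, 2], ["a", "c"]))

    def test_nonpositive_bin_width_is_error(self):
        with pytest.raises(ValueError):
            mc.paired_deviation_summary(_results([1]), _results([1]),
                                        bin_width=0.0)


class TestStratifiedRegression:
    def test_identity_relationship(self):
        ages = pd.Series(np.linspace(1, 80, 40))
        fits = mc.stratified_clock_regression(ages, ages, cutoff=20.0)
        for fit in fits.values():
            assert fit.slope == pytest.approx(1.0, abs=1e-10)
            assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_exact_recovery_of_noiseless_line(self):
        ages = pd.Series(np.linspace(25, 90, 30))
        dnam = 0.85 * ages + 7.0
        fits = mc.stratified_clock_regression(dnam, ages, cutoff=20.0)
        assert set(fits) == {"above"}  # no samples below the cutoff
        assert fits["above"].slope == pytest.approx(0.85, abs=1e-10)
        assert fits["above"].intercept == pytest.approx(7.0, abs=1e-8)

    def test_small_stratum_omitted_with_warning(self, caplog):
        ages = pd.Series([5.0, 30.0, 40.0, 50.0, 60.0])
        with caplog.at_level("WARNING"):
            fits = mc.stratified_clock_regression(ages, ages, cutoff=20.0)
        assert "below" not in fits
        assert "omitted" in caplog.text

    def test_recovers_generative_slope_within_two_se(self):
        """Simulation oracle: with noise, the fitted slope should fall
        within 2 SE of the generative slope in >=95% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ages = pd.Series(rng.uniform(20, 100, 500))
            dnam = 0.85 * ages + 7.0 + rng.normal(0, 3.0, 500)
            fit = mc.stratified_clock_regression(dnam, ages, cutoff=20.0)["above"]
            hits += abs(fit.slope - 0.85) <= 2 * fit.se_slope
        assert hits / n_seeds >= 0.95


class TestCompareSlopes:
    def test_identical_fits(self):
        ages = pd.Series(np.linspace(0, 50, 20))
        fit = mc.ols_fit(ages.to_numpy(), (2 * ages + 1).to_numpy())
        t, p = mc.compare_slopes(fit, fit)
        assert t == 0.0
        assert p == 1.0

    def test_hand_arithmetic_large_n(self):
        fit_a = RegressionFit(intercept=0, slope=1.0, se_intercept=0.1,
                              se_slope=0.1, ci_intercept=(0, 0), ci_slope=(0, 0),
                              n=100000, df_resid=99998,
                              residuals=np.zeros(1))
        fit_b = RegressionFit(intercept=0, slope=0.6, se_intercept=0.1,
                              se_slope=0.1, ci_intercept=(0, 0), ci_slope=(0, 0),
                              n=100000, df_resid=99998,
                              residuals=np.zeros(1))
        t, p = mc.compare_slopes(fit_a, fit_b)
        assert t == pytest.approx(0.4 / np.sqrt(0.02), abs=1e-9)  # 2.828
        assert p == pytest.approx(0.0047, abs=5e-4)

    def test_equal_slopes_noiseless_lines(self):
        x1 = np.linspace(0, 10, 10)
        x2 = np.linspace(5, 25, 12)
        fit_a = mc.ols_fit(x1, 2.0 * x1 + 1.0)
        fit_b = mc.ols_fit(x2, 2.0 * x2 - 4.0)
        t, p = mc.compare_slopes(fit_a, fit_b)
        assert p == 1.0


class TestAgeAcceleration:
    def test_identity_gives_zero_residuals(self):
        ages = pd.Series(np.linspace(10, 60, 10), index=[f"s{i}" for i in range(10)])
        accel = mc.age_acceleration(ages, ages)
        assert np.allclose(accel, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(5)
        ages = pd.Series(rng.uniform(0, 90, 50))
        dnam = pd.Series(0.9 * ages + rng.normal(0, 5, 50))
        accel = mc.age_acceleration(dnam, ages)
        assert abs(accel.sum()) < 1e-9

    def test_five_point_hand_ols(self):
        ages = pd.Series([30.0, 40.0, 50.0, 60.0, 70.0])
        dnam = pd.Series([33.0, 39.0, 55.0, 58.0, 76.0])
        beta, _, resid = closed_form_ols(ages.to_numpy(), dnam.to_numpy())
        accel = mc.age_acceleration(dnam, ages, direction="dnam_on_age")
        assert accel.to_numpy() == pytest.approx(resid, abs=1e-10)

    def test_inverted_direction(self):
        ages = pd.Series([30.0, 40.0, 50.0, 60.0, 70.0])
        dnam = pd.Series([33.0, 39.0, 55.0, 58.0, 76.0])
        beta, _, resid = closed_form_ols(dnam.to_numpy(), ages.to_numpy())
        accel = mc.age_acceleration(dnam, ages, direction="age_on_dnam")
        assert accel.to_numpy() == pytest.approx(resid, abs=1e-10)

    def test_missing_ages_excluded(self):
        ages = pd.Series([30.0, np.nan, 50.0, 60.0, 70.0])
        dnam = pd.Series([33.0, 39.0, 55.0, 58.0, 76.0])
        accel = mc.age_acceleration(dnam, ages)
        assert len(accel) == 4


class TestAccelerationCovariateRegression:
    def _accel(self, rng, n=100):
        idx = [f"s{i}" for i in range(n)]
        return pd.Series(rng.normal(0, 3, n), index=idx), pd.Series(
            rng.choice(["female", "male"], n), index=idx)

    def test_identical_versions_give_p_one(self):
        rng = np.random.default_rng(0)
        accel, sex = self._accel(rng)
        out = mc.acceleration_covariate_regression(accel, accel, sex,
                                                   covariate_name="sex")
        assert out.slope_p == pytest.approx(1.0)

    def test_constant_offset_gives_identical_slopes(self):
        rng = np.random.default_rng(1)
        accel, sex = self._accel(rng)
        out = mc.acceleration_covariate_regression(accel, accel - 3.0, sex)
        assert out.fit_full.slope == pytest.approx(out.fit_reduced.slope,
                                                   abs=1e-10)
        assert out.slope_p == pytest.approx(1.0)

    def test_constant_covariate_is_error(self):
        rng = np.random.default_rng(2)
        accel, _ = self._accel(rng)
        sex = pd.Series("female", index=accel.index)
        with pytest.raises(ValueError, match="constant"):
            mc.acceleration_covariate_regression(accel, accel, sex)

    def test_reference_level_encoding(self):
        accel = pd.Series([1.0, 2.0, 5.0, 6.0], index=list("abcd"))
        sex = pd.Series(["male", "male", "female", "female"], index=list("abcd"))
        out = mc.acceleration_covariate_regression(accel, accel, sex,
                                                   reference="male")
        assert out.reference_level == "male"
        assert out.fit_full.slope == pytest.approx(4.0)  # female - male

    def test_null_effect_ci_coverage(self):
        """With no true covariate effect the 95% CI should cover zero in
        about 95% of repetitions (>=93% tolerated)."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            idx = [f"s{i}" for i in range(500)]
            accel_f = pd.Series(rng.normal(0, 3, 500), index=idx)
            accel_r = accel_f + rng.normal(0, 0.5, 500)
            cov = pd.Series(rng.choice(["female", "male"], 500), index=idx)
            out = mc.acceleration_covariate_regression(accel_f, accel_r, cov)
            lo, hi = out.fit_full.ci_slope
            hits += lo <= 0.0 <= hi
        assert hits / n_seeds >= 0.93


class TestPlatformOffset:
    def test_exact_constant_shift(self):
        ages = np.linspace(20, 80, 30)
        dnam_a = 0.9 * ages + 5
        dnam_b = dnam_a - 4.0
        dnam = pd.Series(np.concatenate([dnam_a, dnam_b]))
        platform = pd.Series(["450k"] * 30 + ["850k"] * 30)
        chrono = pd.Series(np.concatenate([ages, ages]))
        off = mc.platform_offset_regression(dnam, platform, chrono, "450k")
        assert off.offset == pytest.approx(-4.0, abs=1e-9)
        assert off.other_platform == "850k"

    def test_single_platform_is_error(self):
        dnam = pd.Series([1.0, 2.0, 3.0, 4.0])
        platform = pd.Series(["450k"] * 4)
        chrono = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="two platforms"):
            mc.platform_offset_regression(dnam, platform, chrono, "450k")

    def test_identical_distributions_offset_near_zero(self):
        """Null calibration: |offset| < 2 SE in >=93% of 200 seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ages = rng.uniform(20, 90, 400)
            dnam = 0.8 * ages + 8 + rng.normal(0, 4, 400)
            platform = pd.Series(np.where(rng.random(400) < 0.5, "450k", "850k"))
            off = mc.platform_offset_regression(
                pd.Series(dnam), platform, pd.Series(ages), "450k")
            hits += abs(off.offset) < 2 * off.se
        assert hits / n_seeds >= 0.93


class TestOlsAgainstClosedForm:
    def test_matches_normal_equations_on_random_instances(self):
        rng = np.random.default_rng(100)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.normal(0, 10, n)
            y = rng.normal(0, 1) * x + rng.normal(0, 5) + rng.normal(0, 2, n)
            fit = mc.ols_fit(x, y)
            beta, se, resid = closed_form_ols(x, y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            assert fit.slope == pytest.approx(beta[1], abs=1e-8)
            assert fit.se_intercept == pytest.approx(se[0], abs=1e-8)
            assert fit.se_slope == pytest.approx(se[1], abs=1e-8)
            assert fit.residuals == pytest.approx(resid, abs=1e-8)
            tcrit = stats.t.ppf(0.975, n - 2)
            assert fit.ci_slope[0] == pytest.approx(beta[1] - tcrit * se[1],
                                                    abs=1e-8)
            assert fit.ci_slope[1] == pytest.approx(beta[1] + tcrit * se[1],
                                                    abs=1e-8)
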
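"""Trend regression: recovery, deviance explained, scenario construction."""

import numpy as np
import pandas as pd
import pytest

import abxasthma as ax
from abxasthma.trends import TrendResults, build_scenarios

YEARS = range(2001, 2019)


class TestFit:
    def test_noise_free_data_recovers_generating_slopes_exactly(self):
        truth = ax.TrendTruth()
        data = ax.gen_prescription_data(truth, YEARS, seed=0, noise="none")
        fit = ax.PrescriptionTrendModel(data).fit()
        assert abs(fit.slope_pre - truth.slope_pre) < 1e-6
        assert abs(fit.slope_post - truth.slope_post) < 1e-6
        assert abs(fit.params["const"] - truth.intercept_log_rate) < 1e-6
        assert abs(fit.params["male"] - truth.sex_effect) < 1e-6

    def test_sex_coefficient_ci_covers_zero_when_no_sex_effect(self):
        """95% CI of the sex term covers 0 in >= 90 of 100 seeded datasets."""
        truth = ax.TrendTruth(sex_effect=0.0)
        covered = 0
        for seed in range(100):
            data = ax.gen_prescription_data(truth, YEARS, seed=seed)
            fit = ax.PrescriptionTrendModel(data).fit()
            lo, hi = fit.conf_int().loc["male"]
            covered += lo <= 0.0 <= hi
        assert covered >= 90

    def test_row_splitting_leaves_mean_structure_unchanged(self, rate_table):
        """Splitting each count across duplicate half-rows leaves coefficients
        essentially unchanged.  The invariance is exact for the Poisson
        likelihood; under NB2 the variance weights shift slightly with the
        per-row mean, so agreement is to ~1e-3 rather than machine precision
        (the noise-free Poisson-limit case is covered by the exact recovery
        test above)."""
        halves = rate_table.copy()
        halves["births"] = halves["births"] / 2
        halves["prescriptions"] = halves["prescriptions"] / 2
        split = pd.concat([halves, halves], ignore_index=True)
        split = split.drop(columns="rate_per_1000")
        a = ax.PrescriptionTrendModel(rate_table).fit()
        b = ax.PrescriptionTrendModel(split).fit()
        assert np.allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-3)

    def test_self_consistency_round_trip(self, trend_fit):
        """Regenerating data from fitted coefficients recovers them (1e6 births)."""
        refit_truth = ax.TrendTruth(
            intercept_log_rate=float(trend_fit.params["const"]),
            slope_pre=trend_fit.slope_pre,
            slope_post=trend_fit.slope_post,
            sex_effect=float(trend_fit.params["male"]),
            dispersion=np.inf,
            default_births=1_000_000,
        )
        data = ax.gen_prescription_data(refit_truth, YEARS, seed=77)
        refit = ax.PrescriptionTrendModel(data).fit()
        assert abs(refit.slope_pre - trend_fit.slope_pre) < 1e-3
        assert abs(refit.slope_post - trend_fit.slope_post) < 1e-3

    def test_collinear_design_raises_naming_columns(self):
        # only one post-break year makes post and year_post identical columns
        rows = []
        for year in (2003, 2004, 2005, 2006):
            for sex in ("female", "male"):
                rows.append({"year": year, "sex": sex, "births": 1000, "prescriptions": 500})
        with pytest.raises(ValueError, match="post"):
            ax.PrescriptionTrendModel(pd.DataFrame(rows)).fit()

    def test_years_on_one_side_of_break_drop_breakpoint_terms(self, caplog):
        truth = ax.TrendTruth(break_year=2010)
        data = ax.gen_prescription_data(truth, range(2006, 2019), seed=1)
        model = ax.PrescriptionTrendModel(data, break_year=2001)
        fit = model.fit()
        assert "post" not in fit.params.index

    def test_validation_errors(self, rate_table):
        with pytest.raises(ValueError, match="4 distinct years"):
            ax.PrescriptionTrendModel(rate_table[rate_table.year <= 2003])
        with pytest.raises(ValueError, match="both sexes"):
            ax.PrescriptionTrendModel(rate_table[rate_table.sex == "female"])
        bad = rate_table.copy()
        bad.loc[0, "births"] = 0
        with pytest.raises(ValueError, match="births"):
            ax.PrescriptionTrendModel(bad)


class TestDevianceExplained:
    def test_near_noiseless_fit_explains_over_99_percent(self):
        truth = ax.TrendTruth(dispersion=np.inf, default_births=1_000_000)
        data = ax.gen_prescription_data(truth, YEARS, seed=4)
        fit = ax.PrescriptionTrendModel(data).fit()
        assert fit.deviance_explained() > 99.0

    def test_null_model_explains_zero(self, rate_table, trend_fit):
        """Forcing all non-intercept terms to the null solution gives 0%."""
        import statsmodels.api as sm

        y = rate_table["prescriptions"].to_numpy(dtype=float)
        offset = np.log(rate_table["births"].to_numpy(dtype=float))
        fam = sm.families.NegativeBinomial(alpha=max(trend_fit.dispersion, 1e-8))
        null = sm.GLM(y, np.ones((len(y), 1)), family=fam, offset=offset).fit()
        params = pd.Series(0.0, index=trend_fit.params.index)
        params["const"] = null.params[0]
        forced = TrendResults(trend_fit.model, params, trend_fit.dispersion, trend_fit.cov_params)
        assert abs(forced.deviance_explained()) < 1e-6

    def test_invariant_to_sex_relabeling(self, rate_table, trend_fit):
        relabeled = rate_table.copy()
        relabeled["sex"] = relabeled["sex"].map({"female": "male", "male": "female"})
        refit = ax.PrescriptionTrendModel(relabeled).fit()
        assert np.isclose(refit.deviance_explained(), trend_fit.deviance_explained(), atol=1e-6)

    def test_bounded_between_zero_and_hundred(self, trend_fit):
        assert 0.0 <= trend_fit.deviance_explained() <= 100.0


class TestScenarios:
    def test_mid_is_pointwise_mean_of_base_and_flat(self, scenario_curves):
        for year in YEARS:
            for sex in ("female", "male"):
                b = scenario_curves["base"].rate(year, sex)
                f = scenario_curves["flat"].rate(year, sex)
                m = scenario_curves["mid"].rate(year, sex)
                assert m == pytest.approx((b + f) / 2, abs=1e-12)

    def test_flat_anchored_at_base_year_value(self, scenario_curves):
        for sex in ("female", "male"):
            assert scenario_curves["flat"].rate(2001, sex) == pytest.approx(
                scenario_curves["base"].rate(2001, sex)
            )
            values = [scenario_curves["flat"].rate(y, sex) for y in YEARS]
            assert len(set(values)) == 1

    def test_declining_base_orders_flat_above_mid_above_base(self, scenario_curves):
        for year in range(2006, 2019):
            for sex in ("female", "male"):
                b = scenario_curves["base"].rate(year, sex)
                m = scenario_curves["mid"].rate(year, sex)
                f = scenario_curves["flat"].rate(year, sex)
                assert f >= m >= b

    def test_base_curve_has_positive_rates_and_cis(self, scenario_curves):
        v = scenario_curves["base"].values
        assert (v["rate_per_1000"] > 0).all()
        assert (v["ci_low"] <= v["rate_per_1000"]).all()
        assert (v["rate_per_1000"] <= v["ci_high"]).all()

    def test_base_year_must_be_inside_years(self, trend_fit):
        with pytest.raises(ValueError, match="base_year"):
            build_scenarios(trend_fit, range(2005, 2019), base_year=2001)


class TestHeadlineRates:
    @pytest.mark.parametrize(
        "prescriptions, births, expected",
        [(404_675, 773_160, 523), (100, 1_000, 100)],
    )
    def test_mean_rate_per_1000(self, prescriptions, births, expected):
        table = pd.DataFrame(
            [{"year": 2001, "sex": "female", "births": births, "prescriptions": prescriptions}]
        )
        assert ax.mean_rate(table) == expected

    def test_percent_reduction_868_to_236_is_73(self):
        assert ax.percent_reduction(868, 236) == 73

    def test_mean_rate_errors(self):
        with pytest.raises(ValueError):
            ax.mean_rate(pd.DataFrame(columns=["births", "prescriptions"]))
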
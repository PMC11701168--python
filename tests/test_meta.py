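"""Harmonization rules, posterior recovery, and the dose-response function."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import abxasthma as ax
from abxasthma.meta import ConvergenceError, PriorSpec, SamplerConfig, prevalence_logit


def raw_study_rows():
    base = {
        "country": "Japan", "effect_scale": "OR", "se": 0.05, "risk_of_bias": 1,
        "original_research": True, "exposure_first_year": True,
    }
    return pd.DataFrame(
        [
            {**base, "study_id": "A", "age_low": 3, "age_high": 6, "dose_raw": "1-2", "log_effect": 0.1},
            {**base, "study_id": "B", "age_low": 4, "age_high": 5, "dose_raw": "3-4", "log_effect": 0.2},
            {**base, "study_id": "C", "age_low": 1, "age_high": 18, "dose_raw": "2", "log_effect": 0.3},
            {**base, "study_id": "D", "age_low": 3, "age_high": 4, "dose_raw": "5+", "log_effect": 0.4,
             "effect_scale": "HR", "country": "Canada"},
            {**base, "study_id": "E", "age_low": 3, "age_high": 4, "dose_raw": "2", "log_effect": 0.2,
             "se": np.nan},
            {**base, "study_id": "F", "age_low": 3, "age_high": 4, "dose_raw": "1", "log_effect": 0.1,
             "risk_of_bias": 3},
        ]
    )


class TestHarmonize:
    def test_midpoint_recoding_and_filters(self):
        out = ax.harmonize(raw_study_rows())
        assert set(out["study_id"]) == {"A", "B", "D"}
        a = out[out.study_id == "A"].iloc[0]
        assert a["age_mid"] == 4.5 and a["age_range_width"] == 3
        assert out[out.study_id == "B"]["dose"].iloc[0] == 3  # "3-4" -> 3
        assert out[out.study_id == "A"]["dose"].iloc[0] == 1  # "1-2" -> 1
        assert out[out.study_id == "D"]["dose"].iloc[0] == 5  # "5+" -> 5

    def test_wide_age_range_excluded(self):
        out = ax.harmonize(raw_study_rows())
        assert "C" not in set(out["study_id"])  # width 17 >= 6

    def test_hazard_ratios_relabeled_as_odds_ratios(self):
        out = ax.harmonize(raw_study_rows())
        assert (out["effect_scale"] == "OR").all()

    def test_canada_flag_derived_from_country(self):
        out = ax.harmonize(raw_study_rows())
        assert out.groupby("study_id")["canada_flag"].first().sum() == 1

    def test_all_rows_filtered_raises(self):
        rows = raw_study_rows()
        rows["risk_of_bias"] = 3
        with pytest.raises(ValueError, match="filtered out"):
            ax.harmonize(rows)


class TestFit:
    def test_posterior_recovers_truth_in_low_noise_limit(self):
        truth = ax.MetaTruth(
            beta0=0.3, beta_age=-0.1, beta_dose=0.05, sigma_u=0.0,
            canada_effect=0.0, se_range=(1e-4, 1e-4),
        )
        table = ax.gen_meta_studies(truth, seed=8)
        res = ax.DoseResponseMeta(table).fit(seed=8)
        assert res.posterior.mean("beta0") == pytest.approx(0.3, abs=5e-3)
        assert res.posterior.mean("beta_age") == pytest.approx(-0.1, abs=2e-3)
        assert res.posterior.mean("beta_dose") == pytest.approx(0.05, abs=2e-3)

    def test_diagnostics_attached_and_converged(self, meta_results):
        s = meta_results.summary()
        assert {"beta0", "beta_canada", "beta_age", "beta_dose", "sigma_u_sq"} <= set(s.index)
        assert (s["rhat"] <= 1.01).all()
        assert (s["ess"] > 400).all()
        assert (meta_results.posterior.draws["sigma_u_sq"] >= 0).all()

    def test_same_seed_reproduces_identical_summaries(self, meta_table):
        a = ax.DoseResponseMeta(meta_table).fit(seed=5).summary()
        b = ax.DoseResponseMeta(meta_table).fit(seed=5).summary()
        pd.testing.assert_frame_equal(a, b)

    def test_single_study_rejected(self, meta_table):
        one = meta_table[meta_table.study_id == "S00"]
        with pytest.raises(ValueError, match="2 studies"):
            ax.DoseResponseMeta(one)

    def test_multiple_canada_studies_rejected(self, meta_table):
        t = meta_table.copy()
        t["canada_flag"] = True
        with pytest.raises(ValueError, match="Canada"):
            ax.DoseResponseMeta(t)

    def test_improper_prior_spec_raises_config_error(self):
        with pytest.raises(ValueError, match="improper prior"):
            PriorSpec.from_dict({"beta_sd": 10, "bogus_scale": 1})
        with pytest.raises(ValueError, match="positive"):
            PriorSpec(beta_sd=-1)

    def test_divergent_pseudo_chains_fail_the_diagnostics_gate(self, meta_table):
        model = ax.DoseResponseMeta(meta_table)
        rng = np.random.default_rng(0)
        posterior = {"beta0": np.vstack([rng.normal(0, 1, 500), rng.normal(50, 1, 500)])}
        for name in ["beta_age", "beta_dose", "sigma_u"] + [f"u_{s}" for s in model.study_ids]:
            posterior[name] = np.abs(rng.normal(0, 1, (2, 500)))
        with pytest.raises(ConvergenceError, match="beta0"):
            model._finalize(posterior, SamplerConfig())

    def test_emcee_path_agrees_with_exact_sampler(self, meta_table):
        exact = ax.DoseResponseMeta(meta_table).fit(seed=3)
        mcmc = ax.DoseResponseMeta(meta_table).fit(
            seed=3,
            config=SamplerConfig(method="emcee", n_steps=8000, n_burn=3000,
                                 check_convergence=False),
        )
        for p in ("beta0", "beta_age", "beta_dose"):
            assert mcmc.posterior.mean(p) == pytest.approx(exact.posterior.mean(p), abs=5e-3)

    def test_fixed_effects_match_metafor_reml(self, meta_table):
        """Independent oracle: R/metafor multilevel meta-regression.

        With weak priors and informative data the posterior means of the
        fixed effects should sit close to the REML estimates.
        """
        csv = meta_table.to_csv(index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(metafor))
            d <- read.csv("stdin")
            d$vi <- d$se^2
            res <- rma.mv(log_effect, vi, mods = ~ age_mid + dose,
                          random = ~ 1 | study_id, data = d, method = "REML")
            cat(coef(res), sep = ",")
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], input=csv, capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        b0, b_age, b_dose = (float(v) for v in proc.stdout.strip().split(","))
        res = ax.DoseResponseMeta(meta_table).fit(seed=3)
        assert res.posterior.mean("beta_age") == pytest.approx(b_age, abs=0.02)
        assert res.posterior.mean("beta_dose") == pytest.approx(b_dose, abs=0.02)
        assert res.posterior.mean("beta0") == pytest.approx(b0, abs=0.15)

    def test_heldout_study_prediction_interval_coverage(self):
        """Posterior predictive interval contains a held-out study ~95% of seeds."""
        truth = ax.MetaTruth(beta_dose=0.05, sigma_u=0.15, n_studies=7, se_range=(0.05, 0.05))
        inside = 0
        n_seeds = 40
        for seed in range(n_seeds):
            table = ax.gen_meta_studies(truth, seed=seed)
            held = table[table.study_id == "S06"]
            res = ax.DoseResponseMeta(table[table.study_id != "S06"]).fit(seed=seed)
            d = res.posterior.draws
            rng = np.random.default_rng(seed + 10_000)
            row = held.iloc[0]
            u_new = rng.normal(0.0, np.sqrt(d["sigma_u_sq"]))
            pred = (
                d["beta0"] + d["beta_age"] * row["age_mid"] + d["beta_dose"] * row["dose"]
                + u_new + rng.normal(0.0, row["se"], size=len(u_new))
            )
            lo, hi = np.quantile(pred, [0.025, 0.975])
            inside += lo <= row["log_effect"] <= hi
        assert inside / n_seeds >= 0.85


class TestDoseResponse:
    def test_point_or_values(self, dose_response):
        assert dose_response.or_at(3, 1) == pytest.approx(1.05, abs=0.005)
        assert dose_response.or_at(5, 0) == 1.0
        assert dose_response.or_at(8, 5) == 1.0  # effect gone beyond age 7

    def test_or_nondecreasing_in_dose(self, dose_response):
        ors = [dose_response.or_at(4, d) for d in range(6)]
        assert all(b >= a for a, b in zip(ors, ors[1:]))

    def test_dose_clamped_with_warning(self, dose_response):
        with pytest.warns(UserWarning, match="clamped"):
            assert dose_response.or_at(4, 9) == dose_response.or_at(4, 5)

    def test_under_three_rejected(self, dose_response):
        with pytest.raises(ValueError, match="under 3"):
            dose_response.or_at(2, 1)

    def test_draws_flag_returns_interval(self, meta_results):
        point, (lo, hi) = meta_results.dose_response().or_at(4, 3, draws=True)
        assert lo <= point <= hi


class TestPrevalenceLogit:
    def test_published_point_estimates_arithmetic(self, published_posterior):
        val = prevalence_logit(published_posterior, age=3, dose=1, canada=True)
        assert val == pytest.approx(1.71 + 0.12 + 3 * (-0.23) + 0.05, abs=1e-9)
        assert val == pytest.approx(1.19, abs=1e-9)

    def test_age_or_is_079(self, published_posterior):
        assert np.exp(published_posterior.mean("beta_age")) == pytest.approx(0.79, abs=0.005)

    def test_zero_coefficients_give_logit_zero(self):
        post = ax.MetaPosterior.from_point_estimates(0, 0, 0, 0, 0)
        assert prevalence_logit(post, age=10, dose=3) == 0.0

    def test_affine_in_age_and_dose(self, published_posterior):
        f = lambda a, d: prevalence_logit(published_posterior, a, d)
        # zero second differences: proportional on the logit scale
        assert f(5, 2) - 2 * f(4, 2) + f(3, 2) == pytest.approx(0, abs=1e-12)
        assert f(4, 3) - 2 * f(4, 2) + f(4, 1) == pytest.approx(0, abs=1e-12)
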
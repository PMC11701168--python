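# abxasthma

Counterfactual impact analysis of infant antibiotic exposure on the burden
of pediatric asthma.

Antibiotic use in the first year of life disrupts gut-microbiome maturation
and is associated with an elevated risk of childhood asthma. Many
jurisdictions have seen infant prescribing fall sharply after antimicrobial
stewardship programs were introduced, which raises the policy question this
package addresses: *how much asthma burden did the decline in infant
antibiotic prescribing avert?* The answer is obtained by simulating the
pediatric population under the observed exposure trend and under
counterfactual trends (no decline; half the decline) and differencing the
asthma outcomes.

The package is aimed at epidemiologists and health-policy modelers. It
chains four stages, each usable on its own:

1. **Exposure trend** (`trends`) — negative-binomial regression of annual
   infant antibiotic prescription counts with a `log(births)` offset,

   `log E[count] = log(births) + b0 + b_t (year − 2001) + b_s male
   + b_p 1{year ≥ 2006} + b_tp (year − 2005) 1{year ≥ 2006}`,

   a piecewise log-linear trend with a breakpoint at the 2005 stewardship
   rollout. The smoothed fit defines the **base** scenario; **flat** holds
   the 2001 smoothed rate for all years; **mid** is the pointwise average.
2. **Dose-response meta-regression** (`meta`) — Bayesian random-effects
   pooling of published study effects, logit-linear in age at diagnosis and
   the number of first-year prescription courses (dose 0–5+):

   `logit(asthma | age, dose) = β0 + β_Canada + β_age·age + β_dose·dose`,

   with per-study random intercepts `u_i ~ N(0, σ_u²)`; `β_Canada` is the
   realized random intercept of the single Canadian study. The dose odds
   ratio is applied only through age 7, beyond which the association is
   treated as fully attenuated.
3. **Asthma microsimulation** (`microsim`) — an open-population
   discrete-time model: annual birth cohorts by sex, first-year dose
   assignment from the scenario curve, and annual asthma onset, remission
   and exacerbation dynamics from ages 3–18 driven by age/sex calibration
   tables, with the dose odds ratio multiplying onset odds at ages 3–7.
   Scenarios share all random streams (common random numbers), so paired
   runs difference out most Monte Carlo noise.
4. **Reporting** (`report`) — scenario differences, relative changes,
   age-group shares of the excess burden, and a direct-medical-cost
   translation of excess person-years with asthma.

A synthetic-data module (`synthetic`) generates every pipeline input with
known ground truth, so the whole chain is testable without access to
administrative health data.

## Worked example

```python
import abxasthma as ax

# 1. exposure trend: synthetic annual prescription data, NB regression
data = ax.gen_prescription_data(ax.TrendTruth(), range(2001, 2019), seed=1)
fit = ax.PrescriptionTrendModel(data).fit()
print(f"mean rate: {ax.mean_rate(data)} per 1,000 infants")
print(f"deviance explained: {fit.deviance_explained():.1f}%")
curves = fit.build_scenarios(range(2001, 2019))

# 2. dose-response meta-regression on synthetic study effects
studies = ax.gen_meta_studies(ax.MetaTruth(), seed=1)
meta = ax.DoseResponseMeta(studies).fit(seed=1)
dr = meta.dose_response()
print(f"OR per prescription at age 3: {dr.or_at(3, 1):.3f}; at age 8: {dr.or_at(8, 1):.1f}")

# 3. microsimulation: base vs flat exposure, paired runs
cfg = ax.SimConfig(population_scale=0.05, n_runs=20, base_seed=1)
calib = ax.gen_calibration()
base = ax.AsthmaMicrosim(cfg, curves["base"], calib, dr).run()
flat = ax.AsthmaMicrosim(cfg, curves["flat"], calib, dr).run()

# 4. excess burden of the counterfactual
cmp = ax.compare(base, flat)
print(cmp[cmp.age_group == "overall"][["outcome", "diff_mean", "diff_sd"]].round(1))
```

prints

```
mean rate: 519 per 1,000 infants
deviance explained: 99.2%
OR per prescription at age 3: 1.058; at age 8: 1.0
           outcome  diff_mean  diff_sd
12    person_years      320.9     36.7
13  incident_cases       74.2      9.6
14   exacerbations      137.8     24.7
```

The trend model explains 99.2% of the deviance in the synthetic counts and
the pooled dose effect (posterior mean β_dose ≈ 0.056, OR ≈ 1.06 per
prescription course) is recovered close to the generating value of 0.05.
Had the prescription rate stayed at its 2001 level, this desk-scale
population (5% of full cohort sizes, 20 paired runs) would have accumulated
about 321 additional person-years with asthma, 74 additional incident cases
and 138 additional exacerbations — the flat scenario is worse in every run
because paired common random numbers make the comparison agent-by-agent.

The same pipeline is available from the shell via the `abxasthma` CLI
(`synth`, `fit-trend`, `fit-meta`, `simulate`, `report` subcommands).

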
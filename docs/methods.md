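# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the known limitations of the package.

## Exposure trend model

Annual infant antibiotic prescription counts by calendar year and sex are
modeled as NB2 negative binomial with a `log(births)` offset:

```
log E[count] = log(births) + b0 + b_t (year − 2001) + b_s male
             + b_p 1{year ≥ 2006} + b_tp (year − 2005) 1{year ≥ 2006}
```

* Calendar time is centered at 2001, so `b0` is the female log-rate in the
  first study year. "After 2005" is implemented as `year ≥ 2006` (strict
  inequality on the breakpoint year); the boundary is configurable via
  `break_year`.
* Counts are modeled with an offset rather than modeling the rate directly;
  the two are equivalent in expectation and the offset form is standard for
  rate regression.
* Estimation is maximum likelihood (statsmodels discrete NB2) started from
  the Poisson GLM solution. When the ML dispersion collapses to the Poisson
  boundary — noise-free or nearly noise-free data — the Poisson GLM
  coefficients are reported with the dispersion at the boundary value
  (1e-8). Coefficient recovery on noise-free data is exact to ~1e-15.
* No sex × time interaction by default (`sex_time_interaction=True`
  enables one).
* **Deviance explained** is `100 × (1 − residual/null deviance)` with the
  null model intercept + offset only, both deviances evaluated at the
  fitted dispersion. A null deviance of (numerically) zero raises instead
  of returning an indeterminate ratio.
* Smoothed scenario curves: `base` is the fitted rate per 1,000 with
  delta-method 95% CIs (normal interval on the linear predictor,
  exponentiated); `flat` repeats the smoothed 2001 value per sex; `mid` is
  the pointwise mean of the two. Rates are reported rounded half-up when a
  single integer per 1,000 is requested.

## Dose-response meta-regression

Study-level log odds ratios of asthma versus dose 0 (hazard ratios are
treated interchangeably with odds ratios, acceptable at low prevalence) are
pooled with the logit-linear model

```
y_ij ~ Normal(mu_ij, se_ij²)
mu_ij = β0 + β_age · age_i + β_dose · dose_ij + u_i,   u_i ~ N(0, σ_u²)
```

where `age_i` is the midpoint of the study's age-at-diagnosis range (ranges
of 6+ years are excluded at harmonization) and dose ranges are recoded by
their lower bound (1–2 → 1, 3–4 → 3, 5+ → 5). `β_Canada` is reported as the
posterior of the realized random intercept of the single Canada-flagged
study, so the pooled equation can lean on the Canadian evidence.

* Priors: Normal(0, 10) on fixed effects, half-Normal(0, 5) on σ_u;
  configurable through `PriorSpec` / a YAML file.
* Age enters uncentered, in years; β0 is therefore interpretable only
  relative to this parameterization.
* **Posterior computation.** The model is linear-Gaussian given σ_u, so the
  default sampler integrates (β, u) out analytically (Gaussian evidence
  identity), samples the one-dimensional σ_u marginal exactly by inverse
  CDF on an adaptive grid (extended until the density falls 25 log units
  below its peak; 512 points; within-cell jitter), and then draws (β, u)
  from their exact joint Gaussian conditional per σ_u draw, using batched
  Cholesky factorizations. The draws are independent, so convergence is a
  non-issue; split-R̂ and bulk ESS are still computed (over four
  pseudo-chains) and gate the result at R̂ ≤ 1.01, the same gate applied to
  the alternative `method="emcee"` ensemble-MCMC path (differential-
  evolution moves on the random-effect-marginalized posterior, intercept
  sampled in age-centered coordinates). The two paths agree to a few 1e-3
  on posterior means; the fixed effects also match R/metafor REML estimates
  on the same table (cross-checked in the tests).
* **Dose-response function.** The point odds ratio is
  `exp(mean(β_dose) · dose)` — the plug-in at the posterior mean, which is
  what a reported "OR per course" corresponds to; `draws=True` returns the
  per-draw OR distribution and its central 95% interval. The OR is exactly
  1 at dose 0 and at all ages above `max_effect_age` (default 7): the age
  attenuation of the association is conservatively treated as complete
  there, implemented as a hard switch. Doses above 5 are clamped to 5 with
  a warning; ages below 3 are rejected because asthma is not modeled under
  age 3.
* `prevalence_logit` evaluates the literal logit-linear predictor
  (including `β_Canada` when requested). It is exposed alongside `or_at`
  because the pooled equation can be read either as a prevalence logit or
  as a log-OR model with study baselines absorbed into the random
  intercepts; the simulator consumes only the odds-ratio form.
* An age × dose interaction (which would let the dose effect decay
  smoothly with age rather than switch off at 7) is intentionally not
  modeled; the hard cutoff stands in for it.

## Microsimulation

An open population is followed in annual steps over 2001–2018. Each year
adds a newborn cohort per sex (default 43,000, roughly the annual birth
cohort implied by 773,160 births over 18 years; scaled by
`population_scale` for desk runs). Agents age out past 18. The standing
population at the start year (ages 1–18) is built by simulating each
pre-2001 birth cohort forward from birth under the same calibration, with
first-year doses drawn from the start-year exposure rate; tallies
accumulate only inside the study window.

Per year and agent, in fixed order: (1) infants are assigned a dose by
inverting a uniform draw through the count-distribution quantile function
(truncated Poisson by default with mean `rate/1000`; a negative-binomial
option takes its dispersion from the trend fit); (2) asthma-free agents
aged ≥ 3 face onset with probability `odds⁻¹(OR(age, dose) × odds(p_inc))`;
(3) agents who entered the year with asthma face remission (remission
before exacerbation, fixed order); (4) every agent with asthma after these
transitions contributes one person-year and a Poisson number of
exacerbations at the calibrated rate. Incident cases count only first-ever
onsets; age-group attribution uses the age attained in the event year
(groups 3–4, 5–9, 10–14, 15–18).

* Applying the *prevalence* odds ratio from the meta-regression to annual
  *onset* odds is the module's central approximation: the original policy
  model links the two through a registry recalibration that cannot be
  reproduced without its data. With the OR active only at ages 3–7 and
  near 1, the induced prevalence ratio is close to the onset ratio.
* Death and migration are omitted (pediatric mortality is negligible at
  this scale; no migration parameters are modeled).
* **Common random numbers.** Every decision consumes a uniform stream
  keyed by (base seed + run, calendar year, decision kind) and indexed by a
  deterministic global agent id, so the same agent sees the same uniforms
  under every scenario. Quantile inversion makes doses comonotone across
  scenarios; with the default calibration (remission zero before age 12,
  dose effect confined to ages ≤ 7) the flat-versus-base comparison is
  ordered agent-by-agent, not just in expectation — paired runs difference
  out most Monte Carlo noise and the per-run ordering is asserted in the
  tests.
* Replicate *k* uses seed `base_seed + k`; `n_runs=1` warns and reports an
  MC SD of 0. Outcome tables keep per-run tallies, so the overall row
  equals the sum of age-group rows exactly, run by run.

## Synthetic-data generators

A single global seed fans out to per-generator substreams
(`SeedSequence([seed, label_offset])`), so stages regenerate independently.

* **Prescription counts**: piecewise log-linear trend, continuous at the
  2005 breakpoint, NB size-parameter noise (`dispersion=inf` is the Poisson
  limit; `noise="none"` returns exact expectations for recovery tests).
  Defaults — intercept log(0.715), pre/post slopes −0.02/−0.09 per year,
  male offset +0.25, 43,000 births per sex-year — were chosen so the
  generated series matches the documented study conditions: a period mean
  near 523 prescriptions per 1,000 infants, a smoothed decline near 71%,
  and a male/female rate ratio near 586/457. The default dispersion (size
  400, ≈5% extra-Poisson noise per cell) keeps the trend fit realistic
  rather than saturated.
* **Study effects**: each of 6 studies (one Canada-flagged, age midpoints
  spread over 3–7 years) contributes one log-OR row per dose category 1–5,
  drawn from the full logit-linear predictor plus its study random effect
  and Normal(0, SE) noise. The Canada study's random effect is pinned at a
  known value so country-term recovery is testable.
* **Calibration tables**: incidence is an asymmetric Gaussian bump in age
  (peak 0.028/yr at age 4, floor 0.002, rise/fall widths 1.5/4.5 years,
  male factor 1.2); remission is zero before age 12 and ramps to 0.14/yr;
  exacerbation rates per person-year with asthma are 1.2 / 0.30 / 0.08 /
  0.05 for ages 3–4 / 5–9 / 10–14 / 15–18 (the ratios implied by the
  published burden table). These defaults make cohort prevalence rise
  through childhood, peak near age 12 and decline in adolescence
  (prevalence at 14 below prevalence at 8), verified by direct simulation.
  Shapes that push any probability outside [0, 1] raise rather than clamp.

What the generators deliberately do **not** emulate: record-level
prescription data (only annual aggregates), individual-level confounders
(the meta-analysis consumes adjusted effect sizes), registry-calibrated
absolute incidence/prevalence levels, and immigration/emigration/mortality.
Passing tests therefore demonstrate that the pipeline recovers known
parameters and orders scenarios correctly under its stated assumptions —
not that its absolute burden projections match any particular registry.

## Problem sizes and reproducibility

Simulation-backed tests and the acceptance script run at
`population_scale=0.05` (2,150 births per sex-year) with 20 paired
replicates, the package's desk-scale configuration; expected tallies scale
linearly in the population scale (tested at 0.05 vs 0.1). Coverage checks
use 100 seeded replicates of the generate-then-fit loop. All randomness
descends from explicit integer seeds; identical seeds give byte-identical
generator output, identical posterior summaries and identical simulation
tallies.

## Known limitations

* The odds-on-onset approximation above; absolute simulated burden is
  therefore calibration-dependent and not comparable to registry totals.
* The dose effect's age attenuation is a hard cutoff at 7, not a smooth
  interaction.
* The within-study likelihood is Normal on the log-OR scale with known SE —
  the classical approximation; rare-event corrections are not applied.
* Published summary tables shipped with the package are rounded to the
  integers they were printed with; derived differences can shift by ±1
  relative to differences of unrounded run averages, and the table renderer
  allows exactly that slack for summary-only inputs.
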
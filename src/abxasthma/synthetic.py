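"""Synthetic input generators with known ground truth.

Every downstream stage of the pipeline (trend regression, dose-response
meta-regression, microsimulation) consumes tables that, for the original
analysis, came from administrative health data, a literature review, and a
calibrated policy model.  None of those sources ship with this package, so
this module generates statistically faithful stand-ins with fully known
parameters:

* annual infant antibiotic prescription counts following a piecewise
  log-linear trend with a breakpoint (a stewardship-program-style decline)
  and negative-binomial count noise;
* study-level dose-response effect tables consistent with the logit-linear
  meta-regression model, including study random effects;
* age-shaped baseline asthma calibration tables (incidence rising in early
  childhood and declining afterwards, remission appearing in adolescence).

A single global integer seed fans out to independent per-generator
substreams via :func:`substream` (SeedSequence spawning keyed by a stable
label), so each stage can be regenerated on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrendTruth",
    "MetaTruth",
    "CalibrationShape",
    "CalibrationTables",
    "substream",
    "gen_prescription_data",
    "gen_meta_studies",
    "gen_calibration",
    "default_truths",
]

#: label -> fixed offset used when splitting the global seed into substreams
_STREAM_LABELS = {"prescriptions": 0, "meta": 1, "calibration": 2, "microsim": 3}


def substream(seed: int, label: str) -> np.random.Generator:
    """Derive the RNG substream for one generator from the global seed.

    The splitting rule is ``SeedSequence([seed, offset(label)])`` with a
    fixed documented offset per label, so regenerating one stage never
    perturbs another.
    """
    if label not in _STREAM_LABELS:
        raise ValueError(f"unknown substream label {label!r}; known: {sorted(_STREAM_LABELS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_LABELS[label]]))


# ---------------------------------------------------------------------------
# Prescription-trend truth and generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendTruth:
    """Ground-truth parameters of the piecewise log-linear prescription trend.

    The log rate (prescriptions per infant) at calendar year ``y`` for sex
    ``s`` is::

        lp(y, s) = intercept_log_rate
                   + slope_pre * (y - y0)
                   + (slope_post - slope_pre) * max(0, y - break_year)
                   + sex_effect * 1{s == male}

    where ``y0`` is the first simulated year, so the trend is continuous at
    the breakpoint.  Counts are negative-binomial with mean
    ``births * exp(lp)`` and size parameter ``dispersion`` (variance
    ``mu + mu^2 / dispersion``; ``dispersion = inf`` is the Poisson limit).
    """

    intercept_log_rate: float = float(np.log(0.715))
    slope_pre: float = -0.02
    slope_post: float = -0.09
    break_year: int = 2005
    sex_effect: float = 0.25  # male vs female, additive on the log-rate scale
    dispersion: float = 400.0
    births_per_year: Mapping[int, int] | None = None  # year -> births per sex
    default_births: int = 43_000  # per sex per year when births_per_year is None

    def __post_init__(self) -> None:
        if not (self.dispersion > 0):
            raise ValueError("dispersion must be > 0")
        if self.births_per_year is not None and any(b < 0 for b in self.births_per_year.values()):
            raise ValueError("births_per_year values must be >= 0")

    def births(self, year: int) -> int:
        if self.births_per_year is not None:
            return int(self.births_per_year[year])
        return self.default_births

    def log_rate(self, year: int | np.ndarray, male: bool, y0: int) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        lp = (
            self.intercept_log_rate
            + self.slope_pre * (year - y0)
            + (self.slope_post - self.slope_pre) * np.maximum(0.0, year - self.break_year)
        )
        if male:
            lp = lp + self.sex_effect
        return lp


def gen_prescription_data(
    truth: TrendTruth,
    years: Sequence[int],
    seed: int,
    noise: str = "nb",
) -> pd.DataFrame:
    """Sample an annual prescription-rate table (one row per year and sex).

    Parameters
    ----------
    truth
        Generating parameters; ``truth.break_year`` must lie inside `years`.
    years
        Calendar years to simulate (the first year anchors the intercept).
    seed
        Global seed; the ``"prescriptions"`` substream is used.
    noise
        ``"nb"`` (negative-binomial counts, Poisson when
        ``dispersion == inf``) or ``"none"`` (counts equal their exact
        expectation, useful for noise-free recovery checks).

    Returns
    -------
    DataFrame with columns ``year, sex, births, prescriptions,
    rate_per_1000``, sorted by year then sex.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    if not (min(years) <= truth.break_year <= max(years)):
        raise ValueError(
            f"break_year {truth.break_year} outside simulated span {min(years)}-{max(years)}"
        )
    if noise not in ("nb", "none"):
        raise ValueError(f"unknown noise mode {noise!r}")
    rng = substream(seed, "prescriptions")
    y0 = min(years)
    rows = []
    for year in sorted(years):
        births = truth.births(year)
        for sex, male in (("female", False), ("male", True)):
            mu = births * float(np.exp(truth.log_rate(year, male, y0)))
            if noise == "none":
                count = mu
            elif np.isinf(truth.dispersion):
                count = int(rng.poisson(mu))
            else:
                r = truth.dispersion
                count = int(rng.negative_binomial(r, r / (r + mu)))
            rows.append(
                {
                    "year": year,
                    "sex": sex,
                    "births": births,
                    "prescriptions": count,
                    "rate_per_1000": count / births * 1000.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Meta-analysis truth and generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaTruth:
    """Ground truth for the dose-response meta-regression generator.

    The noise-free log odds ratio reported by study *i* at age ``a`` and
    dose ``d`` is the logit-linear predictor
    ``beta0 + beta_age * a + beta_dose * d + u_i`` with study random effect
    ``u_i ~ Normal(0, sigma_u^2)``; the single Canada-flagged study's random
    effect is pinned at ``canada_effect`` so recovery tests have a known
    target for the country term.
    """

    beta0: float = 0.0
    beta_age: float = 0.0
    beta_dose: float = 0.05
    sigma_u: float = 0.1
    canada_effect: float = 0.12
    n_studies: int = 6
    se_range: tuple[float, float] = (0.02, 0.08)
    doses: tuple[int, ...] = (1, 2, 3, 4, 5)
    age_range: tuple[float, float] = (3.0, 7.0)

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.n_studies < 2:
            raise ValueError("n_studies must be >= 2")
        if not (self.se_range[0] > 0):
            raise ValueError("se_range low must be > 0")


def gen_meta_studies(truth: MetaTruth, seed: int) -> pd.DataFrame:
    """Sample a harmonized study effect table.

    Each study contributes one row per dose category in ``truth.doses``
    (log-OR versus dose 0), with Normal measurement noise at a
    per-study standard error drawn uniformly from ``truth.se_range``.
    Exactly the first study is Canada-flagged.  Age at diagnosis midpoints
    are spread evenly over ``truth.age_range``.

    Returns a DataFrame matching the harmonized study-table schema
    (``study_id, country, canada_flag, age_low, age_high, age_mid, dose_raw,
    dose, effect_scale, log_effect, se, risk_of_bias, age_range_width``).
    """
    rng = substream(seed, "meta")
    ages = np.linspace(truth.age_range[0], truth.age_range[1], truth.n_studies)
    u = rng.normal(0.0, truth.sigma_u, size=truth.n_studies)
    u[0] = truth.canada_effect
    countries = ["Canada"] + [f"Country{i}" for i in range(1, truth.n_studies)]
    rows = []
    for i in range(truth.n_studies):
        se_i = float(rng.uniform(*truth.se_range))
        for d in truth.doses:
            mu = truth.beta0 + truth.beta_age * ages[i] + truth.beta_dose * d + u[i]
            rows.append(
                {
                    "study_id": f"S{i:02d}",
                    "country": countries[i],
                    "canada_flag": i == 0,
                    "age_low": ages[i] - 1.0,
                    "age_high": ages[i] + 1.0,
                    "age_mid": ages[i],
                    "dose_raw": "5+" if d >= 5 else str(d),
                    "dose": min(d, 5),
                    "effect_scale": "OR",
                    "log_effect": mu + rng.normal(0.0, se_i),
                    "se": se_i,
                    "risk_of_bias": 1,
                    "age_range_width": 2.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Baseline asthma calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationShape:
    """Shape parameters of the baseline asthma calibration tables.

    Incidence follows an asymmetric Gaussian bump in age: it rises to
    ``incidence_peak`` at ``incidence_peak_age`` (which must be < 10) over a
    rise width of ``rise_width`` years and decays over ``fall_width`` years
    towards ``incidence_floor``.  Remission is zero before
    ``remission_start_age`` and ramps linearly to ``remission_max`` over
    three years.  Exacerbation rates per person-year with asthma are
    piecewise-constant over the reporting age groups.
    """

    incidence_peak: float = 0.028
    incidence_peak_age: float = 4.0
    rise_width: float = 1.5
    fall_width: float = 4.5
    incidence_floor: float = 0.002
    male_incidence_factor: float = 1.2
    remission_start_age: int = 12
    remission_max: float = 0.14
    exacerbation_rates: Mapping[str, float] = field(
        default_factory=lambda: {"3-4": 1.2, "5-9": 0.30, "10-14": 0.08, "15-18": 0.05}
    )

    def __post_init__(self) -> None:
        if not (self.incidence_peak_age < 10):
            raise ValueError("incidence must peak before age 10")
        if self.incidence_peak <= self.incidence_floor:
            raise ValueError("incidence_peak must exceed incidence_floor")


@dataclass(frozen=True)
class CalibrationTables:
    """Baseline asthma rates by single year of age and sex.

    ``incidence`` and ``remission`` are annual probabilities; the
    exacerbation entry is an expected count per person-year with asthma.
    Entries cover every simulated age 3-18 for both sexes.
    """

    incidence: Mapping[tuple[int, str], float]
    remission: Mapping[tuple[int, str], float]
    exacerbation_rate: Mapping[tuple[int, str], float]
    ages: tuple[int, ...] = tuple(range(3, 19))

    def __post_init__(self) -> None:
        for name, table in (("incidence", self.incidence), ("remission", self.remission)):
            for key, p in table.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{key}] = {p} outside [0, 1]")
        for key, r in self.exacerbation_rate.items():
            if r < 0:
                raise ValueError(f"exacerbation_rate[{key}] = {r} negative")
        for age in self.ages:
            for sex in ("female", "male"):
                for name, table in (
                    ("incidence", self.incidence),
                    ("remission", self.remission),
                    ("exacerbation_rate", self.exacerbation_rate),
                ):
                    if (age, sex) not in table:
                        raise ValueError(f"missing {name} entry for (age={age}, sex={sex!r})")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "age": age,
                "sex": sex,
                "incidence": self.incidence[(age, sex)],
                "remission": self.remission[(age, sex)],
                "exacerbation_rate": self.exacerbation_rate[(age, sex)],
            }
            for age in self.ages
            for sex in ("female", "male")
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationTables":
        inc, rem, exa = {}, {}, {}
        for row in df.itertuples(index=False):
            key = (int(row.age), str(row.sex))
            inc[key] = float(row.incidence)
            rem[key] = float(row.remission)
            exa[key] = float(row.exacerbation_rate)
        ages = tuple(sorted({k[0] for k in inc}))
        return cls(incidence=inc, remission=rem, exacerbation_rate=exa, ages=ages)


def _age_group(age: int) -> str:
    if 3 <= age <= 4:
        return "3-4"
    if 5 <= age <= 9:
        return "5-9"
    if 10 <= age <= 14:
        return "10-14"
    if 15 <= age <= 18:
        return "15-18"
    raise ValueError(f"age {age} outside modeled range 3-18")


def gen_calibration(shape: CalibrationShape | None = None) -> CalibrationTables:
    """Build baseline calibration tables from a unimodal age-incidence shape.

    Raises ``ValueError`` (never clamps) if the shape parameters push any
    probability outside [0, 1].
    """
    shape = shape or CalibrationShape()
    inc, rem, exa = {}, {}, {}
    for age in range(3, 19):
        w = shape.rise_width if age < shape.incidence_peak_age else shape.fall_width
        base = shape.incidence_floor + (shape.incidence_peak - shape.incidence_floor) * float(
            np.exp(-(((age - shape.incidence_peak_age) / w) ** 2))
        )
        if age < shape.remission_start_age:
            r = 0.0
        else:
            r = shape.remission_max * min(1.0, (age - shape.remission_start_age + 1) / 3.0)
        for sex in ("female", "male"):
            p = base * (shape.male_incidence_factor if sex == "male" else 1.0)
            if not (0.0 <= p <= 1.0) or not (0.0 <= r <= 1.0):
                raise ValueError(
                    f"calibration shape yields probability outside [0, 1] at age {age} ({sex})"
                )
            inc[(age, sex)] = p
            rem[(age, sex)] = r
            exa[(age, sex)] = float(shape.exacerbation_rates[_age_group(age)])
    return CalibrationTables(incidence=inc, remission=rem, exacerbation_rate=exa)


def default_truths() -> dict:
    """Default ground-truth parameter set for an end-to-end synthetic run."""
    return {
        "trend": TrendTruth(),
        "meta": MetaTruth(),
        "calibration": CalibrationShape(),
    }


def dump_truth_yaml(path: str, trend: TrendTruth, meta: MetaTruth, shape: CalibrationShape) -> None:
    """Write the ground-truth parameters to YAML for recovery tests."""

    def plain(v):
        if isinstance(v, Mapping):
            return {plain(k): plain(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [plain(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    def as_dict(obj):
        return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}

    with open(path, "w") as fh:
        yaml.safe_dump(
            {"trend": as_dict(trend), "meta": as_dict(meta), "calibration": as_dict(shape)},
            fh,
            sort_keys=False,
        )
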
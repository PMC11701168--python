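"""Open-population discrete-time microsimulation of pediatric asthma.

A virtual population is followed year by year over the study window
(default 2001-2018).  Agents enter by birth (an annual newborn cohort per
sex) and leave when they age past 18.  In their first year of life each
agent is assigned a number of antibiotic prescription courses (dose, capped
at 5 for "5+") drawn from the scenario's population rate.  From age 3 —
asthma is not modeled under 3 years of age — agents face annual asthma
onset, remission and exacerbation dynamics driven by age- and sex-specific
calibration tables; the dose-response odds ratio from the meta-regression
multiplies the onset odds through age 7, beyond which the association is
treated as fully attenuated.

The standing population at the start year (ages 1-18) is built by
simulating each pre-start birth cohort forward from birth under the same
calibration, with doses drawn from the start-year exposure rate; outcome
tallies only accumulate inside the study window.

Common random numbers: every stochastic decision consumes a uniform stream
indexed by (run, calendar year, decision kind) and positioned by a
deterministic global agent id, so the *same* agent sees the *same* uniforms
under every scenario.  Doses are inverted from the uniform through the
count-distribution quantile function, making per-agent doses comonotone
across scenarios: pointwise-ordered exposure curves yield per-agent ordered
doses, onsets, person-years and exacerbations by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import DoseResponse
from .synthetic import CalibrationTables
from .trends import ScenarioCurve

__all__ = [
    "SimConfig",
    "OutcomeTable",
    "AsthmaMicrosim",
    "assign_dose",
    "onset_probability",
    "AGE_GROUPS",
]

AGE_GROUPS = ("3-4", "5-9", "10-14", "15-18")
OUTCOMES = ("person_years", "incident_cases", "exacerbations")

_GROUP_OF_AGE = {}
for _a in range(3, 19):
    _GROUP_OF_AGE[_a] = ("3-4" if _a <= 4 else "5-9" if _a <= 9 else "10-14" if _a <= 14 else "15-18")

# decision-kind codes for the uniform substreams
_KIND = {"dose": 0, "onset": 1, "remission": 2, "exacerbation": 3}


@dataclass(frozen=True)
class SimConfig:
    """Microsimulation configuration.

    ``population_scale`` shrinks every birth cohort for desk-scale runs
    (expected tallies scale linearly).  ``dose_distribution`` is "poisson"
    or "nb"; the negative-binomial option takes its dispersion (NB2 alpha)
    from ``dose_dispersion``.
    """

    start_year: int = 2001
    end_year: int = 2018
    births_per_year: int = 43_000  # per sex
    population_scale: float = 1.0
    n_runs: int = 100
    base_seed: int = 0
    min_asthma_age: int = 3
    max_age: int = 18
    dose_effect_max_age: int = 7
    dose_distribution: str = "poisson"
    dose_dispersion: float = 1.0  # NB2 alpha, used when dose_distribution == "nb"

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")
        if not (0 < self.population_scale <= 1):
            raise ValueError("population_scale must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.min_asthma_age < 3:
            raise ValueError("asthma is not modeled under 3 years of age")
        if self.dose_distribution not in ("poisson", "nb"):
            raise ValueError("dose_distribution must be 'poisson' or 'nb'")

    @property
    def cohort_size(self) -> int:
        return max(1, round(self.births_per_year * self.population_scale))


class OutcomeTable:
    """Per-run outcome tallies by age group, with MC means and SDs.

    `runs` is an array of shape (n_runs, n_age_groups, n_outcomes); the
    overall row is derived as the sum over age groups within each run, so
    the per-run conservation identity holds exactly.  Summary-only tables
    (e.g. published results) carry `runs=None` plus explicit means and SDs.
    """

    def __init__(
        self,
        scenario: str,
        runs: np.ndarray | None = None,
        summary: pd.DataFrame | None = None,
        n_runs: int | None = None,
    ):
        self.scenario = scenario
        self.runs = runs
        if runs is not None:
            self.n_runs = runs.shape[0]
            if self.n_runs == 1:
                warnings.warn("single replicate: MC SD is reported as 0", stacklevel=2)
            self._summary = self._summarize(runs)
        else:
            if summary is None:
                raise ValueError("need either per-run tallies or a summary table")
            self.n_runs = n_runs or 0
            self._summary = summary

    def _summarize(self, runs: np.ndarray) -> pd.DataFrame:
        rows = []
        groups = list(AGE_GROUPS) + ["overall"]
        totals = runs.sum(axis=1)  # (n_runs, n_outcomes)
        for gi, group in enumerate(groups):
            per_run = totals if group == "overall" else runs[:, gi, :]
            for oi, outcome in enumerate(OUTCOMES):
                vals = per_run[:, oi]
                rows.append(
                    {
                        "scenario": self.scenario,
                        "age_group": group,
                        "outcome": outcome,
                        "mean": float(vals.mean()),
                        "mc_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return self._summary.copy()

    def value(self, age_group: str, outcome: str, stat: str = "mean") -> float:
        s = self._summary
        sel = s[(s["age_group"] == age_group) & (s["outcome"] == outcome)]
        if sel.empty:
            raise KeyError(f"no cell ({age_group!r}, {outcome!r}) in scenario {self.scenario!r}")
        return float(sel[stat].iloc[0])

    def per_run(self, age_group: str, outcome: str) -> np.ndarray:
        if self.runs is None:
            raise ValueError("summary-only table has no per-run tallies")
        oi = OUTCOMES.index(outcome)
        if age_group == "overall":
            return self.runs[:, :, oi].sum(axis=1)
        return self.runs[:, AGE_GROUPS.index(age_group), oi]

    @classmethod
    def from_summary(cls, scenario: str, summary: pd.DataFrame, n_runs: int = 0) -> "OutcomeTable":
        return cls(scenario, summary=summary.reset_index(drop=True), n_runs=n_runs)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def assign_dose(
    rate_per_1000: float,
    rng: np.random.Generator,
    size: int = 1,
    distribution: str = "poisson",
    dispersion: float = 1.0,
    cap: int = 5,
) -> np.ndarray:
    """Draw first-year antibiotic course counts from a population rate.

    The count distribution has mean ``rate_per_1000 / 1000`` and is
    truncated (censored) at `cap` to represent the "5+" category.
    """
    if rate_per_1000 < 0:
        raise ValueError("rate must be >= 0")
    mu = rate_per_1000 / 1000.0
    u = rng.uniform(size=size)
    return _dose_from_uniform(u, mu, distribution, dispersion, cap)


def _dose_from_uniform(
    u: np.ndarray, mu: float, distribution: str, dispersion: float, cap: int = 5
) -> np.ndarray:
    """Quantile-invert uniforms into capped counts (comonotone in mu)."""
    if mu == 0:
        return np.zeros_like(u, dtype=np.int64)
    if distribution == "poisson":
        d = stats.poisson.ppf(u, mu)
    elif distribution == "nb":
        # NB2: var = mu + alpha mu^2 -> size r = 1/alpha, p = r/(r+mu)
        r = 1.0 / dispersion
        d = stats.nbinom.ppf(u, r, r / (r + mu))
    else:
        raise ValueError(f"unknown dose distribution {distribution!r}")
    return np.minimum(d, cap).astype(np.int64)


def onset_probability(base_p: float | np.ndarray, or_value: float | np.ndarray):
    """Multiply the annual onset odds by an odds ratio.

    adjusted = or * p / (1 - p + or * p); the identity at or = 1 and the
    boundaries p = 0, 1 are exact.
    """
    base_p = np.asarray(base_p, dtype=float)
    or_value = np.asarray(or_value, dtype=float)
    if np.any(base_p < 0) or np.any(base_p > 1):
        raise ValueError("base probability outside [0, 1]")
    if np.any(or_value <= 0):
        raise ValueError("odds ratio must be > 0")
    out = or_value * base_p / (1.0 - base_p + or_value * base_p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------


class AsthmaMicrosim:
    """Open-population asthma microsimulation under one exposure scenario.

    Parameters
    ----------
    config
        Simulation window, cohort sizes, replicate count and seeds.
    scenario
        Exposure curve supplying the annual prescription rate per 1,000
        infants by sex (must cover every simulated birth year in the window;
        pre-window cohorts use the start-year value).
    calibration
        Baseline incidence / remission / exacerbation tables by age and sex.
    dose_response
        Dose odds-ratio function from the meta-regression.
    """

    def __init__(
        self,
        config: SimConfig,
        scenario: ScenarioCurve,
        calibration: CalibrationTables,
        dose_response: DoseResponse,
    ):
        self.config = config
        self.scenario = scenario
        self.calibration = calibration
        self.dose_response = dose_response
        self._check_coverage()
        # odds-ratio lookup by (age, dose): 1 beyond the effect-age cutoff
        cfg = config
        self._or_table = np.ones((cfg.max_age + 1, 6))
        for age in range(cfg.min_asthma_age, cfg.max_age + 1):
            for dose in range(6):
                if age <= cfg.dose_effect_max_age:
                    self._or_table[age, dose] = dose_response.or_at(age, dose)
        # calibration lookups: [age, sex_index] with sex 0=female, 1=male
        self._inc = np.zeros((cfg.max_age + 1, 2))
        self._rem = np.zeros((cfg.max_age + 1, 2))
        self._exa = np.zeros((cfg.max_age + 1, 2))
        for age in range(cfg.min_asthma_age, cfg.max_age + 1):
            for si, sex in enumerate(("female", "male")):
                key = (age, sex)
                for name, target, table in (
                    ("incidence", self._inc, calibration.incidence),
                    ("remission", self._rem, calibration.remission),
                    ("exacerbation_rate", self._exa, calibration.exacerbation_rate),
                ):
                    if key not in table:
                        raise KeyError(f"missing calibration {name} cell for (age={age}, sex={sex!r})")
                    target[age, si] = table[key]
        self._layout = self._build_layout()

    def _check_coverage(self) -> None:
        cfg = self.config
        have = set(self.scenario.years)
        need = set(range(cfg.start_year, cfg.end_year + 1))
        if not need <= have:
            raise ValueError(f"scenario does not cover years {sorted(need - have)}")

    # -- population layout (identical across scenarios) ---------------------
    def _build_layout(self) -> pd.DataFrame:
        """Deterministic global agent ids per (birth_year, sex) cohort."""
        cfg = self.config
        first_birth = cfg.start_year - cfg.max_age  # standing population ages 1-18
        rows = []
        offset = 0
        for birth_year in range(first_birth, cfg.end_year + 1):
            for si in (0, 1):
                n = cfg.cohort_size
                rows.append(
                    {"birth_year": birth_year, "sex_index": si, "start": offset, "n": n}
                )
                offset += n
        return pd.DataFrame(rows)

    def _uniforms(self, run: int, year: int, kind: str, n_total: int) -> np.ndarray:
        """Uniform stream for one (run, year, decision kind), agent-indexed."""
        seq = np.random.SeedSequence(
            [int(self.config.base_seed) + int(run), int(year), _KIND[kind]]
        )
        return np.random.Generator(np.random.Philox(seq)).uniform(size=n_total)

    def _scenario_rate(self, year: int, sex: str) -> float:
        cfg = self.config
        y = min(max(year, cfg.start_year), cfg.end_year)
        return self.scenario.rate(y, sex)

    # -- core loop -----------------------------------------------------------
    def _run_once(self, run: int) -> np.ndarray:
        """One replicate; returns tallies of shape (len(AGE_GROUPS), len(OUTCOMES))."""
        cfg = self.config
        layout = self._layout
        n_total = int(layout["start"].iloc[-1] + layout["n"].iloc[-1])
        birth_year = np.empty(n_total, dtype=np.int32)
        sex_index = np.empty(n_total, dtype=np.int8)
        for row in layout.itertuples(index=False):
            sl = slice(row.start, row.start + row.n)
            birth_year[sl] = row.birth_year
            sex_index[sl] = row.sex_index
        dose = np.zeros(n_total, dtype=np.int8)
        has_asthma = np.zeros(n_total, dtype=bool)
        ever_asthma = np.zeros(n_total, dtype=bool)

        tallies = np.zeros((len(AGE_GROUPS), len(OUTCOMES)))
        group_index = np.full(cfg.max_age + 1, -1, dtype=np.int64)
        for age, g in _GROUP_OF_AGE.items():
            if age <= cfg.max_age:
                group_index[age] = AGE_GROUPS.index(g)

        first_year = int(layout["birth_year"].min())
        for year in range(first_year, cfg.end_year + 1):
            in_window = year >= cfg.start_year
            age = year - birth_year
            alive = (age >= 0) & (age <= cfg.max_age)

            # 1. dose assignment for this year's infants (age 0)
            newborn = alive & (age == 0)
            if newborn.any():
                u = self._uniforms(run, year, "dose", n_total)
                for si, sex in enumerate(("female", "male")):
                    mask = newborn & (sex_index == si)
                    if mask.any():
                        mu = self._scenario_rate(year, sex) / 1000.0
                        dose[mask] = _dose_from_uniform(
                            u[mask], mu, cfg.dose_distribution, cfg.dose_dispersion
                        )

            eligible = alive & (age >= cfg.min_asthma_age)
            if not eligible.any():
                continue
            a = age.clip(0, cfg.max_age)

            # 2. onset among the asthma-free, odds modulated by dose OR
            free = eligible & ~has_asthma
            if free.any():
                base_p = self._inc[a[free], sex_index[free]]
                or_val = self._or_table[a[free], dose[free]]
                p = onset_probability(base_p, or_val)
                u = self._uniforms(run, year, "onset", n_total)[free]
                onset = u < p
                idx = np.flatnonzero(free)[onset]
                has_asthma[idx] = True
                new_cases = idx[~ever_asthma[idx]]
                ever_asthma[new_cases] = True
                if in_window and new_cases.size:
                    np.add.at(
                        tallies[:, OUTCOMES.index("incident_cases")],
                        group_index[a[new_cases]],
                        1.0,
                    )
                newly = np.zeros(n_total, dtype=bool)
                newly[idx] = True
            else:
                newly = np.zeros(n_total, dtype=bool)

            # 3. remission among agents who entered the year with asthma
            standing = eligible & has_asthma & ~newly
            if standing.any():
                u = self._uniforms(run, year, "remission", n_total)[standing]
                remit = u < self._rem[a[standing], sex_index[standing]]
                has_asthma[np.flatnonzero(standing)[remit]] = False

            # 4. person-years and exacerbations for everyone with asthma now
            active = eligible & has_asthma
            if in_window and active.any():
                np.add.at(
                    tallies[:, OUTCOMES.index("person_years")], group_index[a[active]], 1.0
                )
                u = self._uniforms(run, year, "exacerbation", n_total)[active]
                counts = stats.poisson.ppf(u, self._exa[a[active], sex_index[active]])
                np.add.at(
                    tallies[:, OUTCOMES.index("exacerbations")],
                    group_index[a[active]],
                    counts,
                )
        return tallies

    def run(self, n_runs: int | None = None) -> OutcomeTable:
        """Execute the replicates and return the outcome table.

        Replicate *k* uses seed ``base_seed + k``, so paired scenarios run
        with the same config share all random streams (common random
        numbers).
        """
        n = n_runs or self.config.n_runs
        runs = np.stack([self._run_once(k) for k in range(n)])
        return OutcomeTable(self.scenario.scenario_id, runs=runs)
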
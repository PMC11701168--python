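"""Negative-binomial trend regression for infant antibiotic prescription rates.

The observed data are annual counts of antibiotic prescriptions dispensed to
infants (<1 year of age), with the number of live births as the population
denominator, by calendar year and sex.  Prescribing declined sharply after
the introduction of a provincial stewardship program in 2005, so the mean
model is piecewise log-linear in calendar time with a breakpoint::

    log E[prescriptions] = log(births) + b0 + b_t (year - 2001) + b_s male
                           + b_p 1{year >= 2006} + b_tp (year - 2005) 1{year >= 2006}

estimated by maximum likelihood under an NB2 negative-binomial count
distribution.  The fitted (smoothed) rates define the factual exposure
scenario; counterfactual scenarios hold the rate flat at its 2001 smoothed
value or halve the decline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PrescriptionTrendModel",
    "TrendResults",
    "ScenarioCurve",
    "build_scenarios",
    "mean_rate",
    "percent_reduction",
]

#: ML dispersion below this is treated as the Poisson boundary
_ALPHA_FLOOR = 1e-8


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def validate_rate_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check an annual rate table (year, sex, births, prescriptions)."""
    required = {"year", "sex", "births", "prescriptions"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    if (data["births"] <= 0).any():
        raise ValueError("births must be > 0 in every row")
    if (data["prescriptions"] < 0).any():
        raise ValueError("prescriptions must be >= 0")
    bad_sex = set(data["sex"]) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    if "rate_per_1000" in data.columns:
        expected = data["prescriptions"] / data["births"] * 1000.0
        if not np.allclose(data["rate_per_1000"], expected, atol=0.5):
            raise ValueError("rate_per_1000 inconsistent with prescriptions/births")
    return data


@dataclass(frozen=True)
class ScenarioCurve:
    """Smoothed annual prescription rates per 1,000 infants for one scenario.

    `values` has columns ``year, sex, rate_per_1000`` and, for the base
    scenario, delta-method 95% confidence bounds ``ci_low, ci_high``.
    """

    scenario_id: str  # "base", "flat" or "mid"
    values: pd.DataFrame

    def rate(self, year: int, sex: str) -> float:
        sel = self.values[(self.values["year"] == year) & (self.values["sex"] == sex)]
        if sel.empty:
            raise KeyError(f"scenario {self.scenario_id!r} has no value for ({year}, {sex!r})")
        return float(sel["rate_per_1000"].iloc[0])

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.values["year"].unique())


class PrescriptionTrendModel:
    """Negative-binomial regression of prescription counts on time and sex.

    Parameters
    ----------
    data
        Annual rate table with columns ``year, sex, births, prescriptions``.
    base_year
        Year at which calendar time is centered (the intercept is the
        log-rate for females in this year).
    break_year
        Last year of the pre-decline regime; the post indicator is
        ``year >= break_year + 1``.
    sex_time_interaction
        Include a male x time term (off by default; the published model used
        calendar time and sex as covariates without it).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        base_year: int = 2001,
        break_year: int = 2005,
        sex_time_interaction: bool = False,
    ):
        self.data = validate_rate_table(data.copy()).sort_values(["year", "sex"]).reset_index(drop=True)
        self.base_year = int(base_year)
        self.break_year = int(break_year)
        self.sex_time_interaction = sex_time_interaction
        years = self.data["year"].unique()
        if len(years) < 4:
            raise ValueError("need >= 4 distinct years to fit the breakpoint model")
        if set(self.data["sex"]) != {"female", "male"}:
            raise ValueError("both sexes must be present")
        self._has_break = years.min() <= break_year < years.max()
        if not self._has_break:
            logger.warning(
                "all years on one side of breakpoint %d; dropping breakpoint terms", break_year
            )

    # -- design ------------------------------------------------------------
    def _design(self, year: np.ndarray, male: np.ndarray) -> tuple[np.ndarray, list[str]]:
        year = np.asarray(year, dtype=float)
        male = np.asarray(male, dtype=float)
        t = year - self.base_year
        cols = [np.ones_like(t), t, male]
        names = ["const", "year_c", "male"]
        if self._has_break:
            post = (year >= self.break_year + 1).astype(float)
            cols += [post, (year - self.break_year) * post]
            names += ["post", "year_post"]
        if self.sex_time_interaction:
            cols.append(t * male)
            names.append("year_male")
        return np.column_stack(cols), names

    def exog(self) -> tuple[np.ndarray, list[str]]:
        male = (self.data["sex"] == "male").to_numpy()
        return self._design(self.data["year"].to_numpy(), male)

    # -- estimation --------------------------------------------------------
    def fit(self) -> "TrendResults":
        """Maximum-likelihood NB2 fit with a log(births) offset.

        Falls back to the Poisson GLM solution when the ML dispersion
        collapses to the Poisson boundary (e.g. noise-free data).
        """
        X, names = self.exog()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns by testing rank without each
            collinear = [
                names[j]
                for j in range(X.shape[1])
                if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
            ]
            raise ValueError(f"singular design; collinear columns: {collinear}")
        y = self.data["prescriptions"].to_numpy(dtype=float)
        offset = np.log(self.data["births"].to_numpy(dtype=float))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        alpha = np.nan
        params = pois.params
        cov = np.asarray(pois.cov_params())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                nb = sm.NegativeBinomial(y, X, offset=offset).fit(
                    start_params=np.append(pois.params, 0.05), disp=0, maxiter=200
                )
                alpha = float(nb.params[-1])
            except Exception:  # perfectly separated / boundary cases
                alpha = _ALPHA_FLOOR
        if np.isfinite(alpha) and alpha > _ALPHA_FLOOR:
            params = nb.params[:-1]
            cov = np.asarray(nb.cov_params())[:-1, :-1]
        else:
            alpha = _ALPHA_FLOOR  # Poisson boundary; keep GLM coefficients
        return TrendResults(self, pd.Series(params, index=names), alpha, cov)


class TrendResults:
    """Fitted prescription-trend model: coefficients, dispersion, smoothing.

    Attributes
    ----------
    params : pd.Series
        Coefficients on the log-rate scale (``const, year_c, male`` and,
        when the data span the breakpoint, ``post, year_post``).
    dispersion : float
        NB2 alpha (variance ``mu + alpha mu^2``); the Poisson boundary is
        reported as 1e-8.
    cov_params : ndarray
        Covariance of the coefficients.
    """

    def __init__(self, model: PrescriptionTrendModel, params: pd.Series, dispersion: float, cov: np.ndarray):
        self.model = model
        self.params = params
        self.dispersion = float(dispersion)
        self.cov_params = cov

    # -- derived slopes ----------------------------------------------------
    @property
    def slope_pre(self) -> float:
        """Annual log-rate change before the breakpoint."""
        return float(self.params["year_c"])

    @property
    def slope_post(self) -> float:
        """Annual log-rate change after the breakpoint."""
        if "year_post" not in self.params.index:
            return self.slope_pre
        return float(self.params["year_c"] + self.params["year_post"])

    # -- prediction ---------------------------------------------------------
    def predict_rate(self, year, sex: str, ci: bool = False):
        """Smoothed rate per 1,000 infants (optionally with delta-method CI).

        The CI exponentiates a normal interval on the linear predictor.
        """
        year = np.atleast_1d(np.asarray(year))
        male = np.full(year.shape, sex == "male")
        X, _ = self.model._design(year, male)
        beta = self.params.to_numpy()
        lp = X @ beta
        rate = np.exp(lp) * 1000.0
        if not ci:
            return rate if rate.size > 1 else float(rate[0])
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov_params, X))
        z = stats.norm.ppf(0.975)
        lo = np.exp(lp - z * se) * 1000.0
        hi = np.exp(lp + z * se) * 1000.0
        return rate, lo, hi

    def deviance_explained(self) -> float:
        """Percentage deviance explained, 100 x (1 - residual/null deviance).

        The null model is intercept + offset only; both deviances are
        evaluated at the fitted NB2 dispersion.
        """
        y = self.model.data["prescriptions"].to_numpy(dtype=float)
        offset = np.log(self.model.data["births"].to_numpy(dtype=float))
        fam = sm.families.NegativeBinomial(alpha=max(self.dispersion, _ALPHA_FLOOR))
        X, _ = self.model.exog()
        mu_full = np.exp(X @ self.params.to_numpy() + offset)
        null = sm.GLM(y, np.ones((len(y), 1)), family=fam, offset=offset).fit()
        dev_null = float(null.deviance)
        if dev_null <= 0:
            raise ZeroDivisionError("null deviance is zero; deviance explained undefined")
        dev_full = float(fam.deviance(y, mu_full))
        return 100.0 * (1.0 - dev_full / dev_null)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        se = np.sqrt(np.diag(self.cov_params))
        return pd.DataFrame(
            {"low": self.params.to_numpy() - z * se, "high": self.params.to_numpy() + z * se},
            index=self.params.index,
        )

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.cov_params))
        lines = [
            "Negative-binomial prescription trend fit",
            f"  dispersion (alpha): {self.dispersion:.3g}",
            f"  deviance explained: {self.deviance_explained():.1f}%",
            f"  {'term':<10}{'coef':>10}{'se':>10}",
        ]
        for name, b, s in zip(self.params.index, self.params, se):
            lines.append(f"  {name:<10}{b:>10.4f}{s:>10.4f}")
        return "\n".join(lines)

    def build_scenarios(self, years: Iterable[int], base_year: int | None = None):
        return build_scenarios(self, years, base_year)


def build_scenarios(
    fit: TrendResults, years: Iterable[int], base_year: int | None = None
) -> dict[str, ScenarioCurve]:
    """Construct the base / flat / mid exposure scenario curves.

    * ``base`` — model-smoothed rates with 95% CIs;
    * ``flat`` — the smoothed `base_year` value repeated for every year,
      per sex;
    * ``mid`` — the pointwise arithmetic mean of base and flat.
    """
    years = np.sort(np.asarray(list(years), dtype=int))
    base_year = fit.model.base_year if base_year is None else int(base_year)
    if base_year not in years:
        raise ValueError(f"base_year {base_year} not in scenario years")
    frames: dict[str, list[dict]] = {"base": [], "flat": [], "mid": []}
    for sex in ("female", "male"):
        rate, lo, hi = fit.predict_rate(years, sex, ci=True)
        anchor = float(fit.predict_rate(base_year, sex))
        for i, year in enumerate(years):
            frames["base"].append(
                {"year": int(year), "sex": sex, "rate_per_1000": float(rate[i]),
                 "ci_low": float(lo[i]), "ci_high": float(hi[i])}
            )
            frames["flat"].append({"year": int(year), "sex": sex, "rate_per_1000": anchor})
            frames["mid"].append(
                {"year": int(year), "sex": sex, "rate_per_1000": (float(rate[i]) + anchor) / 2.0}
            )
    return {sid: ScenarioCurve(sid, pd.DataFrame(rows)) for sid, rows in frames.items()}


def scenarios_to_frame(curves: dict[str, ScenarioCurve]) -> pd.DataFrame:
    out = []
    for sid, curve in curves.items():
        df = curve.values.copy()
        df.insert(0, "scenario", sid)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def scenarios_from_frame(df: pd.DataFrame) -> dict[str, ScenarioCurve]:
    return {
        sid: ScenarioCurve(sid, sub.drop(columns="scenario").reset_index(drop=True))
        for sid, sub in df.groupby("scenario")
    }


def mean_rate(data: pd.DataFrame) -> int:
    """Overall prescriptions per 1,000 births, rounded half-up to integer."""
    if data.empty:
        raise ValueError("empty rate table")
    births = float(data["births"].sum())
    if births <= 0:
        raise ZeroDivisionError("total births is zero")
    return _round_half_up(float(data["prescriptions"].sum()) / births * 1000.0)


def percent_reduction(rate_from: float, rate_to: float) -> int:
    """Percent reduction between two rates, rounded half-up to integer."""
    if rate_from <= 0:
        raise ZeroDivisionError("starting rate must be > 0")
    return _round_half_up(100.0 * (rate_from - rate_to) / rate_from)
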
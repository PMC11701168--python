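"""Scenario comparison, excess-burden tables and the cost translation.

Counterfactual scenarios are compared against the base (factual) scenario
cell by cell: differences (counterfactual minus base), relative changes in
percent, Monte Carlo SDs from per-run paired differences when paired
replicates are available (variance addition otherwise), age-group shares of
the excess burden, and a direct-medical-cost translation of excess
person-years with asthma.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microsim import AGE_GROUPS, OUTCOMES, OutcomeTable

__all__ = [
    "compare",
    "age_group_share",
    "cost_savings",
    "CostSummary",
    "render_table2",
    "parse_rendered_csv",
]

_ALL_GROUPS = list(AGE_GROUPS) + ["overall"]


def _check_structure(base: OutcomeTable, cf: OutcomeTable) -> None:
    missing = []
    for table, label in ((base, "base"), (cf, "counterfactual")):
        s = table.summary()
        cells = set(zip(s["age_group"], s["outcome"]))
        for g in _ALL_GROUPS:
            for o in OUTCOMES:
                if (g, o) not in cells:
                    missing.append(f"{label}:({g}, {o})")
    if missing:
        raise ValueError("mismatched outcome tables; missing cells: " + ", ".join(missing))
    if base.n_runs and cf.n_runs and base.n_runs != cf.n_runs:
        raise ValueError(f"n_runs differ: base {base.n_runs} vs counterfactual {cf.n_runs}")


def compare(base: OutcomeTable, cf: OutcomeTable, paired_runs: bool = True) -> pd.DataFrame:
    """Cellwise excess burden of a counterfactual over the base scenario.

    Returns a DataFrame with columns ``scenario, age_group, outcome,
    base_mean, cf_mean, diff_mean, diff_sd, rel_change, rel_change_sd``.
    With `paired_runs` and per-run tallies on both tables, difference SDs
    come from the per-run paired differences and relative-change SDs from
    the per-run ratios; otherwise SDs combine by variance addition (and the
    relative-change SD is scaled by the base mean).
    """
    _check_structure(base, cf)
    paired = paired_runs and base.runs is not None and cf.runs is not None
    rows = []
    for g in _ALL_GROUPS:
        for o in OUTCOMES:
            b_mean = base.value(g, o)
            c_mean = cf.value(g, o)
            if paired:
                d = cf.per_run(g, o) - base.per_run(g, o)
                diff_mean = float(d.mean())
                diff_sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
                if b_mean != 0:
                    r = 100.0 * d / base.per_run(g, o)
                    rel, rel_sd = float(r.mean()), float(r.std(ddof=1)) if len(r) > 1 else 0.0
                else:
                    rel, rel_sd = np.nan, np.nan
            else:
                diff_mean = c_mean - b_mean
                diff_sd = float(np.hypot(base.value(g, o, "mc_sd"), cf.value(g, o, "mc_sd")))
                rel = 100.0 * diff_mean / b_mean if b_mean != 0 else np.nan
                rel_sd = 100.0 * diff_sd / b_mean if b_mean != 0 else np.nan
            rows.append(
                {
                    "scenario": cf.scenario,
                    "age_group": g,
                    "outcome": o,
                    "base_mean": b_mean,
                    "cf_mean": c_mean,
                    "diff_mean": diff_mean,
                    "diff_sd": diff_sd,
                    "rel_change": rel,
                    "rel_change_sd": rel_sd,
                }
            )
    return pd.DataFrame(rows)


def age_group_share(
    comparison: pd.DataFrame, groups: list[str], outcome: str
) -> float:
    """Share (percent, 1 dp) of the overall excess attributable to `groups`."""
    sub = comparison[comparison["outcome"] == outcome].set_index("age_group")
    unknown = set(groups) - set(AGE_GROUPS)
    if unknown:
        raise ValueError(f"unknown age groups: {sorted(unknown)}")
    overall = float(sub.loc["overall", "diff_mean"])
    if overall == 0:
        raise ZeroDivisionError("overall difference is zero; share undefined")
    selected = float(sub.loc[list(groups), "diff_mean"].sum())
    return round(100.0 * selected / overall, 1)


@dataclass(frozen=True)
class CostSummary:
    """Direct-medical-cost translation of excess person-years with asthma."""

    unit_cost: float  # currency per person-year (2024 CAD)
    excess_person_years: float
    total_savings: float

    @property
    def savings_millions(self) -> int:
        """Total savings rounded to the nearest million, for presentation."""
        return int(np.floor(self.total_savings / 1e6 + 0.5))


def cost_savings(excess_person_years: float, unit_cost: float = 550.0) -> CostSummary:
    """Excess person-years times the annual per-person cost of asthma."""
    if excess_person_years < 0 or unit_cost < 0:
        raise ValueError("inputs must be >= 0")
    return CostSummary(
        unit_cost=float(unit_cost),
        excess_person_years=float(excess_person_years),
        total_savings=float(unit_cost) * float(excess_person_years),
    )


# ---------------------------------------------------------------------------
# Burden-table rendering
# ---------------------------------------------------------------------------

_OUTCOME_LABEL = {
    "person_years": "Cumulative person-years with asthma",
    "incident_cases": "Cumulative asthma incident cases",
    "exacerbations": "Asthma exacerbations",
}


def render_table2(
    base: OutcomeTable, cf_flat: OutcomeTable, cf_mid: OutcomeTable
) -> tuple[pd.DataFrame, str]:
    """Render the three-scenario excess-burden table (CSV frame + text).

    Layout mirrors the published presentation: estimated values per
    scenario, differences versus base, and relative changes, with MC SDs in
    brackets in the text rendering.  A consistency check asserts that the
    age-group rows sum to the overall row for every scenario and outcome.
    """
    for t in (base, cf_flat, cf_mid):
        if t.summary().empty:
            raise ValueError("empty outcome table; nothing to render")
    _check_structure(base, cf_flat)
    _check_structure(base, cf_mid)
    cmp_flat = compare(base, cf_flat)
    cmp_mid = compare(base, cf_mid)
    records = []
    for o in OUTCOMES:
        for g in _ALL_GROUPS:
            rec = {"outcome": o, "age_group": g}
            for label, t in (("s1", base), ("s2", cf_flat), ("s3", cf_mid)):
                rec[f"{label}_mean"] = t.value(g, o)
                rec[f"{label}_sd"] = t.value(g, o, "mc_sd")
            for label, c in (("s2", cmp_flat), ("s3", cmp_mid)):
                row = c[(c["age_group"] == g) & (c["outcome"] == o)].iloc[0]
                rec[f"diff_{label}"] = row["diff_mean"]
                rec[f"diff_{label}_sd"] = row["diff_sd"]
                rec[f"rel_{label}"] = row["rel_change"]
                rec[f"rel_{label}_sd"] = row["rel_change_sd"]
            records.append(rec)
    df = pd.DataFrame(records)
    # consistency: age rows must sum to overall.  With per-run tallies this
    # holds to float precision; summary-only tables (published, rounded to
    # integers) are allowed printed-rounding slack of +/- 2.
    summary_only = any(t.runs is None for t in (base, cf_flat, cf_mid))
    atol_base = 2.0 if summary_only else 1e-6
    for o in OUTCOMES:
        sub = df[df["outcome"] == o].set_index("age_group")
        for col in ("s1_mean", "s2_mean", "s3_mean"):
            parts = sub.loc[list(AGE_GROUPS), col].sum()
            total = sub.loc["overall", col]
            if not np.isclose(parts, total, rtol=0, atol=max(atol_base * max(abs(total) * 1e-6, 1.0), atol_base)):
                raise AssertionError(
                    f"rendered {o}/{col}: age rows sum to {parts}, overall is {total}"
                )
    return df, _format_text(df)


def _fmt_count(x: float) -> str:
    return f"{x:,.0f}"


def _format_text(df: pd.DataFrame) -> str:
    lines = ["Evaluation of infant antibiotic exposure trends on asthma outcomes", ""]
    header = (
        f"{'Age group':<10}{'Scenario 1':>20}{'Scenario 2':>20}{'Scenario 3':>20}"
        f"{'Diff S2':>18}{'Diff S3':>18}{'Rel S2 (%)':>14}{'Rel S3 (%)':>14}"
    )
    for o in df["outcome"].unique():
        lines.append(_OUTCOME_LABEL.get(o, o))
        lines.append(header)
        for _, r in df[df["outcome"] == o].iterrows():
            lines.append(
                f"{r['age_group']:<10}"
                f"{_fmt_count(r['s1_mean']) + ' (' + _fmt_count(r['s1_sd']) + ')':>20}"
                f"{_fmt_count(r['s2_mean']) + ' (' + _fmt_count(r['s2_sd']) + ')':>20}"
                f"{_fmt_count(r['s3_mean']) + ' (' + _fmt_count(r['s3_sd']) + ')':>20}"
                f"{_fmt_count(r['diff_s2']) + ' (' + _fmt_count(r['diff_s2_sd']) + ')':>18}"
                f"{_fmt_count(r['diff_s3']) + ' (' + _fmt_count(r['diff_s3_sd']) + ')':>18}"
                f"{r['rel_s2']:>9.1f} ({r['rel_s2_sd']:.1f})"
                f"{r['rel_s3']:>9.1f} ({r['rel_s3_sd']:.1f})"
            )
        lines.append("")
    return "\n".join(lines)


def parse_rendered_csv(text: str) -> pd.DataFrame:
    """Re-parse a rendered CSV (round-trips `render_table2`'s frame)."""
    return pd.read_csv(io.StringIO(text))
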
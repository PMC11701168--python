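"""Loaders for the small published summary tables shipped with the package.

These are aggregated results of the British Columbia analysis as printed:
the three-scenario pediatric asthma burden table (means and Monte Carlo SDs
across 100 runs), the meta-regression posterior summaries, and headline
exposure statistics for the 2001-2018 study period.  They serve as inputs
for the desk-scale arithmetic (differences, shares, cost translation) and
as documented reference points; they are not outputs of this package's
simulator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta import MetaPosterior
from .microsim import OutcomeTable

__all__ = [
    "load_published_burden",
    "load_published_meta_posterior",
    "load_published_exposure_stats",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("abxasthma.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_published_burden() -> dict[str, OutcomeTable]:
    """Published three-scenario burden table as summary-only OutcomeTables.

    Keys are ``base`` (observed trends), ``flat`` (rate held at its 2001
    value) and ``mid`` (half the observed decline); each table reports 100
    Monte Carlo runs.
    """
    df = _read("published_burden_table.csv")
    return {
        sid: OutcomeTable.from_summary(sid, sub.reset_index(drop=True), n_runs=100)
        for sid, sub in df.groupby("scenario")
    }


def load_published_meta_posterior() -> MetaPosterior:
    """Published meta-regression point estimates as a degenerate posterior."""
    df = _read("published_meta_estimates.csv").set_index("parameter")
    return MetaPosterior.from_point_estimates(
        beta0=df.loc["beta0", "mean"],
        beta_canada=df.loc["beta_canada", "mean"],
        beta_age=df.loc["beta_age", "mean"],
        beta_dose=df.loc["beta_dose", "mean"],
        sigma_u_sq=df.loc["sigma_u_sq", "mean"],
    )


def load_published_exposure_stats() -> dict[str, float]:
    """Headline exposure statistics of the study period (quantity -> value)."""
    df = _read("published_exposure_stats.csv")
    return dict(zip(df["quantity"], df["value"].astype(float)))
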
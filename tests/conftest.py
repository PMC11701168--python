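import numpy as np
import pytest

import abxasthma as ax
from abxasthma.datasets import (
    load_published_burden,
    load_published_exposure_stats,
    load_published_meta_posterior,
)

YEARS = range(2001, 2019)


@pytest.fixture(scope="session")
def trend_truth():
    return ax.TrendTruth()


@pytest.fixture(scope="session")
def rate_table(trend_truth):
    return ax.gen_prescription_data(trend_truth, YEARS, seed=11)


@pytest.fixture(scope="session")
def trend_fit(rate_table):
    return ax.PrescriptionTrendModel(rate_table).fit()


@pytest.fixture(scope="session")
def scenario_curves(trend_fit):
    return trend_fit.build_scenarios(YEARS)


@pytest.fixture(scope="session")
def calibration():
    return ax.gen_calibration()


@pytest.fixture(scope="session")
def published_posterior():
    return load_published_meta_posterior()


@pytest.fixture(scope="session")
def published_burden():
    return load_published_burden()


@pytest.fixture(scope="session")
def published_stats():
    return load_published_exposure_stats()


@pytest.fixture(scope="session")
def dose_response(published_posterior):
    return ax.DoseResponse(published_posterior)


@pytest.fixture(scope="session")
def meta_table():
    truth = ax.MetaTruth(
        beta0=0.0, beta_age=0.0, beta_dose=0.05, sigma_u=0.1,
        n_studies=6, se_range=(0.02, 0.02),
    )
    return ax.gen_meta_studies(truth, seed=3)


@pytest.fixture(scope="session")
def meta_results(meta_table):
    return ax.DoseResponseMeta(meta_table).fit(seed=3)


@pytest.fixture(scope="session")
def quick_sim_config():
    """Small but non-trivial simulation settings for fast paired tests."""
    return ax.SimConfig(population_scale=0.02, n_runs=3, base_seed=5)


@pytest.fixture(scope="session")
def quick_outcomes(quick_sim_config, scenario_curves, calibration, dose_response):
    """Paired base/flat outcome tables sharing seeds (common random numbers)."""
    tables = {}
    for sid in ("base", "flat", "mid"):
        sim = ax.AsthmaMicrosim(
            quick_sim_config, scenario_curves[sid], calibration, dose_response
        )
        tables[sid] = sim.run()
    return tables


def seeds(n: int) -> np.ndarray:
    """Canonical seed list for coverage-style simulations."""
    return np.arange(n)
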
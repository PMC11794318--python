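import warnings

import numpy as np
import pandas as pd
import pytest

from trapnet import (
    MCMCConfig,
    SimScenario,
    SiteRegistry,
    TrapDataset,
    generate_dataset,
    impute_missing,
)


@pytest.fixture(autouse=True)
def _silence_convergence_warnings():
    # fast MCMC profiles legitimately trip the split-Rhat warning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def tri_registry():
    return SiteRegistry((1, 2, 3), np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]]))


def make_dataset(registry, counts_by_site_year):
    """counts_by_site_year: {(year, site): [weekly counts or None]}"""
    rows = []
    for (year, site), weekly in counts_by_site_year.items():
        for w, z in enumerate(weekly, start=1):
            rows.append(
                {
                    "year": year,
                    "site_id": site,
                    "week": w,
                    "count": np.nan if z is None else float(z),
                }
            )
    return TrapDataset(registry, pd.DataFrame(rows))


@pytest.fixture
def tiny_dataset(tri_registry):
    return make_dataset(
        tri_registry,
        {
            (2022, 1): [1.0, 2.0, 3.0],
            (2022, 2): [0.0, 0.0, 0.0],
            (2022, 3): [0.5, 0.0, 2.5],
        },
    )


@pytest.fixture(scope="session")
def study_scenario():
    return SimScenario(seed=3)


@pytest.fixture(scope="session")
def study_dataset(study_scenario):
    """Imputed study-schedule dataset plus its ground truth."""
    ds, truth = generate_dataset(study_scenario)
    return impute_missing(ds), truth


@pytest.fixture(scope="session")
def small_scenario():
    # near-constant fields in a compact region: kriging nearly exact
    return SimScenario(
        L=8,
        region_km=(10.0, 10.0),
        weeks_per_year={2021: 8, 2022: 9, 2023: 10},
        absent_site_years=frozenset(),
        missing_site_weeks=frozenset(),
        rho_beta=500.0,
        rho_gamma=500.0,
        sigma2_beta=0.25,
        sigma2_gamma=0.04,
        sigma2=1e-8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    ds, truth = generate_dataset(small_scenario)
    return ds, truth


@pytest.fixture
def fast_mcmc():
    return MCMCConfig.fast(seed=7)
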
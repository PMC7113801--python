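"""Shared fixtures: small seeded cohorts and window sets built at test time."""

import numpy as np
import pandas as pd
import pytest

from wtte_icu import cohort, preprocess


@pytest.fixture(scope="session")
def small_spec():
    """A compact drift cohort exercising every generator feature."""
    return cohort.CohortSpec(
        n_event=10, n_censored=50, horizon_steps=12,
        min_outcome_hours=13.0, max_stay_hours=96.0, seed=123,
    )


@pytest.fixture(scope="session")
def small_records(small_spec):
    return cohort.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_records_missing(small_spec, small_records):
    return cohort.inject_missingness(small_records, small_spec)


@pytest.fixture(scope="session")
def small_frames(small_records_missing):
    return cohort.cohort_frames(small_records_missing)


@pytest.fixture(scope="session")
def small_windows(small_spec, small_frames):
    series, patients = small_frames
    catalog = cohort.variable_catalog(small_spec.n_vars)
    wide, _ = preprocess.select_common_features(series, catalog["variable"].to_list(), patients)
    daily = catalog.loc[catalog["sampling"] == "daily", "variable"].to_list()
    wide = preprocess.resample_daily_to_hourly(wide, daily)
    ws = preprocess.build_windows(wide, patients, horizon_steps=12, max_windows=12)
    return ws, patients


def make_wide(cells: dict, n_hours: int, variables: list, patient_id: str = "p0"):
    """Hand-built wide feature table: cells maps (hour, var) -> value."""
    idx = pd.MultiIndex.from_product([[patient_id], range(n_hours)],
                                     names=["patient_id", "hour"])
    wide = pd.DataFrame(np.nan, index=idx, columns=variables)
    for (h, v), val in cells.items():
        wide.loc[(patient_id, h), v] = val
    return wide
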
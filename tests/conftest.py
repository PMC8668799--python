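"""Shared fixtures: seeded synthetic records at full and toy scale."""

import numpy as np
import pandas as pd
import pytest

from trygen import builder, fixtures, station

SEED = 1234


@pytest.fixture(scope="session")
def station_record_30y():
    return fixtures.gen_station_record(fixtures.StationConfig(), seed=SEED)


@pytest.fixture(scope="session")
def std_record(station_record_30y):
    return station.to_standard_calendar(station_record_30y)


@pytest.fixture(scope="session")
def daily_record(std_record):
    return station.daily_aggregate(std_record)


@pytest.fixture(scope="session")
def co2_record_30y():
    return fixtures.gen_co2_record(fixtures.StationConfig(), seed=SEED + 1)


@pytest.fixture(scope="session")
def small_record():
    """Fast 3-year record for unit tests."""
    cfg = fixtures.StationConfig(years=(2001, 2003))
    return station.to_standard_calendar(fixtures.gen_station_record(cfg, seed=7))


@pytest.fixture(scope="session")
def small_daily(small_record):
    return station.daily_aggregate(small_record)


@pytest.fixture(scope="session")
def ensemble_members():
    """Full 9-model x 3x3-grid mock ensemble with injected signals."""
    return fixtures.gen_ensemble(seed=42)


@pytest.fixture(scope="session")
def pc_try(std_record, co2_record_30y):
    return builder.build_try(std_record, co2_record_30y, None,
                             builder.ScenarioConfig(scenario="pc"))


def hourly_frame(values: dict, start="2001-01-01", freq="h") -> pd.DataFrame:
    """Small helper to build hourly frames in tests."""
    n = len(next(iter(values.values())))
    idx = pd.date_range(start, periods=n, freq=freq)
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()},
                        index=idx)
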
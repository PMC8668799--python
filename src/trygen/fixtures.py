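"""Seeded synthetic inputs: station record, CO2 record, model ensemble, logs.

Everything the pipeline consumes can be generated here without downloads:
a multi-decade hourly station record with seasonal/diurnal cycles,
autocorrelated weather noise and physically plausible covariation between
temperature, humidity, radiation and ozone; a CO2 record with an annual
cycle; a mock multi-member ensemble whose future runs carry known injected
climate signals (for parameter-recovery tests); and noisy minute-resolution
"measured" facility logs.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from trygen.ensemble import (
    EnsembleMemberSeries,
    saturation_vapor_pressure,
    subdaily_to_daily,
)
from trygen.station import HourlyStationRecord, record_from_frame

DAYS = 365


@dataclass
class StationConfig:
    years: tuple[int, int] = (1987, 2016)
    latitude_deg: float = 50.16
    ta_mean: float = 8.3
    ta_seasonal_amp: float = 9.0
    ta_diurnal_amp: float = 3.0
    #: weather-noise AR(1): high hourly persistence gives multi-day synoptic
    #: anomalies of several degC, as in real records
    ar_coeff: float = 0.99
    ar_sigma: float = 0.7
    rh_base: float = 78.6
    rh_slope: float = 1.2  # % per degC of temperature anomaly
    rh_sigma: float = 0.2  # independent rh noise innovation
    o3_sigma: float = 0.3  # independent ozone noise innovation
    solar_constant: float = 1000.0  # clear-sky peak W m-2
    o3_base: float = 22.0
    o3_rg_coupling: float = 0.03  # ppb per W m-2
    o3_ta_coupling: float = 0.5  # ppb per degC anomaly
    p_mean: float = 956.0
    co2_mean: float = 375.0

    def __post_init__(self) -> None:
        if self.years[1] - self.years[0] + 1 < 2:
            raise ValueError("need at least two years")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")


def _ar1(rng: np.random.Generator, n: int, coeff: float, sigma: float) -> np.ndarray:
    eps = rng.normal(0.0, sigma, n)
    return lfilter([1.0], [1.0, -coeff], eps)


def _season(doy_frac: np.ndarray) -> np.ndarray:
    """Annual cycle in [-1, 1] peaking in late July (day ~196)."""
    return np.cos(2 * np.pi * (doy_frac - 196.0) / 365.25)


def _solar_envelope(idx: pd.DatetimeIndex, latitude_deg: float) -> np.ndarray:
    """sin(solar elevation), floored at 0: simple declination/hour-angle model."""
    doy = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (doy + 10.0) / 365.25)
    lat = np.deg2rad(latitude_deg)
    hour_angle = np.deg2rad(15.0 * (idx.hour.to_numpy() - 12.0))
    sin_elev = (np.sin(lat) * np.sin(decl)
                + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))
    return np.clip(sin_elev, 0.0, None)


def gen_station_record(
    config: StationConfig | None = None, seed: int = 0
) -> HourlyStationRecord:
    """Synthetic hourly multivariate station record over the configured years."""
    cfg = config or StationConfig()
    rng = np.random.default_rng(seed)
    idx = pd.date_range(
        f"{cfg.years[0]}-01-01", f"{cfg.years[1]}-12-31 23:00", freq="h"
    )
    n = len(idx)
    doy_frac = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    season = _season(doy_frac)
    hour = idx.hour.to_numpy()
    diurnal = np.cos(2 * np.pi * (hour - 14.0) / 24.0)

    ta_noise = _ar1(rng, n, cfg.ar_coeff, cfg.ar_sigma)
    ta = (cfg.ta_mean
          + cfg.ta_seasonal_amp * season
          + cfg.ta_diurnal_amp * (0.6 + 0.4 * season) * diurnal
          + ta_noise)
    ta_anom = ta - (cfg.ta_mean + cfg.ta_seasonal_amp * season)

    rh = np.clip(
        cfg.rh_base
        - cfg.rh_slope * ta_anom
        - 6.0 * (0.6 + 0.4 * season) * diurnal
        + _ar1(rng, n, cfg.ar_coeff, cfg.rh_sigma),
        0.0, 100.0,
    )

    envelope = _solar_envelope(idx, cfg.latitude_deg)
    cloud = np.clip(0.7 + _ar1(rng, n, 0.98, 0.04), 0.05, 1.0)
    rg = cfg.solar_constant * envelope * cloud

    o3 = np.clip(
        cfg.o3_base
        + cfg.o3_rg_coupling * rg
        + cfg.o3_ta_coupling * ta_anom
        + _ar1(rng, n, cfg.ar_coeff, cfg.o3_sigma),
        0.0, None,
    )

    p = cfg.p_mean + _ar1(rng, n, 0.98, 0.5)

    df = pd.DataFrame({"ta": ta, "rh": rh, "p": p, "rg": rg, "o3": o3}, index=idx)
    return record_from_frame(df)


def gen_co2_record(
    config: StationConfig | None = None, seed: int = 1
) -> pd.Series:
    """Synthetic hourly CO2 record (ppm) with an annual cycle and AR noise."""
    cfg = config or StationConfig()
    rng = np.random.default_rng(seed)
    idx = pd.date_range(
        f"{cfg.years[0]}-01-01", f"{cfg.years[1]}-12-31 23:00", freq="h"
    )
    doy_frac = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    # Northern-hemisphere-style cycle: maximum in spring, trough in late summer
    cycle = 8.0 * np.cos(2 * np.pi * (doy_frac - 120.0) / 365.25)
    diurnal = 2.0 * np.cos(2 * np.pi * (idx.hour.to_numpy() - 4.0) / 24.0)
    noise = _ar1(rng, len(idx), 0.9, 0.5)
    return pd.Series(cfg.co2_mean + cycle + diurnal + noise, index=idx, name="co2")


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    n_models: int = 9
    grid_lats: tuple = (50.0, 50.15, 50.3)
    grid_lons: tuple = (9.2, 9.4, 9.6)
    ref_years: tuple[int, int] = (1987, 2016)
    split_year: int = 2005
    fc_years: tuple[int, int] = (2071, 2100)
    member_offset_sd: float = 1.0
    day_noise_sd: float = 1.0
    ta_seasonal_amp: float = 9.0
    ta_mean: float = 8.3
    rh_base: float = 78.6
    p_mean: float = 956.0
    #: injected additive signals per scenario: {"rcp26": (dta, drh), ...}
    signals: dict = field(default_factory=dict)
    q_model_index: int = 0  # this model delivers specific humidity
    subdaily_p_model_index: int = 1  # this model delivers 3-h pressure
    multirun_model_index: int = 2  # this model delivers several runs
    n_runs: int = 3


def default_injected_signals() -> dict:
    """Constant +3.3 degC warming and a summer-weighted humidity decline."""
    d = np.arange(DAYS)
    summer = 0.5 * (1 + np.cos(2 * np.pi * (d - 195) / DAYS))  # 1 mid-July, 0 mid-Jan
    return {
        "rcp26": (np.full(DAYS, 1.1), -2.0 * summer),
        "rcp85": (np.full(DAYS, 3.3), -6.0 * summer),
    }


def _std_doy_index(idx: pd.DatetimeIndex) -> np.ndarray:
    """0-based standard-calendar day index; Feb 29 reuses the Feb 28 value."""
    doy = idx.dayofyear.to_numpy().copy()
    leap = idx.is_leap_year & (doy > 59)
    doy[leap] -= 1
    return np.minimum(doy - 1, DAYS - 1)


def _rh_to_q(rh: np.ndarray, p: np.ndarray, ta: np.ndarray) -> np.ndarray:
    """Exact inverse of the package's q -> rh conversion."""
    e = rh / 100.0 * saturation_vapor_pressure(ta)
    return 0.622 * e / (p - 0.378 * e)


def gen_ensemble(
    config: EnsembleConfig | None = None, seed: int = 42
) -> list[EnsembleMemberSeries]:
    """Mock model ensemble with known injected future climate signals.

    Every (model, grid point) emits a historical run over the pre-split
    reference years and RCP2.6/RCP8.5 runs covering both the post-split
    reference years (no injected signal) and the future period (climatology
    plus the injected scenario signal).  One model delivers specific
    humidity, one delivers 3-h pressure (aggregated internally) and one
    delivers several runs to be averaged.
    """
    cfg = config or EnsembleConfig()
    signals = cfg.signals or default_injected_signals()
    rng = np.random.default_rng(seed)

    d = np.arange(DAYS)
    ta_clim = cfg.ta_mean + cfg.ta_seasonal_amp * np.cos(2 * np.pi * (d - 196) / DAYS)
    rh_clim = cfg.rh_base - 0.8 * (ta_clim - cfg.ta_mean)

    hist_idx = pd.date_range(
        f"{cfg.ref_years[0]}-01-01", f"{cfg.split_year - 1}-12-31", freq="D"
    )
    rcp_idx = pd.date_range(
        f"{cfg.split_year}-01-01", f"{cfg.ref_years[1]}-12-31", freq="D"
    ).append(pd.date_range(
        f"{cfg.fc_years[0]}-01-01", f"{cfg.fc_years[1]}-12-31", freq="D"
    ))

    members: list[EnsembleMemberSeries] = []
    for mi in range(cfg.n_models):
        model = f"GCM{mi}:RCM{mi}"
        off_ta = rng.normal(0.0, cfg.member_offset_sd)
        off_rh = rng.normal(0.0, cfg.member_offset_sd)
        n_runs = cfg.n_runs if mi == cfg.multirun_model_index else 1
        for lat in cfg.grid_lats:
            for lon in cfg.grid_lons:
                for run in range(n_runs):
                    run_id = f"r{run + 1}"
                    members.append(_make_member(
                        cfg, rng, model, "historical", lat, lon, run_id,
                        hist_idx, ta_clim, rh_clim, off_ta, off_rh, None, mi,
                    ))
                    for scen in ("rcp26", "rcp85"):
                        members.append(_make_member(
                            cfg, rng, model, scen, lat, lon, run_id,
                            rcp_idx, ta_clim, rh_clim, off_ta, off_rh,
                            signals[scen], mi,
                        ))
    return members


def _make_member(
    cfg: EnsembleConfig,
    rng: np.random.Generator,
    model: str, scenario: str, lat: float, lon: float, run_id: str,
    idx: pd.DatetimeIndex,
    ta_clim: np.ndarray, rh_clim: np.ndarray,
    off_ta: float, off_rh: float,
    signal: tuple | None,
    model_index: int,
) -> EnsembleMemberSeries:
    di = _std_doy_index(idx)
    n = len(idx)
    ta = ta_clim[di] + off_ta + rng.normal(0.0, cfg.day_noise_sd, n)
    rh = np.clip(rh_clim[di] + off_rh + rng.normal(0.0, cfg.day_noise_sd, n), 0, 100)
    if signal is not None:
        future = idx.year.to_numpy() >= cfg.fc_years[0]
        dta, drh = signal
        ta = ta + np.where(future, np.asarray(dta)[di], 0.0)
        rh = np.clip(rh + np.where(future, np.asarray(drh)[di], 0.0), 0, 100)

    if model_index == cfg.subdaily_p_model_index:
        sub_idx = pd.date_range(idx[0], idx[-1] + pd.Timedelta(hours=21), freq="3h")
        sub_idx = sub_idx[np.isin(sub_idx.normalize().to_numpy(), idx.to_numpy())]
        sub = pd.Series(cfg.p_mean + rng.normal(0.0, 2.0, len(sub_idx)), index=sub_idx)
        p = subdaily_to_daily(sub, 3).reindex(idx).to_numpy()
    else:
        p = cfg.p_mean + rng.normal(0.0, 2.0, n)

    kind = "rh"
    hum = rh
    if model_index == cfg.q_model_index:
        kind = "q"
        hum = _rh_to_q(rh, p, ta)
    df = pd.DataFrame({"ta": ta, "hum": hum, "p": p}, index=idx)
    return EnsembleMemberSeries(model, scenario, lat, lon, df, kind, run_id)


# ---------------------------------------------------------------------------
# measured facility logs
# ---------------------------------------------------------------------------

#: Realistic default sensor noise per variable.
DEFAULT_LOG_NOISE = {"ta": 0.1, "rh": 1.5, "ppfd": 10.0, "o3": 1.5, "co2": 5.0}


def gen_measured_logs(
    minutes: pd.DataFrame,
    noise_sd: dict | None = None,
    faults: list[dict] | None = None,
    seed: int = 7,
) -> pd.DataFrame:
    """Minute-resolution "measured" logs: trajectory + noise + fault episodes.

    Fault dicts: ``{"kind": "stuck"|"offset"|"dropout", "variable": v,
    "start": i, "length": n, "value": x}`` (``value`` is the held value for
    stuck, the additive shift for offset, ignored for dropout).
    """
    rng = np.random.default_rng(seed)
    sd = {**DEFAULT_LOG_NOISE, **(noise_sd or {})}
    out = minutes.copy()
    for var in out.columns:
        out[var] = out[var].to_numpy(float) + rng.normal(0.0, sd.get(var, 0.0), len(out))
    for fault in faults or []:
        var = fault["variable"]
        sl = slice(fault["start"], fault["start"] + fault["length"])
        col = out[var].to_numpy(float)
        if fault["kind"] == "stuck":
            col[sl] = fault["value"]
        elif fault["kind"] == "offset":
            col[sl] += fault["value"]
        elif fault["kind"] == "dropout":
            col[sl] = np.nan
        else:
            raise ValueError(f"unknown fault kind {fault['kind']!r}")
        out[var] = col
    return out
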
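"""Climate signals from ensemble model output.

Converts per-member daily model series (temperature, humidity, pressure) to
365-day reference climatologies, smooths them by truncating the annual
Fourier series after the third harmonic, and differences a future-period
climatology against a present-climate climatology assembled from historical
runs plus the two-scenario average of the early projection years.  Member x
grid-point signals are averaged flat into one ensemble-mean signal per
scenario.

Humidity from members that deliver specific humidity is converted to
relative humidity through the Magnus-type saturation vapor pressure and the
mixing-ratio form of the vapor pressure before any climatology is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS = 365


# ---------------------------------------------------------------------------
# humidity conversion
# ---------------------------------------------------------------------------

def vapor_pressure(q, P):
    """Vapor pressure e (hPa) from specific humidity q (kg/kg) and pressure P (hPa).

    e = q * P / (0.378 q + 0.622).
    """
    q = np.asarray(q, dtype=float)
    P = np.asarray(P, dtype=float)
    if (q < 0).any():
        raise ValueError("specific humidity must be non-negative")
    if (P <= 0).any():
        raise ValueError("pressure must be positive")
    return q * P / (0.378 * q + 0.622)


def saturation_vapor_pressure(ta):
    """Saturation vapor pressure E (hPa) at air temperature ta (degC).

    E = 6.122 * exp(17.62 ta / (243.12 + ta)).
    """
    ta = np.asarray(ta, dtype=float)
    if (ta <= -243.12).any():
        raise ValueError("temperature at or below -243.12 degC")
    return 6.122 * np.exp(17.62 * ta / (243.12 + ta))


def specific_humidity_to_rh(q, P, ta, return_clipped: bool = False):
    """Relative humidity (%) from specific humidity, clipped to [0, 100].

    With ``return_clipped`` also returns how many values were clipped.
    """
    rh = vapor_pressure(q, P) / saturation_vapor_pressure(ta) * 100.0
    clipped = int(((rh < 0) | (rh > 100)).sum())
    rh = np.clip(rh, 0.0, 100.0)
    if return_clipped:
        return rh, clipped
    return rh


# ---------------------------------------------------------------------------
# member series
# ---------------------------------------------------------------------------

@dataclass
class EnsembleMemberSeries:
    """Daily series of one model run at one grid point for one scenario.

    ``data`` is date-indexed with columns ``ta`` (degC), ``hum`` (% if
    ``humidity_kind == 'rh'``, kg/kg if ``'q'``) and ``p`` (hPa).
    """

    model_id: str
    scenario: str  # 'historical' | 'rcp26' | 'rcp85'
    lat: float
    lon: float
    data: pd.DataFrame
    humidity_kind: str = "rh"
    run_id: str = "r1"

    def __post_init__(self) -> None:
        if self.humidity_kind not in ("rh", "q"):
            raise ValueError(f"unknown humidity_kind {self.humidity_kind!r}")

    def with_rh(self) -> "EnsembleMemberSeries":
        """Return an equivalent member carrying relative humidity."""
        if self.humidity_kind == "rh":
            return self
        df = self.data.copy()
        df["hum"] = specific_humidity_to_rh(
            df["hum"].to_numpy(), df["p"].to_numpy(), df["ta"].to_numpy()
        )
        return EnsembleMemberSeries(
            self.model_id, self.scenario, self.lat, self.lon, df, "rh", self.run_id
        )


def subdaily_to_daily(series: pd.Series, step_hours: int) -> pd.Series:
    """Mean of each day's 24/step sub-daily values; partial days are an error."""
    if 24 % step_hours:
        raise ValueError("step_hours must divide 24")
    per_day = 24 // step_hours
    dates = series.index.normalize()
    counts = series.groupby(dates).size()
    if (counts != per_day).any():
        bad = counts.index[counts != per_day][0]
        raise ValueError(f"partial day {bad.date()}: {counts.loc[bad]} of {per_day} values")
    out = series.groupby(dates).mean()
    out.index = pd.DatetimeIndex(out.index)
    return out


def average_member_runs(runs: list[EnsembleMemberSeries]) -> EnsembleMemberSeries:
    """Day-wise mean over multiple runs of one model/scenario/grid point."""
    if not runs:
        raise ValueError("no runs to average")
    first = runs[0]
    for r in runs[1:]:
        if (r.model_id, r.scenario, r.lat, r.lon, r.humidity_kind) != (
            first.model_id, first.scenario, first.lat, first.lon, first.humidity_kind
        ):
            raise ValueError("runs differ in model/scenario/grid/humidity kind")
        if not r.data.index.equals(first.data.index):
            raise ValueError("runs have mismatched calendars")
    mean = sum(r.data for r in runs) / len(runs)
    return EnsembleMemberSeries(
        first.model_id, first.scenario, first.lat, first.lon, mean,
        first.humidity_kind, run_id="mean",
    )


# ---------------------------------------------------------------------------
# climatologies and smoothing
# ---------------------------------------------------------------------------

def annual_course(series: pd.Series) -> np.ndarray:
    """365-value mean annual course over all complete standard-calendar years.

    Feb 29 values are discarded; every year present must then contribute
    exactly 365 days.
    """
    idx = series.index
    keep = ~((idx.month == 2) & (idx.day == 29))
    s = series[keep]
    years = s.index.year
    counts = pd.Series(1, index=years).groupby(level=0).sum()
    if (counts != DAYS).any():
        bad = counts.index[counts != DAYS][0]
        raise ValueError(f"year {bad} is incomplete ({counts.loc[bad]} days)")
    doy = _standard_doy(s.index)
    course = s.groupby(doy).mean().to_numpy()
    if len(course) != DAYS:
        raise ValueError("series does not cover all 365 calendar days")
    return course


def _standard_doy(idx: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year 1..365 after Feb 29 removal (Mar 1 is always day 60)."""
    doy = idx.dayofyear.to_numpy().copy()
    leap = idx.is_leap_year & (doy > 59)
    doy[leap] -= 1
    return doy


def fft_smooth(climatology: np.ndarray, max_order: int = 3) -> np.ndarray:
    """Zero all Fourier harmonics above ``max_order`` on a 365-day series.

    Harmonic k completes k cycles per year; k = 0 (the mean) is always kept,
    so the day-mean is preserved exactly.
    """
    x = np.asarray(climatology, dtype=float)
    if x.shape != (DAYS,):
        raise ValueError(f"expected a length-{DAYS} series, got {x.shape}")
    spec = np.fft.rfft(x)
    spec[max_order + 1:] = 0.0
    return np.fft.irfft(spec, n=DAYS)


def build_pc_series(
    historical: pd.DataFrame,
    rcp26: pd.DataFrame,
    rcp85: pd.DataFrame,
    split_year: int,
    ref_years: tuple[int, int] = (1987, 2016),
) -> pd.DataFrame:
    """Present-climate daily series for the reference period.

    Years before ``split_year`` come from the historical run; years from
    ``split_year`` to the end of the reference period are the day-wise
    average of the two RCP projections.
    """
    start, end = ref_years
    hist = historical[(historical.index.year >= start)
                      & (historical.index.year < split_year)]
    a = rcp26[(rcp26.index.year >= split_year) & (rcp26.index.year <= end)]
    b = rcp85[(rcp85.index.year >= split_year) & (rcp85.index.year <= end)]
    if not a.index.equals(b.index):
        raise ValueError("RCP2.6 and RCP8.5 projections cover different days")
    have_hist = set(hist.index.year)
    if have_hist != set(range(start, split_year)):
        raise ValueError("historical run does not cover the pre-split reference years")
    if set(a.index.year) != set(range(split_year, end + 1)):
        raise ValueError("projections do not cover the post-split reference years")
    return pd.concat([hist, (a + b) / 2.0]).sort_index()


# ---------------------------------------------------------------------------
# climate signals
# ---------------------------------------------------------------------------

@dataclass
class ClimateSignal:
    """Additive 365-day deltas of one scenario relative to present climate."""

    scenario: str
    delta_ta: np.ndarray
    delta_rh: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.delta_ta = np.asarray(self.delta_ta, dtype=float)
        self.delta_rh = np.asarray(self.delta_rh, dtype=float)
        for arr in (self.delta_ta, self.delta_rh):
            if arr.shape != (DAYS,):
                raise ValueError("climate signal must have 365 daily values")
            if not np.isfinite(arr).all():
                raise ValueError("climate signal contains non-finite values")

    @classmethod
    def zero(cls, scenario: str = "pc") -> "ClimateSignal":
        return cls(scenario, np.zeros(DAYS), np.zeros(DAYS))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day_of_year": np.arange(1, DAYS + 1),
            "delta_ta": self.delta_ta,
            "delta_rh": self.delta_rh,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scenario: str) -> "ClimateSignal":
        df = df.sort_values("day_of_year")
        return cls(scenario, df["delta_ta"].to_numpy(), df["delta_rh"].to_numpy())


def climate_signal(
    fc_ta: np.ndarray, fc_rh: np.ndarray,
    pc_ta: np.ndarray, pc_rh: np.ndarray,
    scenario: str, provenance=None,
) -> ClimateSignal:
    """Day-wise future-minus-present difference of smoothed climatologies."""
    for a in (fc_ta, fc_rh, pc_ta, pc_rh):
        if np.asarray(a).shape != (DAYS,):
            raise ValueError("climatology length mismatch")
    return ClimateSignal(
        scenario,
        np.asarray(fc_ta) - np.asarray(pc_ta),
        np.asarray(fc_rh) - np.asarray(pc_rh),
        provenance=list(provenance or []),
    )


def ensemble_mean_signal(signals: list[ClimateSignal]) -> ClimateSignal:
    """Flat day-wise mean over all member x grid-point signals."""
    if not signals:
        raise ValueError("no signals to average")
    scen = signals[0].scenario
    dta = np.mean([s.delta_ta for s in signals], axis=0)
    drh = np.mean([s.delta_rh for s in signals], axis=0)
    prov = [p for s in signals for p in (s.provenance or [f"{scen}"])]
    return ClimateSignal(scen, dta, drh, provenance=prov)


def compute_ensemble_signal(
    members: list[EnsembleMemberSeries],
    scenario: str,
    split_year: int = 2005,
    ref_years: tuple[int, int] = (1987, 2016),
    fc_years: tuple[int, int] = (2071, 2100),
    max_order: int = 3,
) -> ClimateSignal:
    """Ensemble-mean climate signal of one RCP scenario.

    For every (model, grid point): average multi-run members, convert
    specific humidity, assemble the present-climate series, compute smoothed
    365-day climatologies for both periods and difference them; then average
    all signals flat.
    """
    if scenario not in ("rcp26", "rcp85"):
        raise ValueError(f"scenario must be an RCP, got {scenario!r}")
    groups: dict[tuple, dict[str, list[EnsembleMemberSeries]]] = {}
    for m in members:
        key = (m.model_id, round(m.lat, 6), round(m.lon, 6))
        groups.setdefault(key, {}).setdefault(m.scenario, []).append(m)

    signals = []
    for (model, lat, lon), by_scen in sorted(groups.items()):
        try:
            hist = average_member_runs(by_scen["historical"]).with_rh()
            r26 = average_member_runs(by_scen["rcp26"]).with_rh()
            r85 = average_member_runs(by_scen["rcp85"]).with_rh()
        except KeyError as missing:
            raise ValueError(
                f"member {model} at ({lat},{lon}) lacks scenario {missing}"
            ) from None
        pc = build_pc_series(hist.data, r26.data, r85.data, split_year, ref_years)
        fc_all = r26 if scenario == "rcp26" else r85
        fc = fc_all.data[(fc_all.data.index.year >= fc_years[0])
                         & (fc_all.data.index.year <= fc_years[1])]
        sig = climate_signal(
            fft_smooth(annual_course(fc["ta"]), max_order),
            fft_smooth(annual_course(fc["hum"]), max_order),
            fft_smooth(annual_course(pc["ta"]), max_order),
            fft_smooth(annual_course(pc["hum"]), max_order),
            scenario,
            provenance=[f"{model}@{lat},{lon}"],
        )
        signals.append(sig)
    return ensemble_mean_signal(signals)


# ---------------------------------------------------------------------------
# long-format CSV interchange
# ---------------------------------------------------------------------------

def members_to_frame(members: list[EnsembleMemberSeries]) -> pd.DataFrame:
    """Serialize members to a long-format table (one row per day/variable)."""
    rows = []
    for m in members:
        long = m.data.reset_index(names="date").melt(
            id_vars="date", var_name="variable", value_name="value"
        )
        long.insert(0, "model_id", m.model_id)
        long.insert(1, "run_id", m.run_id)
        long.insert(2, "scenario", m.scenario)
        long.insert(3, "lat", m.lat)
        long.insert(4, "lon", m.lon)
        long.insert(5, "humidity_kind", m.humidity_kind)
        rows.append(long)
    return pd.concat(rows, ignore_index=True)


def members_from_frame(df: pd.DataFrame) -> list[EnsembleMemberSeries]:
    """Inverse of :func:`members_to_frame`."""
    members = []
    keys = ["model_id", "run_id", "scenario", "lat", "lon", "humidity_kind"]
    for vals, g in df.groupby(keys, sort=True):
        wide = g.pivot_table(index="date", columns="variable", values="value")
        wide.index = pd.DatetimeIndex(wide.index)
        wide = wide.sort_index()[["ta", "hum", "p"]]
        wide.columns.name = None
        wide.index.name = None
        model, run, scen, lat, lon, hum = vals
        members.append(EnsembleMemberSeries(model, scen, float(lat), float(lon),
                                            wide, hum, run))
    return members
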
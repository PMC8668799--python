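"""Hourly station records: reading, quality control, gap filling, aggregation.

A record holds an hourly-regular multivariate table (air temperature ``ta``
in degC, relative humidity ``rh`` in %, pressure ``p`` in hPa, global
radiation ``rg`` in W m-2, ozone ``o3`` in ppb and optionally ``co2`` in
ppm) together with a per-cell QC flag table.  Flags distinguish observed
values, gap-filled values and invalid cells; after :func:`fill_gaps` no cell
is missing and every synthetic cell is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: QC flag codes stored per cell.
OBSERVED = 0
FILLED = 1
INVALID = 2

#: Canonical variable order; ``co2`` is optional and appended when present.
CORE_VARS = ("ta", "rh", "p", "rg", "o3")

#: Units accepted per variable by the CSV reader.
KNOWN_UNITS = {
    "ta": {"degC", "C"},
    "rh": {"%", "percent"},
    "p": {"hPa"},
    "rg": {"W/m2", "W m-2"},
    "o3": {"ppb"},
    "co2": {"ppm"},
}

#: Default plausibility limits: (min, max, max |step| between adjacent hours).
DEFAULT_LIMITS = {
    "ta": (-40.0, 45.0, 10.0),
    "rh": (0.0, 100.0, 50.0),
    "p": (850.0, 1080.0, 10.0),
    "rg": (0.0, 1200.0, 800.0),
    "o3": (0.0, 250.0, 60.0),
    "co2": (250.0, 1200.0, 60.0),
}


@dataclass
class FormatSpec:
    """Column layout of a station CSV file.

    ``columns`` maps internal variable names to CSV column headers and
    ``units`` gives the unit string of each mapped column.
    """

    timestamp: str = "timestamp"
    columns: dict = field(
        default_factory=lambda: {
            "ta": "ta_C",
            "rh": "rh_pct",
            "p": "P_hPa",
            "rg": "Rg_Wm2",
            "o3": "o3_ppb",
        }
    )
    units: dict = field(
        default_factory=lambda: {
            "ta": "degC",
            "rh": "%",
            "p": "hPa",
            "rg": "W/m2",
            "o3": "ppb",
            "co2": "ppm",
        }
    )


@dataclass
class HourlyStationRecord:
    """Hourly-regular station record with per-cell QC flags.

    ``data`` and ``flags`` share an hourly :class:`~pandas.DatetimeIndex`
    (timezone-naive local standard time; the stamp marks the start of the
    averaging hour).  Invalid cells hold NaN in ``data``.
    """

    data: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.flags.index):
            raise ValueError("data and flags must share one index")
        if list(self.data.columns) != list(self.flags.columns):
            raise ValueError("data and flags must share one column set")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "HourlyStationRecord":
        return HourlyStationRecord(self.data.copy(), self.flags.copy())

    def __len__(self) -> int:
        return len(self.data)


def _hourly_regularize(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sort, de-duplicate and reindex onto a gap-free hourly grid."""
    df = df[~df.index.duplicated(keep="first")].sort_index()
    full = pd.date_range(df.index[0], df.index[-1], freq="h")
    out = df.reindex(full)
    flags = pd.DataFrame(OBSERVED, index=full, columns=df.columns, dtype=np.int8)
    flags[out.isna()] = INVALID
    return out, flags


def record_from_frame(df: pd.DataFrame) -> HourlyStationRecord:
    """Build a record from an hourly data frame (NaN cells become invalid)."""
    data, flags = _hourly_regularize(df.astype(float))
    return HourlyStationRecord(data, flags)


def read_station_record(path, format_spec: FormatSpec | None = None) -> HourlyStationRecord:
    """Read a station CSV and return an hourly-regularized record.

    Missing hours are inserted as invalid cells.  Unparseable timestamps and
    unknown units are hard errors.
    """
    spec = format_spec or FormatSpec()
    for var, unit in spec.units.items():
        if var in KNOWN_UNITS and unit not in KNOWN_UNITS[var]:
            raise ValueError(f"unknown unit {unit!r} for variable {var!r}")
    raw = pd.read_csv(path, float_precision="round_trip")
    if spec.timestamp not in raw.columns:
        raise ValueError(f"timestamp column {spec.timestamp!r} not in file")
    ts = pd.to_datetime(raw[spec.timestamp], errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp at data row {bad}: {raw[spec.timestamp].iloc[bad]!r}"
        )
    cols = {}
    for var, col in spec.columns.items():
        if col not in raw.columns:
            raise ValueError(f"column {col!r} for variable {var!r} not in file")
        cols[var] = pd.to_numeric(raw[col], errors="coerce").to_numpy(float)
    df = pd.DataFrame(cols, index=pd.DatetimeIndex(ts))
    return record_from_frame(df)


def write_station_record(record: HourlyStationRecord, path,
                         format_spec: FormatSpec | None = None) -> None:
    """Write the record as CSV in the same dialect :func:`read_station_record` reads."""
    spec = format_spec or FormatSpec()
    out = pd.DataFrame({spec.timestamp: record.data.index})
    for var in record.variables:
        out[spec.columns.get(var, var)] = record.data[var].to_numpy()
    # 17 significant digits round-trip any double, so write->read is exact
    out.to_csv(path, index=False, float_format="%.17g")


def quality_control(
    record: HourlyStationRecord, limits: dict | None = None
) -> tuple[HourlyStationRecord, dict]:
    """Flag out-of-range values and isolated spikes as invalid.

    ``limits`` maps variable -> (min, max, max hourly step).  A cell is a
    spike when the absolute step to *both* neighbours exceeds the step limit.
    Always succeeds; returns the cleaned record and a per-variable report of
    newly invalidated cell counts.
    """
    limits = {**DEFAULT_LIMITS, **(limits or {})}
    out = record.copy()
    report: dict[str, int] = {}
    for var in out.variables:
        lo, hi, jump = limits.get(var, (-np.inf, np.inf, np.inf))
        x = out.data[var].to_numpy(float)
        bad = (x < lo) | (x > hi)
        d = np.abs(np.diff(x))
        spike = np.zeros_like(bad)
        spike[1:-1] = (d[:-1] > jump) & (d[1:] > jump)
        bad |= spike
        bad &= ~np.isnan(x)
        report[var] = int(bad.sum())
        col = out.data[var].to_numpy(float)
        col[bad] = np.nan
        out.data[var] = col
        fl = out.flags[var].to_numpy()
        fl[bad] = INVALID
        out.flags[var] = fl
    return out, report


def _calendar_hour_key(index: pd.DatetimeIndex) -> np.ndarray:
    """(month, day, hour) encoded as a single int for group-wise climatology."""
    return (index.month.to_numpy() * 10000
            + index.day.to_numpy() * 100
            + index.hour.to_numpy())


def fill_gaps(record: HourlyStationRecord, max_linear_gap: int = 6) -> HourlyStationRecord:
    """Fill every invalid cell; linear for short gaps, climatological beyond.

    Gaps of at most ``max_linear_gap`` hours bounded by valid values are
    linearly interpolated; anything longer (or unbounded) takes the mean of
    the valid values at the same calendar (month, day, hour) across all
    years.  Every filled cell is flagged ``FILLED``.
    """
    out = record.copy()
    key = _calendar_hour_key(out.data.index)
    for var in out.variables:
        x = out.data[var].to_numpy(float).copy()
        missing = np.isnan(x)
        if missing.all():
            raise ValueError(f"variable {var!r} has no valid data to fill from")
        if not missing.any():
            continue
        lin = pd.Series(x, index=out.data.index).interpolate(
            method="linear", limit=max_linear_gap, limit_area="inside"
        )
        # identify runs short enough for the linear rule
        runs = _nan_runs(missing)
        linear_ok = np.zeros_like(missing)
        for start, stop in runs:
            if stop - start <= max_linear_gap and start > 0 and stop < len(x):
                linear_ok[start:stop] = True
        x[linear_ok] = lin.to_numpy()[linear_ok]
        still = np.isnan(x)
        if still.any():
            observed = out.data[var].to_numpy(float)  # NaN at every gap cell
            clim = pd.Series(observed).groupby(key).mean()
            fill = clim.reindex(key[still]).to_numpy()
            if np.isnan(fill).any():
                # calendar slot never observed (e.g. Feb 29 in a short record)
                fill = np.where(np.isnan(fill), np.nanmean(x), fill)
            x[still] = fill
        filled = missing & ~np.isnan(x)
        out.data[var] = x
        fl = out.flags[var].to_numpy()
        fl[filled] = FILLED
        out.flags[var] = fl
    return out


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive True values."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def to_standard_calendar(record: HourlyStationRecord) -> HourlyStationRecord:
    """Drop every Feb 29 so each full year has exactly 8,760 hours."""
    idx = record.data.index
    keep = ~((idx.month == 2) & (idx.day == 29))
    return HourlyStationRecord(record.data.loc[keep].copy(), record.flags.loc[keep].copy())


def daily_aggregate(record: HourlyStationRecord) -> pd.DataFrame:
    """Aggregate a gap-filled standard-calendar record to daily resolution.

    Returns a date-indexed frame with per-variable daily means plus
    ``tmin``/``tmax``/``tmean`` from the 24 hourly ``ta`` values.  A day with
    any invalid cell is a hard error — gap filling must run first.
    """
    if (record.flags.to_numpy() == INVALID).any():
        raise ValueError("record contains invalid cells; run fill_gaps first")
    dates = record.data.index.normalize()
    counts = pd.Series(1, index=dates).groupby(level=0).sum()
    if (counts != 24).any():
        bad = counts.index[counts != 24][0]
        raise ValueError(f"day {bad.date()} has {counts.loc[bad]} hours, expected 24")
    grouped = record.data.groupby(dates)
    daily = grouped.mean()
    daily["tmin"] = grouped["ta"].min()
    daily["tmax"] = grouped["ta"].max()
    daily["tmean"] = daily["ta"]
    daily.index = pd.DatetimeIndex(daily.index)
    return daily
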
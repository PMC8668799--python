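"""Facility adaptation: clipping, PPFD conversion, ozone treatments, ramps.

The raw TRY exceeds what a walk-in climate chamber can deliver, so hourly
setpoints are clipped to the facility envelope (temperature capped at 30 degC,
day/night floors, humidity caps), global radiation is converted to PPFD with
month-specific factors and the high-intensity range is compressed into the
LED envelope, ozone is shifted into treatment gradients, and the hourly
program is expanded to a minute trajectory under per-variable slew limits
(CO2 limited on enrichment only; light steps instantly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default month -> Rg-to-PPFD factor (umol J-1); winter low, summer high.
DEFAULT_PPFD_FACTORS = {
    1: 1.90, 2: 1.90, 3: 2.00, 4: 2.00, 5: 2.00, 6: 2.10,
    7: 2.10, 8: 2.10, 9: 2.00, 10: 2.00, 11: 2.00, 12: 1.90,
}

#: Per-minute slew limits; CO2 applies to increases (enrichment) only.
DEFAULT_SLEW = {"ta": 0.08, "rh": 0.3, "o3": 0.3, "co2": 0.7}

O3_TREATMENTS = ("unchanged", "preindustrial", "moderate", "high")


@dataclass
class FacilityLimits:
    t_max: float = 30.0
    t_min_day: float = 10.0
    t_min_night: float = 4.0
    rh_max_day: float = 75.0
    rh_max_night: float = 90.0
    rh_min: float = 30.0
    ppfd_floor: float = 24.0
    ppfd_compress_lo: float = 600.0
    ppfd_compress_hi_in: float = 2030.0
    ppfd_compress_hi_out: float = 800.0
    slew: dict = field(default_factory=lambda: dict(DEFAULT_SLEW))

    def __post_init__(self) -> None:
        if not (self.t_min_night <= self.t_min_day <= self.t_max):
            raise ValueError("temperature bounds out of order")
        if not (self.rh_min <= self.rh_max_day <= self.rh_max_night):
            raise ValueError("humidity bounds out of order")
        if not (self.ppfd_floor < self.ppfd_compress_lo
                <= self.ppfd_compress_hi_out <= self.ppfd_compress_hi_in):
            raise ValueError("PPFD bounds out of order")


@dataclass
class ChamberProgram:
    """Hourly chamber setpoints, optionally with a minute-resolution trajectory."""

    hourly: pd.DataFrame  # columns ta, rh, ppfd, o3, co2
    treatment: str = "unchanged"
    minutes: pd.DataFrame | None = None


def day_mask(rg: np.ndarray) -> np.ndarray:
    """Photoperiod classification: an hour is 'day' when radiation is positive."""
    return np.asarray(rg, dtype=float) > 0


def apply_facility_limits(
    ta: np.ndarray, rh: np.ndarray, is_day: np.ndarray,
    limits: FacilityLimits | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Clip temperature and humidity into the chamber envelope.

    Temperature: capped at ``t_max``; raised to the day or night floor.
    Humidity: capped at the day/night maximum, floored at ``rh_min``.
    """
    lim = limits or FacilityLimits()
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    is_day = np.asarray(is_day, dtype=bool)
    t_floor = np.where(is_day, lim.t_min_day, lim.t_min_night)
    rh_cap = np.where(is_day, lim.rh_max_day, lim.rh_max_night)
    return (
        np.clip(ta, t_floor, lim.t_max),
        np.clip(rh, lim.rh_min, rh_cap),
    )


def rg_to_ppfd(rg: np.ndarray, month: np.ndarray, factors: dict | None = None) -> np.ndarray:
    """PPFD (umol m-2 s-1) = Rg (W m-2) times a month-specific factor."""
    table = {**DEFAULT_PPFD_FACTORS, **(factors or {})}
    for m, f in table.items():
        if not 1.90 <= f <= 2.10:
            warnings.warn(f"PPFD factor {f} for month {m} outside [1.90, 2.10]")
    month = np.asarray(month, dtype=int)
    fac = np.array([table[m] for m in range(1, 13)])
    return np.asarray(rg, dtype=float) * fac[month - 1]


def compress_ppfd(ppfd: np.ndarray, limits: FacilityLimits | None = None) -> np.ndarray:
    """Compress high intensities into the LED envelope and apply the LED floor.

    Values in (lo, hi_in] map linearly onto (lo, hi_out]; values above hi_in
    clip to hi_out with a warning; positive values below the floor are raised
    to it; zeros (lights off) stay zero.
    """
    lim = limits or FacilityLimits()
    x = np.asarray(ppfd, dtype=float).copy()
    over = x > lim.ppfd_compress_hi_in
    if over.any():
        warnings.warn(f"{int(over.sum())} PPFD values above "
                      f"{lim.ppfd_compress_hi_in}; clipped to {lim.ppfd_compress_hi_out}")
    mid = (x > lim.ppfd_compress_lo) & (x <= lim.ppfd_compress_hi_in)
    scale = (lim.ppfd_compress_hi_out - lim.ppfd_compress_lo) / (
        lim.ppfd_compress_hi_in - lim.ppfd_compress_lo
    )
    x[mid] = lim.ppfd_compress_lo + (x[mid] - lim.ppfd_compress_lo) * scale
    x[over] = lim.ppfd_compress_hi_out
    x[(x > 0) & (x < lim.ppfd_floor)] = lim.ppfd_floor
    return x


def o3_treatment(o3: np.ndarray, treatment: str) -> np.ndarray:
    """Shift the hourly ozone series into one of the treatment gradients.

    unchanged      identity.
    preindustrial  normalized to its annual mean, scaled to a 10 ppb mean.
    moderate       < 40 ppb: +5; > 45 ppb: -5; in between unchanged.
    high           < 40 ppb: +10; 40..<50 ppb: +5; >= 50 ppb: -5.
    """
    x = np.asarray(o3, dtype=float).copy()
    if treatment == "unchanged":
        return x
    if treatment == "preindustrial":
        m = x.mean()
        if m <= 0:
            raise ValueError("ozone mean must be positive for normalization")
        return x / m * 10.0
    if treatment == "moderate":
        out = x.copy()
        out[x < 40.0] += 5.0
        out[x > 45.0] -= 5.0
        return out
    if treatment == "high":
        out = x.copy()
        out[x < 40.0] += 10.0
        out[(x >= 40.0) & (x < 50.0)] += 5.0
        out[x >= 50.0] -= 5.0
        return out
    raise ValueError(f"unknown ozone treatment {treatment!r}")


def ramp_setpoints(
    hourly: pd.DataFrame, slew: dict | None = None
) -> pd.DataFrame:
    """Expand hourly setpoints into a slew-limited 1-minute trajectory.

    Between consecutive setpoints each controlled variable follows the
    linear 60-step path unless its per-minute change would exceed the slew
    limit, in which case it pursues the target at the limit without
    overshooting (and may not reach it within the hour).  The CO2 limit
    applies to enrichment (increases) only.  PPFD has no ramp: it holds and
    steps instantly at the hour boundary.  Output has 60*(n-1)+1 rows.
    """
    caps = {**DEFAULT_SLEW, **(slew or {})}
    if any(v <= 0 for v in caps.values()):
        raise ValueError("slew limits must be positive")
    n = len(hourly)
    if n < 2:
        raise ValueError("need at least two hourly setpoints to ramp")
    total = 60 * (n - 1) + 1
    out = {}
    for var in hourly.columns:
        x = hourly[var].to_numpy(float)
        if var == "ppfd":
            traj = np.empty(total)
            traj[0] = x[0]
            for h in range(n - 1):
                traj[60 * h + 1: 60 * h + 61] = x[h + 1]
            out[var] = traj
            continue
        cap = caps.get(var)
        traj = np.empty(total)
        pos = x[0]
        traj[0] = pos
        for h in range(n - 1):
            target = x[h + 1]
            step = (target - pos) / 60.0
            if cap is not None:
                if var == "co2":
                    if step > cap:
                        step = cap
                elif abs(step) > cap:
                    step = np.sign(step) * cap
            path = pos + step * np.arange(1, 61)
            if step > 0:
                np.minimum(path, target, out=path)
            elif step < 0:
                np.maximum(path, target, out=path)
            traj[60 * h + 1: 60 * h + 61] = path
            pos = path[-1]
        out[var] = traj
    if isinstance(hourly.index, pd.DatetimeIndex):
        idx = pd.date_range(hourly.index[0], periods=total, freq="min")
    else:
        idx = pd.RangeIndex(total)
    return pd.DataFrame(out, index=idx)


def adapt_try(
    try_data: pd.DataFrame,
    treatment: str = "unchanged",
    limits: FacilityLimits | None = None,
    ppfd_factors: dict | None = None,
    with_minutes: bool = False,
) -> ChamberProgram:
    """Full chamber program for one TRY and ozone treatment.

    ``try_data`` is the hourly TRY table (columns ta, rh, p, rg, o3, co2).
    """
    lim = limits or FacilityLimits()
    is_day = day_mask(try_data["rg"].to_numpy())
    ta, rh = apply_facility_limits(
        try_data["ta"].to_numpy(), try_data["rh"].to_numpy(), is_day, lim
    )
    months = (try_data.index.month if isinstance(try_data.index, pd.DatetimeIndex)
              else np.ones(len(try_data), dtype=int))
    ppfd = compress_ppfd(
        rg_to_ppfd(try_data["rg"].to_numpy(), np.asarray(months), ppfd_factors), lim
    )
    o3 = o3_treatment(try_data["o3"].to_numpy(), treatment)
    hourly = pd.DataFrame(
        {"ta": ta, "rh": rh, "ppfd": ppfd, "o3": o3,
         "co2": try_data["co2"].to_numpy(float)},
        index=try_data.index,
    )
    minutes = ramp_setpoints(hourly, lim.slew) if with_minutes else None
    return ChamberProgram(hourly, treatment, minutes)
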
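"""Extreme indices, kernel-density PDFs and prescribed-vs-measured statistics.

Indices follow the standard daily min/max/mean temperature definitions:
percentile indices (TN10p, TX10p, TN90p, TX90p) use per-calendar-day
thresholds pooled over a centered 5-day window of the base period; GSL, FD0,
SU25 and WSDI are run/count indices.  Thresholds are computed once from the
base record and applied to every year — no in-base bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

DAYS = 365


# ---------------------------------------------------------------------------
# percentile thresholds
# ---------------------------------------------------------------------------

def percentile_thresholds(
    base: np.ndarray, q: float, window: int = 5
) -> np.ndarray:
    """Per-calendar-day q-th percentile of a (years, 365) base-period array.

    For each day the pool is every base-period value within the centered
    ``window``-day span (wrapping across the year boundary); percentiles use
    linear interpolation.
    """
    base = np.atleast_2d(np.asarray(base, dtype=float))
    if base.shape[1] != DAYS:
        raise ValueError(f"base record must have {DAYS} columns")
    if base.shape[0] < 5:
        warnings.warn("fewer than 5 base years; percentile thresholds are noisy")
    half = window // 2
    out = np.empty(DAYS)
    for d in range(DAYS):
        cols = [(d + off) % DAYS for off in range(-half, half + 1)]
        out[d] = np.percentile(base[:, cols], q, method="linear")
    return out


def percent_exceedance_indices(
    tmin: np.ndarray, tmax: np.ndarray,
    thr_tn10: np.ndarray, thr_tx10: np.ndarray,
    thr_tn90: np.ndarray, thr_tx90: np.ndarray,
) -> dict:
    """TN10p/TX10p/TN90p/TX90p as % of the 365 days (strict inequalities)."""
    for name, arr in (("tmin", tmin), ("tmax", tmax)):
        if np.asarray(arr).shape != (DAYS,):
            raise ValueError(f"{name} must cover the full year")
        if np.isnan(arr).any():
            raise ValueError(f"{name} contains missing days")
    pct = lambda mask: 100.0 * np.count_nonzero(mask) / DAYS  # noqa: E731
    return {
        "TN10p": pct(tmin < thr_tn10),
        "TX10p": pct(tmax < thr_tx10),
        "TN90p": pct(tmin > thr_tn90),
        "TX90p": pct(tmax > thr_tx90),
    }


# ---------------------------------------------------------------------------
# count and span indices
# ---------------------------------------------------------------------------

def _first_run_start(mask: np.ndarray, min_len: int) -> int | None:
    """Index of the first run of at least ``min_len`` consecutive True."""
    run = 0
    for i, v in enumerate(mask):
        run = run + 1 if v else 0
        if run >= min_len:
            return i - min_len + 1
    return None


def gsl(tg: np.ndarray, threshold: float = 5.0, span: int = 6,
        midyear_index: int = 181) -> int:
    """Growing season length in days.

    Counts days from the first ``span``-day run of daily means above
    ``threshold`` to the day before the first such run below the threshold
    starting after 1 July (index 181).  No start run: 0.  No end run: the
    season runs to 31 December.
    """
    tg = np.asarray(tg, dtype=float)
    if tg.shape != (DAYS,):
        raise ValueError("need 365 daily mean temperatures")
    start = _first_run_start(tg > threshold, span)
    if start is None:
        return 0
    cold = _first_run_start(tg[midyear_index:] < threshold, span)
    end = DAYS if cold is None else midyear_index + cold
    return max(end - start, 0)


def count_indices(tmin: np.ndarray, tmax: np.ndarray) -> dict:
    """FD0 (frost days, tmin < 0) and SU25 (summer days, tmax > 25)."""
    return {
        "FD0": int(np.count_nonzero(np.asarray(tmin, float) < 0.0)),
        "SU25": int(np.count_nonzero(np.asarray(tmax, float) > 25.0)),
    }


def wsdi(tmax: np.ndarray, thr90: np.ndarray, min_run: int = 6) -> int:
    """Warm-spell duration: total days in runs of >= 6 exceedance days."""
    exceed = np.asarray(tmax, float) > np.asarray(thr90, float)
    total = run = 0
    for v in np.append(exceed, False):
        if v:
            run += 1
        else:
            if run >= min_run:
                total += run
            run = 0
    return total


@dataclass
class ExtremeIndexSet:
    TN10p: float
    TX10p: float
    TN90p: float
    TX90p: float
    GSL: int
    FD0: int
    SU25: int
    WSDI: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def extreme_indices(
    tmin: np.ndarray, tmax: np.ndarray, tmean: np.ndarray,
    base_tmin: np.ndarray, base_tmax: np.ndarray,
) -> ExtremeIndexSet:
    """All Table-style indices of one year against a multi-year base period."""
    thr = {
        "tn10": percentile_thresholds(base_tmin, 10),
        "tx10": percentile_thresholds(base_tmax, 10),
        "tn90": percentile_thresholds(base_tmin, 90),
        "tx90": percentile_thresholds(base_tmax, 90),
    }
    pct = percent_exceedance_indices(
        tmin, tmax, thr["tn10"], thr["tx10"], thr["tn90"], thr["tx90"]
    )
    counts = count_indices(tmin, tmax)
    return ExtremeIndexSet(
        TN10p=pct["TN10p"], TX10p=pct["TX10p"],
        TN90p=pct["TN90p"], TX90p=pct["TX90p"],
        GSL=gsl(tmean), FD0=counts["FD0"], SU25=counts["SU25"],
        WSDI=wsdi(tmax, thr["tx90"]),
    )


# ---------------------------------------------------------------------------
# kernel density
# ---------------------------------------------------------------------------

def pdf_kde(
    series: np.ndarray, bandwidth: float = 1.5,
    grid: np.ndarray | None = None, n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density with a fixed absolute bandwidth.

    Returns (grid, density); the default grid spans the data range padded by
    three bandwidths at 512 nodes, over which the density integrates to 1
    within 1e-3.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty series")
    if grid is None:
        grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, n_grid)
    # mixture of N(x_i, bandwidth^2), evaluated in manageable blocks
    dens = np.zeros_like(grid)
    for block in np.array_split(x, max(1, x.size // 4096)):
        dens += stats.norm.pdf(grid[:, None], block[None, :], bandwidth).sum(axis=1)
    dens /= x.size
    return grid, dens


# ---------------------------------------------------------------------------
# prescribed vs measured
# ---------------------------------------------------------------------------

#: Default tolerated deviations per variable.
DEFAULT_TOLERANCES = {"ta": 1.0, "rh": 10.0, "o3": 10.0, "co2": 20.0, "ppfd": 50.0}


@dataclass
class DeviationStats:
    p99: float
    fraction_within: float
    pearson_r: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_within <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def compare_prescribed_measured(
    prescribed: np.ndarray, measured: np.ndarray, tolerance: float
) -> DeviationStats:
    """p99 of |measured - prescribed|, tolerance fraction, Pearson r, n.

    Pairs with a missing value on either side are dropped (sensor dropouts).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    p = np.asarray(prescribed, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape:
        raise ValueError("prescribed and measured series differ in length")
    ok = ~(np.isnan(p) | np.isnan(m))
    p, m = p[ok], m[ok]
    n = p.size
    if n < 2:
        raise ValueError("need at least two valid pairs")
    d = np.abs(m - p)
    if np.allclose(p, p[0]) or np.allclose(m, m[0]):
        r = 1.0 if np.allclose(m - p, m[0] - p[0]) else np.nan
    else:
        r = float(stats.pearsonr(p, m).statistic)
    return DeviationStats(
        p99=float(np.percentile(d, 99)),
        fraction_within=float(np.mean(d <= tolerance)),
        pearson_r=r,
        n=int(n),
    )


def correlation_matrix(series_by_chamber: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlation of one variable across chambers."""
    df = pd.DataFrame(series_by_chamber)
    return df.corr(method="pearson")
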
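"""Test-reference-year assembly by rank-scored weather-segment resampling.

A reference climatology (365-day means of ta/rh/rg plus the across-year SD
of ta) is built from the station record and optionally shifted by an
additive climate signal.  The year is then tiled greedily from 1 January:
at each position every record year contributes one candidate per admissible
segment length, candidates are rank-scored per criterion (mean ta, SD of
ta, mean rh, mean rg and, after the first segment, continuity of mean ta
with the previous segment), weighted scores are summed and the minimum-score
segment wins.  Hourly data are then copied verbatim from the source years,
segment transitions are linearly interpolated over a +-8 h window (never
radiation), and ozone/CO2 are rescaled to scenario target means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from trygen import station as _station
from trygen.ensemble import ClimateSignal

DAYS = 365
HOURS = 24 * DAYS

#: Criterion weights: the two ta criteria are reweighted 0.3 / 0.7.
DEFAULT_WEIGHTS = {
    "mean_ta": 0.3,
    "sd_ta": 0.7,
    "mean_rh": 1.0,
    "mean_rg": 1.0,
    "continuity": 1.0,
}

#: Scenario ozone rescaling factors applied to the station long-term mean.
O3_FACTORS = {"pc": 1.0, "rcp26": 0.75, "rcp85": 1.115}

#: Scenario CO2 annual-mean targets (ppm).
CO2_TARGETS = {"pc": 375.0, "rcp26": 421.0, "rcp85": 936.0}

MIN_SEG = 10
MAX_SEG = 30


@dataclass
class ReferenceClimatology:
    """365-day target course: means of ta/rh/rg and across-year SD of ta."""

    scenario: str
    ta: np.ndarray
    rh: np.ndarray
    rg: np.ndarray
    ta_sd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ta", "rh", "rg", "ta_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (DAYS,):
                raise ValueError(f"{name} must have {DAYS} values")
            setattr(self, name, arr)
        if (self.ta_sd < 0).any():
            raise ValueError("ta_sd must be non-negative")


@dataclass(frozen=True)
class Segment:
    source_year: int
    start_doy: int  # 1-based day of year
    length_days: int
    total_score: float = 0.0


@dataclass
class SegmentPlan:
    """Gap-free, non-overlapping tiling of days 1..365 by record segments."""

    segments: list[Segment]
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def validate(self) -> None:
        pos = 1
        for i, seg in enumerate(self.segments):
            if seg.start_doy != pos:
                raise ValueError(f"segment {i} starts at {seg.start_doy}, expected {pos}")
            last = i == len(self.segments) - 1
            if not last and not (MIN_SEG <= seg.length_days <= MAX_SEG):
                raise ValueError(f"segment {i} has length {seg.length_days}")
            if last and not (1 <= seg.length_days <= MAX_SEG):
                raise ValueError(f"final segment has length {seg.length_days}")
            pos += seg.length_days
        if pos != DAYS + 1:
            raise ValueError(f"plan tiles {pos - 1} days, expected {DAYS}")

    def to_json(self) -> str:
        return json.dumps(
            {"weights": self.weights, "segments": [asdict(s) for s in self.segments]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SegmentPlan":
        obj = json.loads(text)
        return cls([Segment(**s) for s in obj["segments"]], obj["weights"])


@dataclass
class TestReferenceYear:
    """8,760-hour multivariate annual cycle plus its segment provenance.

    ``data`` has a synthetic hourly index over a nominal non-leap year and
    columns ta, rh, p, rg, o3 (co2 attached by :func:`build_co2_series`).
    ``interpolated`` marks hours rewritten by transition smoothing.
    """

    data: pd.DataFrame
    scenario: str
    plan: SegmentPlan
    interpolated: np.ndarray = field(default_factory=lambda: np.zeros(HOURS, bool))

    def __post_init__(self) -> None:
        if len(self.data) != HOURS:
            raise ValueError(f"TRY must have {HOURS} hours, got {len(self.data)}")

    def segment_ids(self) -> np.ndarray:
        """Per-hour index of the owning segment."""
        out = np.empty(HOURS, dtype=int)
        pos = 0
        for i, seg in enumerate(self.plan.segments):
            n = seg.length_days * 24
            out[pos:pos + n] = i
            pos += n
        return out


# ---------------------------------------------------------------------------
# reference climatology
# ---------------------------------------------------------------------------

def _daily_panel(daily: pd.DataFrame, var: str) -> np.ndarray:
    """Reshape one daily variable to (years, 365); requires complete years."""
    idx = daily.index
    keep = ~((idx.month == 2) & (idx.day == 29))
    d = daily.loc[keep, var]
    years = sorted(set(d.index.year))
    counts = d.groupby(d.index.year).size()
    if (counts != DAYS).any():
        bad = counts.index[counts != DAYS][0]
        raise ValueError(f"year {bad} is incomplete")
    return d.to_numpy().reshape(len(years), DAYS)


def reference_climatology(daily: pd.DataFrame, scenario: str = "pc") -> ReferenceClimatology:
    """Per-day multi-year mean of ta/rh/rg and across-year SD of ta."""
    ta = _daily_panel(daily, "ta")
    if ta.shape[0] < 2:
        raise ValueError("need at least two complete years for the SD of ta")
    return ReferenceClimatology(
        scenario=scenario,
        ta=ta.mean(axis=0),
        rh=_daily_panel(daily, "rh").mean(axis=0),
        rg=_daily_panel(daily, "rg").mean(axis=0),
        ta_sd=ta.std(axis=0, ddof=1),
    )


def apply_signal(rc: ReferenceClimatology, signal: ClimateSignal) -> ReferenceClimatology:
    """Shift ta/rh additively by the climate signal; rh clipped to [0, 100]."""
    return ReferenceClimatology(
        scenario=signal.scenario,
        ta=rc.ta + signal.delta_ta,
        rh=np.clip(rc.rh + signal.delta_rh, 0.0, 100.0),
        rg=rc.rg.copy(),
        ta_sd=rc.ta_sd.copy(),
    )


# ---------------------------------------------------------------------------
# candidate enumeration and rank scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    year: int
    start_doy: int
    length_days: int


def enumerate_candidates(
    record_years: list[int],
    start_doy: int,
    min_len: int = MIN_SEG,
    max_len: int = MAX_SEG,
) -> list[Candidate]:
    """All (year, length) candidates anchored at ``start_doy``.

    Lengths run ``min_len``..``max_len`` but never cross 31 December.  When
    fewer than ``min_len`` days remain, each year contributes exactly one
    tail candidate of the remaining length.
    """
    remaining = DAYS - start_doy + 1
    if remaining <= 0:
        return []
    if remaining < min_len:
        lengths = [remaining]
    else:
        lengths = list(range(min_len, min(max_len, remaining) + 1))
    return [
        Candidate(year, start_doy, length)
        for year in sorted(record_years)
        for length in lengths
    ]


def _competition_ranks(diffs: np.ndarray) -> np.ndarray:
    """Ascending competition ranks starting at 0; ties share the minimum rank."""
    order = np.argsort(diffs, kind="stable")
    ranks = np.empty(len(diffs), dtype=float)
    rank = 0
    for i, j in enumerate(order):
        if i and diffs[j] != diffs[order[i - 1]]:
            rank = i
        ranks[j] = rank
    return ranks


def score_segments(
    candidates: list[Candidate],
    panels: dict[str, np.ndarray],
    years: list[int],
    rc: ReferenceClimatology,
    prev_segment_mean_ta: float | None,
    weights: dict | None = None,
) -> list[tuple[Candidate, float]]:
    """Rank-score candidates against the climatology window they cover.

    ``panels`` holds (years, 365) daily arrays for ta/rh/rg.  Each criterion
    independently ranks |candidate - target| ascending (scores 0, 1, 2, ...;
    ties share the minimum); weighted scores are summed.  The continuity
    criterion (|mean ta - previous segment mean ta|) is skipped when
    ``prev_segment_mean_ta`` is None.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    w = {**DEFAULT_WEIGHTS, **(weights or {})}
    year_pos = {y: i for i, y in enumerate(years)}

    n = len(candidates)
    diffs = {k: np.empty(n) for k in ("mean_ta", "sd_ta", "mean_rh", "mean_rg")}
    mean_ta = np.empty(n)
    for i, c in enumerate(candidates):
        s = slice(c.start_doy - 1, c.start_doy - 1 + c.length_days)
        yi = year_pos[c.year]
        ta = panels["ta"][yi, s]
        mean_ta[i] = ta.mean()
        diffs["mean_ta"][i] = abs(ta.mean() - rc.ta[s].mean())
        cand_sd = ta.std(ddof=1) if c.length_days > 1 else 0.0
        diffs["sd_ta"][i] = abs(cand_sd - rc.ta_sd[s].mean())
        diffs["mean_rh"][i] = abs(panels["rh"][yi, s].mean() - rc.rh[s].mean())
        diffs["mean_rg"][i] = abs(panels["rg"][yi, s].mean() - rc.rg[s].mean())

    total = np.zeros(n)
    for crit, d in diffs.items():
        total += w[crit] * _competition_ranks(d)
    if prev_segment_mean_ta is not None:
        total += w["continuity"] * _competition_ranks(
            np.abs(mean_ta - prev_segment_mean_ta)
        )
    return list(zip(candidates, total))


def select_segments(
    daily: pd.DataFrame,
    rc: ReferenceClimatology,
    weights: dict | None = None,
    min_len: int = MIN_SEG,
    max_len: int = MAX_SEG,
    start_doy: int = 1,
) -> SegmentPlan:
    """Greedy left-to-right minimum-score tiling of the year.

    Ties on total score break by smallest |mean-ta difference|, then earliest
    source year, then shortest length — fully deterministic.
    """
    panels = {v: _daily_panel(daily, v) for v in ("ta", "rh", "rg")}
    years = sorted(set(daily.index[~((daily.index.month == 2)
                                     & (daily.index.day == 29))].year))
    year_pos = {y: i for i, y in enumerate(years)}

    segments: list[Segment] = []
    prev_mean_ta: float | None = None
    pos = start_doy
    while pos <= DAYS:
        cands = enumerate_candidates(years, pos, min_len, max_len)
        scored = score_segments(cands, panels, years, rc, prev_mean_ta, weights)

        def sort_key(item):
            c, score = item
            s = slice(c.start_doy - 1, c.start_doy - 1 + c.length_days)
            mdiff = abs(panels["ta"][year_pos[c.year], s].mean() - rc.ta[s].mean())
            return (score, mdiff, c.year, c.length_days)

        best, best_score = min(scored, key=sort_key)
        s = slice(best.start_doy - 1, best.start_doy - 1 + best.length_days)
        prev_mean_ta = float(panels["ta"][year_pos[best.year], s].mean())
        segments.append(Segment(best.year, best.start_doy, best.length_days,
                                float(best_score)))
        pos += best.length_days
    plan = SegmentPlan(segments, {**DEFAULT_WEIGHTS, **(weights or {})})
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# hourly assembly
# ---------------------------------------------------------------------------

TRY_VARS = ("ta", "rh", "p", "rg", "o3")


def try_index(nominal_year: int = 2015) -> pd.DatetimeIndex:
    """Hourly index over a nominal non-leap year."""
    if pd.Timestamp(year=nominal_year, month=1, day=1).is_leap_year:
        raise ValueError("nominal year must not be a leap year")
    return pd.date_range(f"{nominal_year}-01-01", periods=HOURS, freq="h")


def assemble_hourly(
    record: "_station.HourlyStationRecord",
    plan: SegmentPlan,
    scenario: str = "pc",
    nominal_year: int = 2015,
) -> TestReferenceYear:
    """Copy each segment's hours verbatim from its source year.

    The record must be standard-calendar and gap-filled.
    """
    idx = record.data.index
    # hour-level lookup: (year, standard day-of-year, hour) -> row
    years = idx.year.to_numpy()
    doys = np.asarray(_standard_doy_hourly(idx))
    hours = idx.hour.to_numpy()
    lookup = {}
    for row, key in enumerate(zip(years, doys, hours)):
        lookup[key] = row

    out = {v: np.empty(HOURS) for v in TRY_VARS}
    values = {v: record.data[v].to_numpy(float) for v in TRY_VARS}
    pos = 0
    for seg in plan.segments:
        for d in range(seg.start_doy, seg.start_doy + seg.length_days):
            for h in range(24):
                row = lookup.get((seg.source_year, d, h))
                if row is None:
                    raise ValueError(
                        f"source hour missing: year {seg.source_year} day {d} hour {h}"
                    )
                for v in TRY_VARS:
                    out[v][pos] = values[v][row]
                pos += 1
    data = pd.DataFrame(out, index=try_index(nominal_year))
    return TestReferenceYear(data, scenario, plan)


def _standard_doy_hourly(idx: pd.DatetimeIndex) -> np.ndarray:
    doy = idx.dayofyear.to_numpy().copy()
    leap = idx.is_leap_year & (doy > 59)
    doy[leap] -= 1
    return doy


def smooth_transitions(
    try_: TestReferenceYear,
    window_hours: int = 8,
    variables: tuple[str, ...] = ("ta", "rh", "p", "o3"),
) -> TestReferenceYear:
    """Linearly bridge each internal segment boundary over +-``window_hours``.

    At boundary hour b (first hour of the next segment) the values at hours
    b-w and b+w are kept as anchors and the 2w-1 interior hours are replaced
    by the straight line joining them.  Radiation (and CO2) are never
    touched.  Windows must not overlap.
    """
    if len(try_.plan.segments) < 2:
        return try_
    w = window_hours
    boundaries = []
    pos = 0
    for seg in try_.plan.segments[:-1]:
        pos += seg.length_days * 24
        boundaries.append(pos)
    for b0, b1 in zip(boundaries, boundaries[1:]):
        if b0 + w >= b1 - w:
            raise ValueError("interpolation windows overlap")
    if boundaries[0] - w < 0 or boundaries[-1] + w >= HOURS:
        raise ValueError("interpolation window leaves the year")

    data = try_.data.copy()
    mask = try_.interpolated.copy()
    for b in boundaries:
        lo, hi = b - w, b + w
        frac = np.arange(1, 2 * w) / (2.0 * w)
        for v in variables:
            col = data[v].to_numpy(float)
            col[lo + 1:hi] = col[lo] + (col[hi] - col[lo]) * frac
            data[v] = col
        mask[lo + 1:hi] = True
    return TestReferenceYear(data, try_.scenario, try_.plan, mask)


# ---------------------------------------------------------------------------
# scenario gas scaling
# ---------------------------------------------------------------------------

def adjust_o3_scenario(
    o3_hourly: np.ndarray, longterm_mean: float, scenario_factor: float
) -> np.ndarray:
    """Rescale ozone so its annual mean is ``longterm_mean * scenario_factor``.

    The series is normalized by its own mean (shape preserved) and rescaled;
    the output mean hits the target exactly.
    """
    x = np.asarray(o3_hourly, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("ozone series mean must be positive")
    return x / m * (longterm_mean * scenario_factor)


def build_co2_series(
    co2_record: pd.Series, target_mean: float, nominal_year: int = 2015
) -> pd.Series:
    """Scenario CO2 cycle: mean annual hourly course rescaled to a target mean.

    The multi-year record is averaged per calendar (day-of-year, hour),
    normalized by its overall mean and multiplied by ``target_mean``.
    """
    if len(co2_record) == 0:
        raise ValueError("empty CO2 record")
    idx = co2_record.index
    keep = ~((idx.month == 2) & (idx.day == 29))
    s = co2_record[keep]
    key = _standard_doy_hourly(s.index) * 100 + s.index.hour.to_numpy()
    cycle = s.groupby(key).mean()
    if len(cycle) != HOURS:
        raise ValueError("CO2 record does not cover every calendar hour")
    out = cycle.to_numpy() / cycle.to_numpy().mean() * target_mean
    return pd.Series(out, index=try_index(nominal_year), name="co2")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    scenario: str = "pc"
    o3_factor: float | None = None  # default from O3_FACTORS
    co2_target: float | None = None  # default from CO2_TARGETS
    weights: dict = field(default_factory=dict)
    window_hours: int = 8
    nominal_year: int = 2015


def build_try(
    hourly_record: "_station.HourlyStationRecord",
    co2_record: pd.Series,
    signal: ClimateSignal | None,
    config: ScenarioConfig | None = None,
) -> TestReferenceYear:
    """Full scenario TRY from a gap-filled standard-calendar station record.

    Chains reference climatology, signal shift, segment selection, hourly
    assembly, transition smoothing, ozone rescaling and CO2 attachment.
    """
    cfg = config or ScenarioConfig()
    daily = _station.daily_aggregate(hourly_record)
    rc = reference_climatology(daily, scenario=cfg.scenario)
    if signal is not None:
        rc = apply_signal(rc, signal)
    plan = select_segments(daily, rc, weights=cfg.weights or None)
    try_ = assemble_hourly(hourly_record, plan, cfg.scenario, cfg.nominal_year)
    try_ = smooth_transitions(try_, cfg.window_hours)

    # Ozone rescaling applies to the future scenarios only; the present-climate
    # ozone stays verbatim resampled record data.
    o3_factor = cfg.o3_factor
    if o3_factor is None:
        o3_factor = O3_FACTORS.get(cfg.scenario, 1.0)
    if cfg.scenario != "pc" or cfg.o3_factor is not None:
        longterm_o3 = float(hourly_record.data["o3"].mean())
        try_.data["o3"] = adjust_o3_scenario(
            try_.data["o3"].to_numpy(), longterm_o3, o3_factor
        )

    co2_target = cfg.co2_target
    if co2_target is None:
        co2_target = CO2_TARGETS.get(cfg.scenario, CO2_TARGETS["pc"])
    try_.data["co2"] = build_co2_series(
        co2_record, co2_target, cfg.nominal_year
    ).to_numpy()
    return try_


def try_to_frame(try_: TestReferenceYear) -> pd.DataFrame:
    """CSV-ready table: timestamp, variables, segment id, interpolation flag."""
    df = try_.data.copy()
    df.insert(0, "timestamp", df.index)
    df["segment_id"] = try_.segment_ids()
    df["interpolated_flag"] = try_.interpolated.astype(int)
    return df.reset_index(drop=True)
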
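"""Reference climatologies, segment selection, TRY assembly and gas scaling."""

import numpy as np
import pandas as pd
import pytest

from trygen import builder, station
from trygen.builder import (
    DAYS,
    HOURS,
    Candidate,
    ReferenceClimatology,
    Segment,
    SegmentPlan,
    adjust_o3_scenario,
    apply_signal,
    assemble_hourly,
    build_co2_series,
    build_try,
    enumerate_candidates,
    reference_climatology,
    score_segments,
    select_segments,
    smooth_transitions,
)
from trygen.ensemble import ClimateSignal


def _daily_frame(per_year: dict[int, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Daily record from explicit per-year 365-value arrays."""
    frames = []
    for year, cols in per_year.items():
        idx = pd.date_range(f"{year}-01-01", periods=DAYS, freq="D")
        assert not idx.is_leap_year.any() or len(idx) == DAYS
        frames.append(pd.DataFrame({k: np.asarray(v, float) for k, v in cols.items()},
                                   index=idx))
    return pd.concat(frames)


def _rc(ta, rh=None, rg=None, sd=None):
    return ReferenceClimatology(
        "pc",
        np.asarray(ta, float),
        np.full(DAYS, 70.0) if rh is None else np.asarray(rh, float),
        np.full(DAYS, 200.0) if rg is None else np.asarray(rg, float),
        np.full(DAYS, 1.0) if sd is None else np.asarray(sd, float),
    )


class TestReferenceClimatology:
    def test_identical_years_zero_sd(self):
        vals = {"ta": np.arange(DAYS, dtype=float), "rh": np.full(DAYS, 70.0),
                "rg": np.full(DAYS, 200.0)}
        daily = _daily_frame({2001: vals, 2002: vals})
        rc = reference_climatology(daily)
        np.testing.assert_allclose(rc.ta_sd, 0.0)
        np.testing.assert_allclose(rc.ta, vals["ta"])

    def test_symmetric_years_sd_sqrt2(self):
        base = np.full(DAYS, 10.0)
        daily = _daily_frame({
            2001: {"ta": base - 1, "rh": np.full(DAYS, 70.0), "rg": np.full(DAYS, 200.0)},
            2002: {"ta": base + 1, "rh": np.full(DAYS, 70.0), "rg": np.full(DAYS, 200.0)},
        })
        rc = reference_climatology(daily)
        np.testing.assert_allclose(rc.ta, 10.0)
        # oracle: sample SD of {9, 11} with ddof=1 is sqrt(2)
        np.testing.assert_allclose(rc.ta_sd, np.sqrt(2.0))

    def test_matches_bruteforce_on_fixture(self, small_daily):
        rc = reference_climatology(small_daily)
        d = small_daily[~((small_daily.index.month == 2) & (small_daily.index.day == 29))]
        for doy_i in (0, 100, 364):
            per_year = [
                d[d.index.year == y]["ta"].iloc[doy_i] for y in (2001, 2002, 2003)
            ]
            assert rc.ta[doy_i] == pytest.approx(np.mean(per_year), abs=1e-9)
            assert rc.ta_sd[doy_i] == pytest.approx(np.std(per_year, ddof=1), abs=1e-9)

    def test_single_year_rejected(self):
        daily = _daily_frame({2001: {"ta": np.zeros(DAYS), "rh": np.zeros(DAYS),
                                     "rg": np.zeros(DAYS)}})
        with pytest.raises(ValueError, match="two complete years"):
            reference_climatology(daily)


class TestApplySignal:
    def test_zero_signal_identity(self):
        rc = _rc(np.arange(DAYS, dtype=float))
        out = apply_signal(rc, ClimateSignal.zero())
        np.testing.assert_array_equal(out.ta, rc.ta)
        np.testing.assert_array_equal(out.rh, rc.rh)

    def test_constant_warming(self):
        rc = _rc(np.zeros(DAYS))
        sig = ClimateSignal("rcp85", np.full(DAYS, 3.3), np.zeros(DAYS))
        out = apply_signal(rc, sig)
        np.testing.assert_allclose(out.ta, 3.3)
        np.testing.assert_array_equal(out.rg, rc.rg)
        np.testing.assert_array_equal(out.ta_sd, rc.ta_sd)

    def test_rh_clipped(self):
        rc = _rc(np.zeros(DAYS), rh=np.full(DAYS, 99.0))
        sig = ClimateSignal("rcp26", np.zeros(DAYS), np.full(DAYS, 5.0))
        out = apply_signal(rc, sig)
        np.testing.assert_allclose(out.rh, 100.0)


class TestEnumerateCandidates:
    def test_thirty_years_from_jan1(self):
        cands = enumerate_candidates(list(range(1987, 2017)), 1)
        assert len(cands) == 630

    def test_one_year(self):
        assert len(enumerate_candidates([2001], 1)) == 21

    def test_tail_mode(self):
        # oracle by hand: 6 days remain from day 360, below the minimum length,
        # so each year contributes exactly one 6-day candidate
        cands = enumerate_candidates([2001, 2002], 360)
        assert [c.length_days for c in cands] == [6, 6]

    def test_near_year_end_truncates(self):
        # from day 340 only lengths 10..26 fit before 31 December
        cands = enumerate_candidates([2001], 340)
        assert [c.length_days for c in cands] == list(range(10, 27))


class TestScoreSegments:
    def _setup(self, ta_by_year):
        years = sorted(ta_by_year)
        panels = {
            "ta": np.array([ta_by_year[y] for y in years], dtype=float),
            "rh": np.full((len(years), DAYS), 70.0),
            "rg": np.full((len(years), DAYS), 200.0),
        }
        return panels, years

    def test_single_candidate_scores_zero(self):
        panels, years = self._setup({2001: np.zeros(DAYS)})
        rc = _rc(np.zeros(DAYS))
        scored = score_segments([Candidate(2001, 1, 10)], panels, years, rc, None)
        assert scored[0][1] == 0.0

    def test_exact_match_ranks_zero_everywhere(self):
        ta = np.linspace(0, 10, DAYS)
        panels, years = self._setup({2001: ta, 2002: ta + 5.0})
        rc = _rc(ta, sd=np.zeros(DAYS))
        cands = [Candidate(2001, 1, 10), Candidate(2002, 1, 10)]
        scored = dict(score_segments(cands, panels, years, rc, None))
        assert scored[cands[0]] == 0.0
        assert scored[cands[1]] > 0.0

    def test_hand_ranked_table(self):
        # three flat candidate years with mean ta 10, 11, 13 vs target 10:
        # mean-ta diffs 0, 1, 3 -> ranks 0, 1, 2 (weight 0.3)
        # sd diffs equal -> all rank 0; rh/rg equal -> rank 0
        panels, years = self._setup({
            2001: np.full(DAYS, 10.0),
            2002: np.full(DAYS, 11.0),
            2003: np.full(DAYS, 13.0),
        })
        rc = _rc(np.full(DAYS, 10.0), sd=np.zeros(DAYS))
        cands = [Candidate(y, 1, 10) for y in years]
        scored = dict(score_segments(cands, panels, years, rc, None))
        assert scored[cands[0]] == pytest.approx(0.0)
        assert scored[cands[1]] == pytest.approx(0.3 * 1)
        assert scored[cands[2]] == pytest.approx(0.3 * 2)

    def test_continuity_criterion(self):
        panels, years = self._setup({
            2001: np.full(DAYS, 10.0),
            2002: np.full(DAYS, 20.0),
        })
        rc = _rc(np.full(DAYS, 15.0), sd=np.zeros(DAYS))
        cands = [Candidate(2001, 1, 10), Candidate(2002, 1, 10)]
        # previous segment mean 19: year 2002 wins continuity rank 0
        scored = dict(score_segments(cands, panels, years, rc, 19.0))
        assert scored[cands[1]] < scored[cands[0]]

    def test_empty_rejected(self):
        panels, years = self._setup({2001: np.zeros(DAYS)})
        with pytest.raises(ValueError):
            score_segments([], panels, years, _rc(np.zeros(DAYS)), None)


# ---------------------------------------------------------------------------
# brute-force greedy-selection oracle (independent re-implementation)
# ---------------------------------------------------------------------------

def _oracle_ranks(values):
    return [sum(1 for w in values if w < v) for v in values]


def _oracle_plan(daily, rc, weights):
    d = daily[~((daily.index.month == 2) & (daily.index.day == 29))]
    years = sorted(set(d.index.year))
    by_year = {y: d[d.index.year == y] for y in years}
    segs = []
    pos, prev_mean = 1, None
    while pos <= DAYS:
        remaining = DAYS - pos + 1
        lengths = ([remaining] if remaining < 10
                   else list(range(10, min(30, remaining) + 1)))
        cands = [(y, L) for y in years for L in lengths]
        crit = {}
        for name, weight in (("mean_ta", 0.3), ("sd_ta", 0.7),
                             ("mean_rh", 1.0), ("mean_rg", 1.0)):
            diffs = []
            for y, L in cands:
                rows = by_year[y].iloc[pos - 1: pos - 1 + L]
                if name == "mean_ta":
                    diffs.append(abs(rows["ta"].mean() - rc.ta[pos - 1: pos - 1 + L].mean()))
                elif name == "sd_ta":
                    sd = rows["ta"].std(ddof=1) if L > 1 else 0.0
                    diffs.append(abs(sd - rc.ta_sd[pos - 1: pos - 1 + L].mean()))
                elif name == "mean_rh":
                    diffs.append(abs(rows["rh"].mean() - rc.rh[pos - 1: pos - 1 + L].mean()))
                else:
                    diffs.append(abs(rows["rg"].mean() - rc.rg[pos - 1: pos - 1 + L].mean()))
            crit[name] = (weight, diffs)
        totals = [0.0] * len(cands)
        for weight, diffs in crit.values():
            for i, r in enumerate(_oracle_ranks(diffs)):
                totals[i] += weight * r
        if prev_mean is not None:
            cont = [abs(by_year[y].iloc[pos - 1: pos - 1 + L]["ta"].mean() - prev_mean)
                    for y, L in cands]
            for i, r in enumerate(_oracle_ranks(cont)):
                totals[i] += weights.get("continuity", 1.0) * r
        keyed = []
        for (y, L), tot in zip(cands, totals):
            mdiff = abs(by_year[y].iloc[pos - 1: pos - 1 + L]["ta"].mean()
                        - rc.ta[pos - 1: pos - 1 + L].mean())
            keyed.append((tot, mdiff, y, L))
        tot, _, y, L = min(keyed)
        prev_mean = by_year[y].iloc[pos - 1: pos - 1 + L]["ta"].mean()
        segs.append((y, pos, L))
        pos += L
    return segs


class TestSelectSegments:
    def test_matching_year_always_chosen(self):
        rng = np.random.default_rng(0)
        target_ta = 8.0 + 9.0 * np.cos(2 * np.pi * (np.arange(DAYS) - 196) / DAYS)
        target_rh = np.full(DAYS, 70.0) + rng.normal(0, 2, DAYS)
        target_rg = np.full(DAYS, 200.0) + rng.normal(0, 20, DAYS)
        daily = _daily_frame({
            2001: {"ta": target_ta + 2, "rh": target_rh + 5, "rg": target_rg + 30},
            2002: {"ta": target_ta, "rh": target_rh, "rg": target_rg},
            2003: {"ta": target_ta - 2, "rh": target_rh - 5, "rg": target_rg - 30},
        })
        rc = ReferenceClimatology("pc", target_ta, target_rh, target_rg,
                                  np.full(DAYS, 1.0))
        plan = select_segments(daily, rc,
                               weights={"sd_ta": 0.0, "continuity": 0.0})
        assert all(s.source_year == 2002 for s in plan.segments)

    def test_duplicate_years_tiebreak_earliest(self):
        rng = np.random.default_rng(1)
        cols = {"ta": rng.normal(8, 3, DAYS), "rh": rng.uniform(40, 90, DAYS),
                "rg": rng.uniform(0, 400, DAYS)}
        daily = _daily_frame({2001: cols, 2002: cols})
        rc = _rc(cols["ta"], rh=cols["rh"], rg=cols["rg"], sd=np.full(DAYS, 2.0))
        plan = select_segments(daily, rc)
        assert all(s.source_year == 2001 for s in plan.segments)

    def test_plan_tiles_year(self, small_daily):
        rc = reference_climatology(small_daily)
        plan = select_segments(small_daily, rc)
        plan.validate()
        assert sum(s.length_days for s in plan.segments) == DAYS

    def test_equals_bruteforce_oracle(self, small_daily):
        rc = reference_climatology(small_daily)
        plan = select_segments(small_daily, rc)
        oracle = _oracle_plan(small_daily, rc, {"continuity": 1.0})
        got = [(s.source_year, s.start_doy, s.length_days) for s in plan.segments]
        assert got == oracle


class TestAssembleHourly:
    def test_single_segment_full_year(self, small_record):
        plan = SegmentPlan([Segment(2002, 1, DAYS)])
        try_ = assemble_hourly(small_record, plan)
        src = small_record.data.loc["2002"]
        np.testing.assert_array_equal(try_.data["ta"].to_numpy(),
                                      src["ta"].to_numpy())

    def test_two_segments_copy_verbatim(self, small_record):
        plan = SegmentPlan([Segment(2001, 1, 180), Segment(2003, 181, 185)])
        try_ = assemble_hourly(small_record, plan)
        h = 180 * 24
        np.testing.assert_array_equal(
            try_.data["rh"].to_numpy()[:h],
            small_record.data.loc["2001", "rh"].to_numpy()[:h])
        np.testing.assert_array_equal(
            try_.data["rh"].to_numpy()[h:],
            small_record.data.loc["2003", "rh"].to_numpy()[h:])

    def test_fixture_plan_oracle_lookup(self, small_record, small_daily):
        rc = reference_climatology(small_daily)
        plan = select_segments(small_daily, rc)
        try_ = assemble_hourly(small_record, plan)
        # oracle: independent per-hour lookup via pandas label indexing
        pos = 0
        for seg in plan.segments[:3]:
            day0 = pd.Timestamp(f"{seg.source_year}-01-01") + pd.Timedelta(
                days=seg.start_doy - 1)
            for hr in (0, 5, 23):
                ts = day0 + pd.Timedelta(hours=hr)
                assert try_.data["ta"].iloc[pos + hr] == small_record.data.loc[ts, "ta"]
            pos += seg.length_days * 24

    def test_missing_source_hour_rejected(self, small_record):
        plan = SegmentPlan([Segment(1999, 1, DAYS)])  # year not in record
        with pytest.raises(ValueError, match="missing"):
            assemble_hourly(small_record, plan)


class TestSmoothTransitions:
    def _try(self, values, lengths=(180, 185)):
        plan = SegmentPlan([Segment(2001, 1, lengths[0]),
                            Segment(2002, lengths[0] + 1, lengths[1])])
        data = pd.DataFrame(
            {v: np.asarray(values, float).copy() for v in ("ta", "rh", "p", "rg", "o3")},
            index=builder.try_index())
        return builder.TestReferenceYear(data, "pc", plan)

    def test_equal_anchors_constant(self):
        x = np.full(HOURS, 5.0)
        out = smooth_transitions(self._try(x))
        np.testing.assert_array_equal(out.data["ta"].to_numpy(), x)

    def test_linear_bridge_values(self):
        b = 180 * 24
        x = np.zeros(HOURS)
        x[:b - 8 + 1] = 10.0
        x[b - 8 + 1:] = 26.0
        x[b - 8] = 10.0
        x[b + 8] = 26.0
        out = smooth_transitions(self._try(x))
        got = out.data["ta"].to_numpy()
        for k in range(17):
            assert got[b - 8 + k] == pytest.approx(10.0 + k)

    def test_rg_never_touched(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=HOURS)
        try_ = self._try(x)
        out = smooth_transitions(try_)
        np.testing.assert_array_equal(out.data["rg"].to_numpy(), x)
        assert out.interpolated.sum() == 15

    def test_single_segment_noop(self, small_record):
        plan = SegmentPlan([Segment(2002, 1, DAYS)])
        try_ = assemble_hourly(small_record, plan)
        out = smooth_transitions(try_)
        pd.testing.assert_frame_equal(out.data, try_.data)


class TestAdjustO3:
    def test_identity_case(self):
        x = np.abs(np.random.default_rng(3).normal(30, 5, 100))
        out = adjust_o3_scenario(x, x.mean(), 1.0)
        np.testing.assert_allclose(out, x, rtol=1e-12)

    def test_closed_form_mean(self):
        x = np.random.default_rng(4).uniform(10, 48, 8760)
        out = adjust_o3_scenario(x, 30.0, 0.75)
        assert out.mean() == pytest.approx(22.5, abs=1e-9)

    def test_ratio_constant(self):
        x = np.random.default_rng(5).uniform(5, 60, 1000)
        out = adjust_o3_scenario(x, 30.0, 1.115)
        ratios = out / x
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            adjust_o3_scenario(np.zeros(10), 30.0, 1.0)


class TestBuildCo2:
    def test_constant_record(self):
        idx = pd.date_range("2001-01-01", "2002-12-31 23:00", freq="h")
        rec = pd.Series(400.0, index=idx)
        out = build_co2_series(rec, 936.0)
        np.testing.assert_allclose(out.to_numpy(), 936.0)

    def test_target_mean_exact(self, co2_record_30y):
        out = build_co2_series(co2_record_30y, 375.0)
        assert out.mean() == pytest.approx(375.0, abs=1e-9)
        assert len(out) == HOURS

    def test_shape_proportional_across_targets(self, co2_record_30y):
        a = build_co2_series(co2_record_30y, 375.0).to_numpy() / 375.0
        b = build_co2_series(co2_record_30y, 936.0).to_numpy() / 936.0
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_co2_series(pd.Series([], dtype=float), 375.0)


class TestBuildTry:
    def test_pc_annual_means_near_record(self, pc_try, std_record):
        daily = station.daily_aggregate(std_record)
        for var in ("ta", "rh", "rg"):
            annual = daily[var].groupby(daily.index.year).mean()
            sd = annual.std(ddof=1)
            assert abs(pc_try.data[var].mean() - annual.mean()) < 1.5 * sd

    def test_delta_change_property(self, std_record, co2_record_30y, pc_try):
        # humidity signal consistent with the fixture's ta-rh coupling slope,
        # as a real ensemble delta would be
        sig = ClimateSignal("rcp85", np.full(DAYS, 3.3), np.full(DAYS, -1.2 * 3.3))
        fc = build_try(std_record, co2_record_30y, sig,
                       builder.ScenarioConfig(scenario="rcp85"))
        shift = fc.data["ta"].mean() - pc_try.data["ta"].mean()
        assert shift == pytest.approx(3.3, abs=0.5)

    def test_provenance_years_in_record(self, pc_try):
        years = set(range(1987, 2017))
        assert all(s.source_year in years for s in pc_try.plan.segments)

    def test_determinism(self, std_record, co2_record_30y, pc_try):
        again = build_try(std_record, co2_record_30y, None,
                          builder.ScenarioConfig(scenario="pc"))
        pd.testing.assert_frame_equal(again.data, pc_try.data)

    def test_range_containment(self, pc_try, std_record):
        for var in ("ta", "rh", "p", "o3"):
            lo = std_record.data[var].min()
            hi = std_record.data[var].max()
            assert pc_try.data[var].min() >= lo - 1e-9
            assert pc_try.data[var].max() <= hi + 1e-9

    def test_verbatim_outside_windows(self, pc_try, std_record):
        # non-interpolated hours must exist verbatim in the record
        sample = pc_try.data.loc[~pc_try.interpolated].sample(20, random_state=0)
        pool = set(np.round(std_record.data["ta"].to_numpy(), 9))
        assert all(round(v, 9) in pool for v in sample["ta"])
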
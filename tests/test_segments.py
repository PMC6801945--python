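"""Segmentation of minute records: cut-points, windows, compliance, weekly sums."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from yapcal.errors import DataError
from yapcal.segments import (
    ComplianceRule,
    SegmentWindow,
    build_windows,
    classify_epoch,
    filter_compliance,
    segment_weekly,
    summarize_day,
    summarize_windows,
    weekly_estimates,
)
from yapcal.types import ScheduleDay

from conftest import MONDAY, make_week


@pytest.mark.parametrize(
    "met,expected",
    [
        (4.0, "MVPA"),  # inclusive boundary
        (2.0, "SB"),  # inclusive boundary
        (3.0, "LIGHT"),
        (0.0, "SB"),
        (11.5, "MVPA"),
        (2.0001, "LIGHT"),
    ],
)
def test_classify_epoch_cutpoints(met, expected):
    assert classify_epoch(met) == expected


@pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
def test_classify_epoch_rejects_bad_met(bad):
    with pytest.raises(DataError):
        classify_epoch(bad)


class TestBuildWindows:
    def test_window_anchoring_and_durations(self, week_schedule):
        windows = build_windows(week_schedule)
        by = {(w.segment, w.date): w for w in windows}
        mon = MONDAY
        # travel ends at school start; before-travel is the hour before travel
        assert (by[("travel_to_school", mon)].start, by[("travel_to_school", mon)].end) == (510, 540)
        assert (by[("before_travel", mon)].start, by[("before_travel", mon)].end) == (450, 510)
        assert by[("evening", mon)].duration_min == 240
        assert by[("saturday", mon + dt.timedelta(days=5))].duration_min == 900
        assert by[("sunday", mon + dt.timedelta(days=6))].duration_min == 900
        # travel-from-school follows school end; after-school runs to 18:00
        assert (by[("travel_from_school", mon)].start, by[("travel_from_school", mon)].end) == (930, 960)
        assert (by[("after_school", mon)].start, by[("after_school", mon)].end) == (960, 1080)

    def test_pe_only_on_scheduled_days(self, week_schedule):
        windows = build_windows(week_schedule)
        pe_dates = {w.date for w in windows if w.segment == "pe"}
        assert pe_dates == {MONDAY + dt.timedelta(days=1), MONDAY + dt.timedelta(days=3)}

    def test_late_school_end_omits_after_school(self, caplog):
        sched = make_week(end=1075)  # travel ends 18:25 -> empty after-school
        with caplog.at_level("WARNING"):
            windows = build_windows(sched)
        assert not any(w.segment == "after_school" for w in windows)
        assert "after-school" in caplog.text


def _minute_frame(pid, date, minutes, mets, worn=True):
    n = len(minutes)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "date": date,
            "minute_of_day": minutes,
            "met": mets,
            "on_body": [worn] * n if isinstance(worn, bool) else worn,
        }
    )


class TestSummarizeDay:
    def test_counts_mvpa_in_fully_worn_window(self):
        window = SegmentWindow("evening", MONDAY, 1080, 1320)
        mets = [5.0] * 60 + [3.0] * 180
        rec = _minute_frame("p1", MONDAY, range(1080, 1320), mets)
        s = summarize_day(rec, window)
        assert (s.duration_min, s.wear_min, s.mvpa_min, s.sb_min) == (240, 240, 60, 0)

    def test_no_records_means_zero_wear(self):
        window = SegmentWindow("evening", MONDAY, 1080, 1320)
        s = summarize_day(_minute_frame("p1", MONDAY, [], []), window)
        assert (s.wear_min, s.mvpa_min, s.sb_min) == (0, 0, 0)

    def test_partial_wear_hits_seventy_percent_boundary(self):
        window = SegmentWindow("break", MONDAY, 640, 660)
        worn = [True] * 14 + [False] * 6
        rec = _minute_frame("p1", MONDAY, range(640, 660), [1.5] * 20, worn)
        s = summarize_day(rec, window)
        assert s.wear_min / s.duration_min == pytest.approx(0.70)

    def test_duplicate_minute_raises(self):
        window = SegmentWindow("break", MONDAY, 640, 660)
        rec = _minute_frame("p1", MONDAY, [641, 641], [1.0, 2.0])
        with pytest.raises(DataError, match="duplicate"):
            summarize_day(rec, window)


def test_brute_force_recount_matches_vectorised_summaries(week_schedule):
    """Minute-by-minute recount reproduces every day summary exactly."""
    rng = np.random.default_rng(42)
    windows = build_windows(week_schedule)
    dates = sorted({w.date for w in windows})
    rows = []
    for pid in ("pA", "pB"):
        for date in dates[:2]:  # ~2,000 minutes per participant
            keep = rng.random(1440) < 0.6
            minutes = np.arange(1440)[keep]
            rows.append(
                _minute_frame(
                    pid, date, minutes,
                    rng.uniform(0.9, 9.0, size=len(minutes)),
                    list(rng.random(len(minutes)) > 0.1),
                )
            )
    frame = pd.concat(rows, ignore_index=True)
    result = summarize_windows(frame, windows, participants=["pA", "pB"])

    lookup = {
        (r["participant_id"], r["date"], r["minute_of_day"]): (r["met"], r["on_body"])
        for _, r in frame.iterrows()
    }
    for _, row in result.iterrows():
        wear = mvpa = sb = dur = 0
        for w in windows:
            if w.segment != row["segment"] or w.date != row["date"]:
                continue
            dur += w.duration_min
            for m in range(w.start, w.end):
                rec = lookup.get((row["participant_id"], w.date, m))
                if rec is None or not rec[1]:
                    continue
                wear += 1
                mvpa += rec[0] >= 4.0
                sb += rec[0] <= 2.0
        assert (row["duration_min"], row["wear_min"], row["mvpa_min"], row["sb_min"]) == (
            dur, wear, mvpa, sb,
        )


def test_window_mvpa_conserved_below_daily_total(week_schedule):
    rng = np.random.default_rng(7)
    windows = [w for w in build_windows(week_schedule) if w.date == MONDAY]
    frame = _minute_frame(
        "p1", MONDAY, range(1440), rng.uniform(0, 9, 1440), list(rng.random(1440) > 0.2)
    )
    res = summarize_windows(frame, windows, participants=["p1"])
    total_worn_mvpa = int(
        ((frame["met"] >= 4.0) & frame["on_body"]).sum()
    )
    assert res["mvpa_min"].sum() <= total_worn_mvpa


def _summary_rows(pid, segment, wear_by_date, duration=20, mvpa=0, sb=0):
    rows = []
    for date, wear in wear_by_date.items():
        rows.append(
            {
                "participant_id": pid, "segment": segment, "date": date,
                "duration_min": duration, "wear_min": wear,
                "mvpa_min": min(mvpa, wear), "sb_min": min(sb, wear),
            }
        )
    return rows


class TestCompliance:
    dates = [MONDAY + dt.timedelta(days=i) for i in range(5)]

    def _frame(self, wears, segment="break"):
        return pd.DataFrame(
            _summary_rows("p1", segment, dict(zip(self.dates, wears)))
        )

    def test_three_valid_days_retained(self):
        out = filter_compliance(self._frame([20, 0, 20, 20, 0]), ComplianceRule())
        assert out["retained"].all()

    def test_two_valid_days_dropped(self):
        out = filter_compliance(self._frame([20, 0, 20, 0, 0]), ComplianceRule())
        assert not out["retained"].any()

    def test_pe_needs_only_one_day(self):
        out = filter_compliance(self._frame([20, 0, 0, 0, 0], segment="pe"), ComplianceRule())
        assert out["retained"].all()

    def test_seventy_percent_day_boundary_is_inclusive(self):
        out = filter_compliance(self._frame([14, 14, 14, 0, 0]), ComplianceRule())
        assert out["retained"].all()

    def test_filtering_is_monotone_in_rule(self):
        """Tightening wear fraction or day minimum never grows the retained set."""
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            [
                row
                for pid in range(8)
                for row in _summary_rows(
                    f"p{pid}", "break",
                    dict(zip(self.dates, rng.integers(0, 21, size=5))),
                )
            ]
        )
        retained = {}
        fracs = [0.5, 0.7, 0.9]
        days = [1, 2, 3, 4]
        for f, d in itertools.product(fracs, days):
            out = filter_compliance(frame, ComplianceRule(f, d, 1))
            retained[(f, d)] = set(
                out[out["retained"]].apply(lambda r: (r["participant_id"], r["segment"]), axis=1)
            )
        for f1, f2 in zip(fracs, fracs[1:]):
            for d in days:
                assert retained[(f2, d)] <= retained[(f1, d)]
        for d1, d2 in zip(days, days[1:]):
            for f in fracs:
                assert retained[(f, d2)] <= retained[(f, d1)]


class TestWeeklyEstimates:
    def test_break_mean_times_five_scheduled_days(self, week_schedule):
        windows = build_windows(week_schedule)
        dates = [MONDAY + dt.timedelta(days=i) for i in range(5)]
        rows = []
        for date, (wear, mvpa) in zip(dates, [(20, 8), (0, 0), (20, 10), (20, 12), (0, 0)]):
            rows += _summary_rows("p1", "break", {date: wear}, mvpa=mvpa)
        filtered = filter_compliance(pd.DataFrame(rows), ComplianceRule())
        weekly = segment_weekly(filtered, windows)
        row = weekly[weekly["segment"] == "break"].iloc[0]
        assert row["weekly_mvpa_min"] == pytest.approx(50.0)  # mean 10 x 5 days

    def test_weekend_group_pools_both_days(self):
        sat, sun = MONDAY + dt.timedelta(days=5), MONDAY + dt.timedelta(days=6)
        schedule = [ScheduleDay(sat), ScheduleDay(sun)]
        windows = build_windows(schedule)
        rows = _summary_rows("p1", "saturday", {sat: 900}, duration=900, mvpa=30)
        rows += _summary_rows("p1", "sunday", {sun: 900}, duration=900, mvpa=50)
        filtered = filter_compliance(pd.DataFrame(rows), ComplianceRule())
        est = weekly_estimates(filtered, windows)
        week = est[est["group"] == "weekend"].iloc[0]
        assert week["weekly_minutes"] == pytest.approx(80.0)
        assert week["percent_time"] == pytest.approx(100 * 80 / 1800)

    def test_failing_lunch_invalidates_in_school_group(self, week_schedule):
        windows = build_windows(week_schedule)
        dates = [MONDAY + dt.timedelta(days=i) for i in range(5)]
        rows = []
        for seg in ("before_travel", "travel_to_school", "break", "lunch"):
            dur = {"before_travel": 60, "travel_to_school": 30, "break": 20, "lunch": 50}[seg]
            wear = 0 if seg == "lunch" else dur
            for date in dates:
                rows += _summary_rows("p1", seg, {date: wear}, duration=dur, mvpa=min(wear, 5))
        for date in (dates[1], dates[3]):
            rows += _summary_rows("p1", "pe", {date: 60}, duration=60, mvpa=20)
        filtered = filter_compliance(pd.DataFrame(rows), ComplianceRule())
        est = weekly_estimates(filtered, windows)
        row = est[est["group"] == "in_school"].iloc[0]
        assert not row["valid"]
        assert np.isnan(row["percent_time"])
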
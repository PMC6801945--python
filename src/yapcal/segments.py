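"""Segmentation of minute-level wearable MET records into schedule windows.

Converts a week of 60-second epochs into per-segment, per-day MVPA and
sedentary (SB) minutes, applies wear-time compliance, and aggregates to the
weekly segment-group estimates that are temporally matched to the
questionnaire recall frame.

Epoch intensity classification uses the conventional MET cut-points:
MVPA at >= 4.0 METs, SB at <= 2.0 METs, light in between.  Wear compliance
requires the device worn for >= 70% of a segment's duration on at least
three days (one day for PE and weekend segments).
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .types import GROUP_SEGMENTS, SEGMENTS, Group, ScheduleDay

logger = logging.getLogger(__name__)

MVPA_MET_CUTPOINT = 4.0
SB_MET_CUTPOINT = 2.0

EVENING_START = 18 * 60  # 18:00
EVENING_END = 22 * 60  # 22:00
WEEKEND_START = 7 * 60  # 07:00
WEEKEND_END = 22 * 60  # 22:00
TRAVEL_MIN = 30
BEFORE_TRAVEL_MIN = 60

#: Segments that only need one valid day instead of three.
RELAXED_DAY_SEGMENTS = frozenset({"pe", "saturday", "sunday"})

MINUTE_COLUMNS = ("participant_id", "date", "minute_of_day", "met", "on_body")


@dataclass(frozen=True)
class SegmentWindow:
    """A half-open [start, end) clock window of one segment on one day."""

    segment: str
    date: _dt.date
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.segment} on {self.date}: start >= end")

    @property
    def duration_min(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ComplianceRule:
    """Wear-time requirements for a segment-day to count and a segment to be kept."""

    wear_fraction_min: float = 0.70
    min_valid_days: int = 3
    min_valid_days_pe_weekend: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.wear_fraction_min <= 1:
            raise ValueError("wear_fraction_min must lie in (0, 1]")
        if self.min_valid_days < 1 or self.min_valid_days_pe_weekend < 1:
            raise ValueError("minimum valid day counts must be >= 1")

    def required_days(self, segment: str) -> int:
        if segment in RELAXED_DAY_SEGMENTS:
            return self.min_valid_days_pe_weekend
        return self.min_valid_days


@dataclass(frozen=True)
class SegmentDaySummary:
    """Worn, MVPA and SB minutes of one participant in one segment window."""

    participant_id: str
    segment: str
    date: _dt.date
    duration_min: int
    wear_min: int
    mvpa_min: int
    sb_min: int


def classify_epoch(
    met: float,
    mvpa_cutpoint: float = MVPA_MET_CUTPOINT,
    sb_cutpoint: float = SB_MET_CUTPOINT,
) -> str:
    """Classify one epoch's MET value as ``"MVPA"``, ``"SB"`` or ``"LIGHT"``.

    Both cut-points are inclusive: 4.0 METs is MVPA, 2.0 METs is SB.
    """
    if not math.isfinite(met) or met < 0:
        raise DataError(f"MET value must be finite and non-negative, got {met!r}")
    if met >= mvpa_cutpoint:
        return "MVPA"
    if met <= sb_cutpoint:
        return "SB"
    return "LIGHT"


def build_windows(schedule: list[ScheduleDay]) -> list[SegmentWindow]:
    """Derive the ten segment windows for each day of a school's week.

    School days emit: before-travel (the 60 min ending at travel start),
    travel-to-school (the 30 min ending at school start), break / PE / lunch
    when the timetable provides them, travel-from-school (30 min after the
    school end), after-school (travel end to 18:00) and evening (18:00-22:00).
    Weekend days emit a single 07:00-22:00 window named for the day.  An
    after-school window made empty by a late school end is omitted with a
    logged warning.
    """
    windows: list[SegmentWindow] = []
    for day in schedule:
        if day.is_school_day:
            start, end = day.school_start, day.school_end
            assert start is not None and end is not None
            windows.append(
                SegmentWindow("before_travel", day.date, start - TRAVEL_MIN - BEFORE_TRAVEL_MIN, start - TRAVEL_MIN)
            )
            windows.append(SegmentWindow("travel_to_school", day.date, start - TRAVEL_MIN, start))
            if day.break_window:
                windows.append(SegmentWindow("break", day.date, *day.break_window))
            for pe in day.pe_windows:
                windows.append(SegmentWindow("pe", day.date, *pe))
            if day.lunch_window:
                windows.append(SegmentWindow("lunch", day.date, *day.lunch_window))
            windows.append(SegmentWindow("travel_from_school", day.date, end, end + TRAVEL_MIN))
            after_start = end + TRAVEL_MIN
            if after_start < EVENING_START:
                windows.append(SegmentWindow("after_school", day.date, after_start, EVENING_START))
            else:
                logger.warning(
                    "after-school window empty on %s (school ends %d); omitted", day.date, end
                )
            windows.append(SegmentWindow("evening", day.date, EVENING_START, EVENING_END))
        else:
            name = "saturday" if day.date.weekday() == 5 else "sunday"
            windows.append(SegmentWindow(name, day.date, WEEKEND_START, WEEKEND_END))
    return windows


def summarize_day(records: pd.DataFrame, window: SegmentWindow) -> SegmentDaySummary:
    """Count worn, MVPA and SB minutes of one participant inside one window.

    ``records`` is a minute-level frame (columns ``participant_id``, ``date``,
    ``minute_of_day``, ``met``, ``on_body``) for a single participant.
    Minutes absent from the record are treated as off-body; MVPA/SB are
    counted over worn minutes only.
    """
    pids = records["participant_id"].unique() if len(records) else []
    if len(pids) > 1:
        raise DataError(f"records span several participants: {sorted(pids)}")
    day = records[records["date"] == window.date] if len(records) else records
    if len(day) and day["minute_of_day"].duplicated().any():
        dup = day.loc[day["minute_of_day"].duplicated(), "minute_of_day"].iloc[0]
        raise DataError(f"duplicate minute record at {window.date} minute {dup}")
    mask = (day["minute_of_day"] >= window.start) & (day["minute_of_day"] < window.end) if len(day) else []
    inside = day[mask] if len(day) else day
    if len(inside):
        met = inside["met"].to_numpy(dtype=float)
        if not np.all(np.isfinite(met)) or (met < 0).any():
            raise DataError("non-finite or negative MET value inside window")
        worn = inside["on_body"].to_numpy(dtype=bool)
        wear = int(worn.sum())
        mvpa = int((worn & (met >= MVPA_MET_CUTPOINT)).sum())
        sb = int((worn & (met <= SB_MET_CUTPOINT)).sum())
    else:
        wear = mvpa = sb = 0
    pid = str(pids[0]) if len(pids) else ""
    return SegmentDaySummary(pid, window.segment, window.date, window.duration_min, wear, mvpa, sb)


def summarize_windows(
    minutes: pd.DataFrame,
    windows: list[SegmentWindow],
    participants: list[str] | None = None,
) -> pd.DataFrame:
    """Vectorised day summaries for every participant x segment x day.

    Returns one row per (participant_id, segment, date) with columns
    ``duration_min``, ``wear_min``, ``mvpa_min``, ``sb_min``.  Windows of the
    same segment on the same day (several PE lessons) are pooled.  Every
    scheduled window yields a row even when no minutes fall inside it.
    """
    for col in MINUTE_COLUMNS:
        if col not in minutes.columns:
            raise DataError(f"minute table missing column {col!r}")
    if participants is None:
        participants = sorted(minutes["participant_id"].astype(str).unique())
    if minutes.duplicated(["participant_id", "date", "minute_of_day"]).any():
        raise DataError("duplicate (participant, date, minute) records")
    met = minutes["met"].to_numpy(dtype=float)
    if len(met) and (not np.all(np.isfinite(met)) or (met < 0).any()):
        raise DataError("non-finite or negative MET values in minute table")

    seg_index = {s: i for i, s in enumerate(SEGMENTS)}
    # minute-of-day -> segment id lookup per date
    daymaps: dict[_dt.date, np.ndarray] = {}
    durations: dict[tuple[str, _dt.date], int] = {}
    for w in windows:
        dm = daymaps.setdefault(w.date, np.full(1440, -1, dtype=np.int8))
        if (dm[w.start : w.end] != -1).any():
            raise DataError(f"overlapping windows on {w.date} at segment {w.segment}")
        dm[w.start : w.end] = seg_index[w.segment]
        key = (w.segment, w.date)
        durations[key] = durations.get(key, 0) + w.duration_min

    frames = []
    for date, dm in daymaps.items():
        sub = minutes[minutes["date"] == date]
        if not len(sub):
            continue
        mod = sub["minute_of_day"].to_numpy(dtype=int)
        seg_ids = dm[mod]
        inside = seg_ids >= 0
        if not inside.any():
            continue
        sub = sub[inside]
        met_v = sub["met"].to_numpy(dtype=float)
        worn = sub["on_body"].to_numpy(dtype=bool)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": sub["participant_id"].astype(str).to_numpy(),
                    "segment": np.array(SEGMENTS, dtype=object)[seg_ids[inside]],
                    "date": date,
                    "wear_min": worn.astype(int),
                    "mvpa_min": (worn & (met_v >= MVPA_MET_CUTPOINT)).astype(int),
                    "sb_min": (worn & (met_v <= SB_MET_CUTPOINT)).astype(int),
                }
            )
        )
    if frames:
        counts = (
            pd.concat(frames)
            .groupby(["participant_id", "segment", "date"], as_index=False)[
                ["wear_min", "mvpa_min", "sb_min"]
            ]
            .sum()
        )
    else:
        counts = pd.DataFrame(
            columns=["participant_id", "segment", "date", "wear_min", "mvpa_min", "sb_min"]
        )

    grid = pd.DataFrame(
        [
            {"participant_id": pid, "segment": seg, "date": date, "duration_min": dur}
            for pid in participants
            for (seg, date), dur in durations.items()
        ]
    )
    out = grid.merge(counts, on=["participant_id", "segment", "date"], how="left")
    for col in ("wear_min", "mvpa_min", "sb_min"):
        out[col] = out[col].fillna(0).astype(int)
    return out


def filter_compliance(summaries: pd.DataFrame, rule: ComplianceRule) -> pd.DataFrame:
    """Apply the wear-compliance rule to segment-day summaries.

    Adds ``day_valid`` (wear fraction >= threshold for that day) and
    ``retained`` (the participant x segment has enough valid days) columns.
    """
    out = summaries.copy()
    out["day_valid"] = out["wear_min"] / out["duration_min"] >= rule.wear_fraction_min
    valid_days = out.groupby(["participant_id", "segment"])["day_valid"].transform("sum")
    required = out["segment"].map(rule.required_days)
    out["retained"] = valid_days >= required
    return out


def segment_weekly(filtered: pd.DataFrame, windows: list[SegmentWindow]) -> pd.DataFrame:
    """Weekly per-segment minutes: mean over valid days x scheduled occurrences.

    Only retained (participant, segment) pairs appear.  ``weekly_duration_min``
    is the total scheduled duration across the week, valid or not.
    """
    occ: dict[str, set] = {}
    sched_dur: dict[str, int] = {}
    for w in windows:
        occ.setdefault(w.segment, set()).add(w.date)
        sched_dur[w.segment] = sched_dur.get(w.segment, 0) + w.duration_min

    valid = filtered[filtered["retained"] & filtered["day_valid"]]
    weekly = (
        valid.groupby(["participant_id", "segment"], as_index=False)[["mvpa_min", "sb_min"]]
        .mean()
        .rename(columns={"mvpa_min": "mvpa_daily_mean", "sb_min": "sb_daily_mean"})
    )
    weekly["occurrences"] = weekly["segment"].map(lambda s: len(occ[s]))
    weekly["weekly_mvpa_min"] = weekly["mvpa_daily_mean"] * weekly["occurrences"]
    weekly["weekly_sb_min"] = weekly["sb_daily_mean"] * weekly["occurrences"]
    weekly["weekly_duration_min"] = weekly["segment"].map(sched_dur)
    return weekly


def weekly_estimates(
    filtered: pd.DataFrame,
    windows: list[SegmentWindow],
) -> pd.DataFrame:
    """Aggregate compliant segment-days to weekly segment-group estimates.

    Returns one row per (participant_id, group) with ``weekly_minutes``
    (MVPA minutes, or SB minutes for the sedentary group),
    ``weekly_duration_min``, ``percent_time`` and ``valid``.  A group is
    valid only when every member segment scheduled that week was retained
    for the participant.
    """
    scheduled = {w.segment for w in windows}
    seg_weekly = segment_weekly(filtered, windows)
    participants = sorted(filtered["participant_id"].unique())
    seg_map = {
        (row.participant_id, row.segment): row for row in seg_weekly.itertuples(index=False)
    }
    rows = []
    for pid in participants:
        for group in Group:
            members = [s for s in GROUP_SEGMENTS[group] if s in scheduled]
            use_sb = group is Group.SB_OUT_OF_SCHOOL
            have = [seg_map.get((pid, s)) for s in members]
            valid = bool(members) and all(r is not None for r in have)
            duration = sum(
                sum(w.duration_min for w in windows if w.segment == s) for s in members
            )
            if valid and duration > 0:
                minutes = sum(
                    (r.weekly_sb_min if use_sb else r.weekly_mvpa_min) for r in have
                )
                percent = 100.0 * minutes / duration
            else:
                minutes, percent, valid = np.nan, np.nan, False
            rows.append(
                {
                    "participant_id": pid,
                    "group": group.value,
                    "weekly_minutes": minutes,
                    "weekly_duration_min": duration,
                    "percent_time": percent,
                    "valid": valid,
                }
            )
    return pd.DataFrame(rows)


def device_weekly_estimates(
    minutes: pd.DataFrame,
    schedule: list[ScheduleDay],
    rule: ComplianceRule | None = None,
    participants: list[str] | None = None,
) -> pd.DataFrame:
    """Convenience end-to-end path: minutes + schedule -> weekly group table."""
    rule = rule or ComplianceRule()
    windows = build_windows(schedule)
    summaries = summarize_windows(minutes, windows, participants=participants)
    filtered = filter_compliance(summaries, rule)
    return weekly_estimates(filtered, windows)
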
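"""Validation and scoring of the 15-item activity-recall questionnaire.

Items are Likert scores in {1..5}; items 3-5 (break, PE, lunch) may also be
0, meaning the opportunity did not occur during the recall week.  Items
aggregate into four composite scores — in-school (1-5), out-of-school (6-8),
weekend (9-10) and sedentary (11-15) — that are the calibration predictors.
A 0-scored item is dropped from both the composite mean and the matched
weekly duration: an opportunity that never occurred contributes neither
score nor time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .segments import build_windows
from .types import (
    GROUP_ITEMS,
    SEGMENTS,
    ZERO_ALLOWED_SEGMENTS,
    Group,
    ScheduleDay,
)

ITEM_COLUMNS = tuple(f"q{i}" for i in range(1, 16))

#: Items whose value 0 is legal ("did not occur"): break, PE, lunch.
ZERO_ALLOWED_ITEMS = frozenset(
    i + 1 for i, seg in enumerate(SEGMENTS) if seg in ZERO_ALLOWED_SEGMENTS
)


def validate_responses(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen raw responses; return (retained, exclusions-with-reasons).

    A response is excluded when any item is missing, non-integer, outside
    {1..5}, or 0 on an item where 0 is not allowed.  Exclusion never raises:
    incomplete questionnaires are an expected field outcome.
    """
    missing_cols = [c for c in ("participant_id", *ITEM_COLUMNS) if c not in raw.columns]
    if missing_cols:
        raise InputError(f"response table missing columns: {missing_cols}")
    reasons: list[tuple[str, str]] = []
    keep_mask = np.ones(len(raw), dtype=bool)
    for pos, (_, row) in enumerate(raw.iterrows()):
        pid = str(row["participant_id"])
        for i, col in enumerate(ITEM_COLUMNS, start=1):
            val = row[col]
            if pd.isna(val):
                reasons.append((pid, "incomplete"))
                keep_mask[pos] = False
                break
            val = float(val)
            if not val.is_integer() or not (
                val in (1, 2, 3, 4, 5) or (val == 0 and i in ZERO_ALLOWED_ITEMS)
            ):
                reasons.append((pid, "invalid value"))
                keep_mask[pos] = False
                break
    retained = raw[keep_mask].copy()
    retained[list(ITEM_COLUMNS)] = retained[list(ITEM_COLUMNS)].astype(int)
    exclusions = pd.DataFrame(reasons, columns=["participant_id", "reason"])
    return retained, exclusions


def composite_scores(responses: pd.DataFrame) -> pd.DataFrame:
    """Group composite scores: mean of member items, 0-items excluded.

    Returns rows (participant_id, group, score, defined); ``defined`` is
    False when every member item is 0 (the composite is then undefined and
    the score is NaN).
    """
    rows = []
    for _, row in responses.iterrows():
        pid = str(row["participant_id"])
        for group in Group:
            vals = np.array([int(row[f"q{i}"]) for i in GROUP_ITEMS[group]])
            nonzero = vals[vals > 0]
            if len(nonzero):
                rows.append({"participant_id": pid, "group": group.value,
                             "score": float(nonzero.mean()), "defined": True})
            else:
                rows.append({"participant_id": pid, "group": group.value,
                             "score": np.nan, "defined": False})
    return pd.DataFrame(rows)


def group_weekly_duration(
    schedule: list[ScheduleDay], response: pd.Series
) -> dict[Group, float]:
    """Scheduled weekly minutes per group, honouring 0-scored items.

    Segment duration = daily window duration summed over scheduled
    occurrences (from the school timetable).  A segment whose item is 0
    contributes 0 minutes.  The sedentary group reuses the weekday
    out-of-school windows (its items carry no clock windows of their own).
    """
    windows = build_windows(schedule)
    seg_dur: dict[str, int] = {}
    for w in windows:
        seg_dur[w.segment] = seg_dur.get(w.segment, 0) + w.duration_min

    durations: dict[Group, float] = {}
    for group in Group:
        if group is Group.SB_OUT_OF_SCHOOL:
            members = [(None, s) for s in ("travel_from_school", "after_school", "evening")]
        else:
            members = [(i, SEGMENTS[i - 1]) for i in GROUP_ITEMS[group]]
        total = 0.0
        for item, seg in members:
            if seg not in seg_dur:
                if item is not None and int(response[f"q{item}"]) != 0:
                    raise InputError(
                        f"item q{item} answered but segment {seg!r} absent from schedule"
                    )
                continue
            if item is not None and int(response[f"q{item}"]) == 0:
                continue
            total += seg_dur[seg]
        durations[group] = total
    return durations


def score_responses(
    raw: pd.DataFrame, schedules: dict[str, list[ScheduleDay]], roster: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch path: validate, score, and attach per-group weekly durations.

    ``schedules`` maps school_id -> week schedule; ``roster`` links
    participants to schools.  Returns (scores table with columns
    participant_id, group, score, defined, weekly_duration_min; exclusions).
    """
    retained, exclusions = validate_responses(raw)
    school_of = dict(zip(roster["participant_id"].astype(str), roster["school_id"].astype(str)))
    scores = composite_scores(retained)
    durs = []
    for _, row in retained.iterrows():
        pid = str(row["participant_id"])
        if pid not in school_of:
            raise InputError(f"participant {pid} missing from roster")
        gd = group_weekly_duration(schedules[school_of[pid]], row)
        for group, dur in gd.items():
            durs.append({"participant_id": pid, "group": group.value,
                         "weekly_duration_min": dur})
    dur_df = pd.DataFrame(durs)
    if len(dur_df):
        scores = scores.merge(dur_df, on=["participant_id", "group"], how="left")
    else:
        scores["weekly_duration_min"] = np.nan
    return scores, exclusions
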
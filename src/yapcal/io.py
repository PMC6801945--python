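"""Readers and writers for the pipeline's file formats.

All tables are plain CSV; schedules are YAML keyed by school and ISO date;
coefficient sets are JSON (see :mod:`yapcal.calibration`).  Readers validate
schemas and quarantine malformed rows instead of silently dropping them.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd
import yaml

from .errors import InputError
from .types import Participant, ScheduleDay, Stage, format_hhmm, parse_hhmm

MINUTE_COLUMNS = ("participant_id", "date", "minute_of_day", "met", "on_body")
ROSTER_COLUMNS = ("participant_id", "school_id", "stage", "sex")
YAP_COLUMNS = ("participant_id", *[f"q{i}" for i in range(1, 16)])


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")


def read_minutes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the long-format minute CSV; return (clean rows, quarantined rows)."""
    df = pd.read_csv(path)
    _require_columns(df, MINUTE_COLUMNS, path)
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    met = pd.to_numeric(df["met"], errors="coerce")
    minute = pd.to_numeric(df["minute_of_day"], errors="coerce")
    bad = (
        dates.isna()
        | met.isna()
        | (met < 0)
        | minute.isna()
        | (minute < 0)
        | (minute > 1439)
    )
    quarantined = df[bad].copy()
    clean = df[~bad].copy()
    clean["date"] = dates[~bad].dt.date
    clean["minute_of_day"] = minute[~bad].astype(int)
    clean["met"] = met[~bad]
    clean["on_body"] = clean["on_body"].astype(bool)
    clean["participant_id"] = clean["participant_id"].astype(str)
    return clean, quarantined


def write_minutes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["on_body"] = out["on_body"].astype(bool)
    out.to_csv(path, index=False)


def read_roster(path) -> list[Participant]:
    df = pd.read_csv(path)
    _require_columns(df, ROSTER_COLUMNS, path)
    roster = []
    for _, row in df.iterrows():
        try:
            stage = Stage(str(row["stage"]))
        except ValueError:
            raise InputError(f"{path}: unknown stage code {row['stage']!r}") from None
        sex = int(row["sex"])
        if sex not in (0, 1):
            raise InputError(f"{path}: sex must be 0 or 1, got {row['sex']!r}")
        roster.append(Participant(str(row["participant_id"]), str(row["school_id"]), stage, sex))
    if not roster:
        raise InputError(f"{path}: empty roster")
    return roster


def write_roster(roster: list[Participant], path) -> None:
    pd.DataFrame(
        {
            "participant_id": [p.id for p in roster],
            "school_id": [p.school_id for p in roster],
            "stage": [p.stage.value for p in roster],
            "sex": [p.sex for p in roster],
        }
    ).to_csv(path, index=False)


def read_yap(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, YAP_COLUMNS, path)
    if not len(df):
        raise InputError(f"{path}: no responses")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_yap(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_schedules(path) -> dict[str, list[ScheduleDay]]:
    """Read the per-school schedule YAML.

    Layout: ``{school_id: {date: {school_start, school_end, break, lunch,
    pe}}}``; an empty mapping for a date marks a weekend (no-school) day.
    Times are "HH:MM" strings; break/lunch are [start, end] pairs and pe a
    list of such pairs.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise InputError(f"{path}: no schools in schedule file")
    schedules: dict[str, list[ScheduleDay]] = {}
    for school_id, days in raw.items():
        out = []
        for date_str, spec in sorted(days.items()):
            date = _dt.date.fromisoformat(str(date_str))
            spec = spec or {}
            if "school_start" not in spec:
                out.append(ScheduleDay(date))
                continue
            pe = [
                (parse_hhmm(s), parse_hhmm(e)) for s, e in spec.get("pe", [])
            ]
            out.append(
                ScheduleDay(
                    date,
                    school_start=parse_hhmm(spec["school_start"]),
                    school_end=parse_hhmm(spec["school_end"]),
                    break_window=_window(spec.get("break")),
                    lunch_window=_window(spec.get("lunch")),
                    pe_windows=pe,
                )
            )
        schedules[str(school_id)] = out
    return schedules


def _window(pair):
    if pair is None:
        return None
    return (parse_hhmm(pair[0]), parse_hhmm(pair[1]))


def write_schedules(schedules: dict[str, list[ScheduleDay]], path) -> None:
    payload: dict = {}
    for school_id, days in schedules.items():
        payload[school_id] = {}
        for day in days:
            if not day.is_school_day:
                payload[school_id][day.date.isoformat()] = {}
                continue
            spec: dict = {
                "school_start": format_hhmm(day.school_start),
                "school_end": format_hhmm(day.school_end),
            }
            if day.break_window:
                spec["break"] = [format_hhmm(t) for t in day.break_window]
            if day.lunch_window:
                spec["lunch"] = [format_hhmm(t) for t in day.lunch_window]
            if day.pe_windows:
                spec["pe"] = [[format_hhmm(s), format_hhmm(e)] for s, e in day.pe_windows]
            payload[school_id][day.date.isoformat()] = spec
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
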
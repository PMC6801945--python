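"""Shared domain types: participants, school schedules, segment vocabulary.

The week is segmented into ten clock-time windows, one per questionnaire
item 1-10.  Items aggregate into four groups: in-school MVPA (items 1-5),
out-of-school MVPA (items 6-8), weekend MVPA (items 9-10), and out-of-school
sedentary behaviour (items 11-15, which share the out-of-school windows on
the device side).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum


class Stage(str, Enum):
    """School stage of a participant."""

    PRIMARY = "primary"
    SECONDARY = "secondary"


class Group(str, Enum):
    """Segment groups matched between questionnaire and device."""

    IN_SCHOOL = "in_school"
    OUT_OF_SCHOOL = "out_of_school"
    WEEKEND = "weekend"
    SB_OUT_OF_SCHOOL = "sb_out_of_school"


#: The ten week segments, in questionnaire item order.
SEGMENTS: tuple[str, ...] = (
    "before_travel",
    "travel_to_school",
    "break",
    "pe",
    "lunch",
    "travel_from_school",
    "after_school",
    "evening",
    "saturday",
    "sunday",
)

#: Segments whose questionnaire item may legitimately be 0 ("did not occur").
ZERO_ALLOWED_SEGMENTS: frozenset[str] = frozenset({"break", "pe", "lunch"})

#: Member segments of each group (device side).  The sedentary group shares
#: the weekday out-of-school windows; its minutes are counted from SB epochs.
GROUP_SEGMENTS: dict[Group, tuple[str, ...]] = {
    Group.IN_SCHOOL: ("before_travel", "travel_to_school", "break", "pe", "lunch"),
    Group.OUT_OF_SCHOOL: ("travel_from_school", "after_school", "evening"),
    Group.WEEKEND: ("saturday", "sunday"),
    Group.SB_OUT_OF_SCHOOL: ("travel_from_school", "after_school", "evening"),
}

#: Questionnaire items (1-based) contributing to each group's composite score.
GROUP_ITEMS: dict[Group, tuple[int, ...]] = {
    Group.IN_SCHOOL: (1, 2, 3, 4, 5),
    Group.OUT_OF_SCHOOL: (6, 7, 8),
    Group.WEEKEND: (9, 10),
    Group.SB_OUT_OF_SCHOOL: (11, 12, 13, 14, 15),
}

#: Groups whose weekly minutes are averaged over the 5-day school week;
#: the weekend group divides by its 2 days.
SCHOOL_WEEK_GROUPS: frozenset[Group] = frozenset(
    {Group.IN_SCHOOL, Group.OUT_OF_SCHOOL, Group.SB_OUT_OF_SCHOOL}
)


@dataclass(frozen=True)
class Participant:
    """One cohort member with the two calibration covariates.

    ``sex`` is coded 0 = boy, 1 = girl, so a negative sex coefficient
    expresses lower girls' MVPA.
    """

    id: str
    school_id: str
    stage: Stage
    sex: int

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (boy) or 1 (girl), got {self.sex!r}")
        if not isinstance(self.stage, Stage):
            object.__setattr__(self, "stage", Stage(self.stage))


@dataclass
class ScheduleDay:
    """One calendar day of a school's timetable.

    Times are minutes of the day (0-1439).  ``school_start``/``school_end``
    are ``None`` on weekend days.  ``pe_windows`` holds zero or more
    (start, end) pairs; break and lunch are single optional windows.
    """

    date: _dt.date
    school_start: int | None = None
    school_end: int | None = None
    break_window: tuple[int, int] | None = None
    lunch_window: tuple[int, int] | None = None
    pe_windows: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_school_day(self) -> bool:
        return self.school_start is not None

    def __post_init__(self) -> None:
        for win in self._windows():
            if win[0] >= win[1]:
                raise ValueError(f"window {win} on {self.date}: start must precede end")
        wins = sorted(self._windows())
        for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping schedule windows {(s1, e1)} and {(s2, e2)} on {self.date}"
                )

    def _windows(self) -> list[tuple[int, int]]:
        wins = [w for w in (self.break_window, self.lunch_window) if w is not None]
        wins.extend(self.pe_windows)
        return wins


def parse_hhmm(text: str | int) -> int:
    """Convert 'HH:MM' (or an already-numeric minute-of-day) to minutes."""
    if isinstance(text, int):
        if not 0 <= text <= 1439:
            raise ValueError(f"minute-of-day out of range: {text}")
        return text
    hh, mm = text.strip().split(":")
    minute = int(hh) * 60 + int(mm)
    if not 0 <= minute <= 1439:
        raise ValueError(f"time out of range: {text!r}")
    return minute


def format_hhmm(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"
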
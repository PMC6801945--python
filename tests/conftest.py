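"""Shared fixtures: a reference school week and the shipped coefficient set."""

import datetime as dt

import pytest

from yapcal.calibration import load_coefficients
from yapcal.types import ScheduleDay

MONDAY = dt.date(2017, 6, 5)


def make_week(
    start=540,  # 09:00
    end=930,  # 15:30
    break_window=(640, 660),  # 10:40-11:00
    lunch_window=(740, 790),  # 12:20-13:10
    pe_days=(1, 3),  # Tue, Thu
    pe_window=(840, 900),  # 14:00-15:00
):
    """A 5-weekday + weekend schedule with configurable windows."""
    days = []
    for i in range(7):
        date = MONDAY + dt.timedelta(days=i)
        if i >= 5:
            days.append(ScheduleDay(date))
            continue
        days.append(
            ScheduleDay(
                date,
                school_start=start,
                school_end=end,
                break_window=break_window,
                lunch_window=lunch_window,
                pe_windows=[pe_window] if i in pe_days else [],
            )
        )
    return days


@pytest.fixture
def week_schedule():
    return make_week()


@pytest.fixture(scope="session")
def english_coefficients():
    return load_coefficients()
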
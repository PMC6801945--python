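"""Synthetic cohort generator with the statistical structure the calibration assumes.

Each participant carries, per segment group, a latent composite score drawn
uniformly on [1, 5] (optionally on the integer grid) and a true percent time
obtained from the generating coefficient set's linear predictor plus
Gaussian noise, clipped to [0, 100].  Minute-level MET streams realise those
percents inside the schedule windows; questionnaire items are the latent
composite plus Likert noise, rounded and truncated to {1..5}.

Minute intensity classes are laid down by quota (error-diffusion)
allocation: within each group the cumulative MVPA/SB minute counts track
``fraction x window length`` to within one minute across the week, while the
placement of the active minutes inside each window is randomised.  The
expected worn-minute MVPA fraction therefore equals the target exactly, and
a noiseless cohort round-trips through segmentation with at most integer
rounding error.  Non-wear is missing-at-random per minute.

A simulated week is 5 consecutive weekdays plus Saturday and Sunday,
matching the 7-day recall frame of the questionnaire.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationCoefficients, load_coefficients, predict_percent
from .errors import ConfigurationError, DataError
from .segments import SegmentWindow, build_windows
from .types import (
    GROUP_ITEMS,
    GROUP_SEGMENTS,
    SEGMENTS,
    ZERO_ALLOWED_SEGMENTS,
    Group,
    Participant,
    ScheduleDay,
    Stage,
)

#: Monday of the simulated recall week.
WEEK_MONDAY = _dt.date(2017, 6, 5)

# MET ranges drawn per intensity class (uniform); only the class matters
# downstream, the values just need to respect the 2.0 / 4.0 cut-points.
MET_RANGES = {"MVPA": (4.0, 9.0), "LIGHT": (2.2, 3.8), "SB": (0.9, 2.0)}

#: SB share of non-MVPA time in windows without their own SB target.
SB_BACKGROUND_SHARE = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the design of the motivating field study: 9 schools
    (4 primary, 5 secondary), ~36 pupils per school, the published English
    coefficient set as generating truth, and moderate observation noise.
    """

    n_schools: int = 9
    stage_split: float = 4 / 9  # fraction of schools that are primary
    n_per_school: int = 36
    true_coefficients: dict[Group, CalibrationCoefficients] | None = None
    percent_noise_sd: float = 8.0
    likert_noise_sd: float = 0.5
    nonwear_rate: float = 0.05
    composite_grid: bool = False  # draw latent composites from {1..5}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_schools < 1:
            raise ConfigurationError("n_schools must be >= 1")
        if self.n_per_school < 1:
            raise ConfigurationError("n_per_school must be >= 1")
        if not 0 <= self.stage_split <= 1:
            raise ConfigurationError("stage_split must lie in [0, 1]")
        if not 0 <= self.nonwear_rate <= 1:
            raise ConfigurationError("nonwear_rate must lie in [0, 1]")
        if self.percent_noise_sd < 0:
            raise ConfigurationError("percent_noise_sd must be >= 0")
        if self.likert_noise_sd < 0:
            raise ConfigurationError("likert_noise_sd must be >= 0")
        if self.true_coefficients is None:
            object.__setattr__(self, "true_coefficients", load_coefficients())

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _week_dates() -> list[_dt.date]:
    return [WEEK_MONDAY + _dt.timedelta(days=i) for i in range(7)]


def make_school_schedule(rng: np.random.Generator, stage: Stage) -> list[ScheduleDay]:
    """One school's timetable for the simulated week.

    Start/end times vary by school; break, lunch and two PE lessons are
    scheduled on school days (PE on two fixed weekdays).
    """
    start = int(rng.integers(520, 545))  # 08:40-09:05
    end = int(rng.integers(905, 935))  # 15:05-15:35
    break_len = 20 if stage is Stage.PRIMARY else 15
    lunch_len = int(rng.integers(45, 61))
    pe_days = sorted(rng.choice(5, size=2, replace=False).tolist())
    days = []
    for i, date in enumerate(_week_dates()):
        if date.weekday() >= 5:
            days.append(ScheduleDay(date))
            continue
        break_start = start + 100
        lunch_start = start + 200
        pe = []
        if i in pe_days:
            pe_start = lunch_start + lunch_len + 30
            pe.append((pe_start, pe_start + 60))
        days.append(
            ScheduleDay(
                date,
                school_start=start,
                school_end=end,
                break_window=(break_start, break_start + break_len),
                lunch_window=(lunch_start, lunch_start + lunch_len),
                pe_windows=pe,
            )
        )
    return days


def _draw_latent(rng: np.random.Generator, config: GeneratorConfig) -> float:
    if config.composite_grid:
        return float(rng.integers(1, 6))
    return float(rng.uniform(1.0, 5.0))


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[Participant], dict[str, list[ScheduleDay]], pd.DataFrame]:
    """Roster, per-school schedules, and per-participant truth table.

    The truth table has one row per (participant, group) with the latent
    composite and the true percent time (linear predictor + Gaussian noise,
    clipped to [0, 100]).  Because the out-of-school MVPA and SB groups share
    the same clock windows, their two latents are redrawn until the
    noiseless linear predictors sum to at most 100% (activity and sedentary
    time compete for the same minutes); after noise the SB percent is capped
    at the remaining share.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n_primary = int(round(config.n_schools * config.stage_split))
    roster: list[Participant] = []
    schedules: dict[str, list[ScheduleDay]] = {}
    truth_rows = []
    for s in range(config.n_schools):
        school_id = f"S{s + 1:02d}"
        stage = Stage.PRIMARY if s < n_primary else Stage.SECONDARY
        schedules[school_id] = make_school_schedule(rng, stage)
        for p in range(config.n_per_school):
            pid = f"{school_id}P{p + 1:03d}"
            sex = int(rng.integers(0, 2))
            part = Participant(pid, school_id, stage, sex)
            roster.append(part)

            latents = {g: _draw_latent(rng, config) for g in Group}

            def _linpred(group: Group) -> float:
                return predict_percent(
                    config.true_coefficients[group], part, latents[group],
                    clip=(-np.inf, np.inf),
                )

            for _ in range(1000):
                if _linpred(Group.OUT_OF_SCHOOL) + _linpred(Group.SB_OUT_OF_SCHOOL) <= 100:
                    break
                latents[Group.OUT_OF_SCHOOL] = _draw_latent(rng, config)
                latents[Group.SB_OUT_OF_SCHOOL] = _draw_latent(rng, config)

            percents: dict[Group, float] = {}
            for group in Group:
                pct = _linpred(group)
                if config.percent_noise_sd > 0:
                    pct += rng.normal(0.0, config.percent_noise_sd)
                percents[group] = float(np.clip(pct, 0.0, 100.0))
            percents[Group.SB_OUT_OF_SCHOOL] = min(
                percents[Group.SB_OUT_OF_SCHOOL],
                100.0 - percents[Group.OUT_OF_SCHOOL],
            )
            for group in Group:
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "school_id": school_id,
                        "stage": stage.value,
                        "sex": sex,
                        "group": group.value,
                        "latent_composite": latents[group],
                        "true_percent": percents[group],
                    }
                )
    return roster, schedules, pd.DataFrame(truth_rows)


def simulate_regression_rows(
    coeffs: CalibrationCoefficients,
    n: int,
    percent_noise_sd: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Calibration rows (percent_time, composite, stage, sex) from known truth.

    Stage and sex are balanced Bernoulli(0.5), the composite is uniform on
    [1, 5], and the percent outcome is the linear predictor plus Gaussian
    noise, clipped to [0, 100] — the direct data-generating model behind the
    calibration fit, used for parameter-recovery checks.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    stage = np.where(rng.random(n) < 0.5, Stage.PRIMARY.value, Stage.SECONDARY.value)
    sex = rng.integers(0, 2, size=n)
    comp = rng.uniform(1.0, 5.0, size=n)
    primary = stage == Stage.PRIMARY.value
    linpred = np.where(
        primary,
        coeffs.intercept_primary + coeffs.yap_by_primary * comp,
        coeffs.intercept_secondary + coeffs.yap_by_secondary * comp,
    ) + coeffs.sex_coef * sex
    pct = linpred + (rng.normal(0.0, percent_noise_sd, size=n) if percent_noise_sd > 0 else 0.0)
    return pd.DataFrame(
        {
            "percent_time": np.clip(pct, 0.0, 100.0),
            "composite": comp,
            "stage": stage,
            "sex": sex,
        }
    )


class _QuotaAllocator:
    """Error-diffusion counter: allocated counts track cumulative targets."""

    def __init__(self) -> None:
        self.target = 0.0
        self.allocated = 0

    def take(self, n: int, fraction: float, cap: int | None = None) -> int:
        self.target += n * fraction
        k = int(round(self.target - self.allocated))
        k = max(0, min(k, n if cap is None else cap))
        self.allocated += k
        return k


def simulate_minutes(
    participant: Participant,
    schedule: list[ScheduleDay],
    truth: dict[Group, float],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One participant's week of minute records (one row per minute per day).

    ``truth`` maps each group to its true percent time.  Within each segment
    window the worn-minute MVPA fraction matches the group's MVPA percent
    (quota allocation); out-of-school windows also realise the sedentary
    group's SB percent.  Minutes outside every window receive a fixed
    background mixture.  Non-wear is flagged i.i.d. at ``nonwear_rate``.
    """
    if not schedule:
        raise DataError("empty schedule")
    for g, pct in truth.items():
        if not 0 <= pct <= 100:
            raise DataError(f"truth percent for {g} out of [0, 100]: {pct}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    seg_group: dict[str, Group] = {}
    for group in (Group.IN_SCHOOL, Group.OUT_OF_SCHOOL, Group.WEEKEND):
        for seg in GROUP_SEGMENTS[group]:
            seg_group[seg] = group

    windows = sorted(build_windows(schedule), key=lambda w: (w.date, w.start))
    mvpa_alloc = {g: _QuotaAllocator() for g in seg_group.values()}
    sb_alloc = _QuotaAllocator()  # out-of-school SB target

    n_days = len(schedule)
    dates = [d.date for d in schedule]
    total = n_days * 1440
    classes = np.empty(total, dtype="U5")
    classes[:] = ""
    date_of = np.repeat(np.arange(n_days), 1440)
    minute_of = np.tile(np.arange(1440), n_days)
    day_index = {d: i for i, d in enumerate(dates)}

    for w in windows:
        base = day_index[w.date] * 1440 + w.start
        n = w.duration_min
        group = seg_group[w.segment]
        mvpa_frac = truth.get(group, 0.0) / 100.0
        k_mvpa = mvpa_alloc[group].take(n, mvpa_frac)
        if group is Group.OUT_OF_SCHOOL and Group.SB_OUT_OF_SCHOOL in truth:
            sb_frac = min(truth[Group.SB_OUT_OF_SCHOOL] / 100.0, 1.0 - mvpa_frac)
            k_sb = sb_alloc.take(n, sb_frac, cap=n - k_mvpa)
        else:
            k_sb = min(n - k_mvpa, int(round((n - k_mvpa) * SB_BACKGROUND_SHARE)))
        order = rng.permutation(n)
        cls = np.empty(n, dtype="U5")
        cls[order[:k_mvpa]] = "MVPA"
        cls[order[k_mvpa : k_mvpa + k_sb]] = "SB"
        cls[order[k_mvpa + k_sb :]] = "LIGHT"
        classes[base : base + n] = cls

    # background minutes outside every window: mostly sedentary
    bg = classes == ""
    n_bg = int(bg.sum())
    if n_bg:
        classes[bg] = rng.choice(["SB", "LIGHT", "MVPA"], size=n_bg, p=[0.75, 0.22, 0.03])

    met = np.empty(total, dtype=float)
    for name, (lo, hi) in MET_RANGES.items():
        m = classes == name
        met[m] = rng.uniform(lo, hi, size=int(m.sum()))
    if config.nonwear_rate >= 1.0:
        on_body = np.zeros(total, dtype=bool)
    elif config.nonwear_rate <= 0.0:
        on_body = np.ones(total, dtype=bool)
    else:
        on_body = rng.random(total) >= config.nonwear_rate

    return pd.DataFrame(
        {
            "participant_id": participant.id,
            "date": [dates[i] for i in date_of],
            "minute_of_day": minute_of,
            "met": met,
            "on_body": on_body,
        }
    )


def simulate_yap(
    participant: Participant,
    latent_composite: dict[Group, float],
    schedule: list[ScheduleDay],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """One participant's 15 questionnaire items.

    Every item of a group is the group's latent composite plus Gaussian
    Likert noise, rounded and truncated to {1..5}.  Break/PE/lunch items are
    0 when the week's schedule contains no such window.
    """
    for g, val in latent_composite.items():
        if not 1 <= val <= 5:
            raise DataError(f"latent composite for {g} outside [1, 5]: {val}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scheduled = {w.segment for w in build_windows(schedule)}
    items: dict[str, int] = {}
    for group in Group:
        latent = latent_composite[group]
        for item in GROUP_ITEMS[group]:
            seg = SEGMENTS[item - 1] if item <= 10 else None
            if seg in ZERO_ALLOWED_SEGMENTS and seg not in scheduled:
                items[f"q{item}"] = 0
                continue
            noise = rng.normal(0.0, config.likert_noise_sd) if config.likert_noise_sd > 0 else 0.0
            items[f"q{item}"] = int(np.clip(round(latent + noise), 1, 5))
    return items


@dataclass
class SyntheticCohort:
    """Everything the pipeline reads, generated in memory."""

    roster: list[Participant]
    schedules: dict[str, list[ScheduleDay]]
    truth: pd.DataFrame
    minutes: pd.DataFrame
    responses: pd.DataFrame
    config: GeneratorConfig = field(repr=False, default=None)

    @property
    def roster_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.id for p in self.roster],
                "school_id": [p.school_id for p in self.roster],
                "stage": [p.stage.value for p in self.roster],
                "sex": [p.sex for p in self.roster],
            }
        )


def generate_dataset(config: GeneratorConfig) -> SyntheticCohort:
    """Full synthetic dataset: roster, schedules, truth, minutes, responses."""
    roster, schedules, truth = generate_cohort(config)
    rng = np.random.default_rng(config.seed + 1)
    minute_frames = []
    yap_rows = []
    for part in roster:
        t = truth[truth["participant_id"] == part.id]
        truth_map = {Group(r["group"]): r["true_percent"] for _, r in t.iterrows()}
        latent_map = {Group(r["group"]): r["latent_composite"] for _, r in t.iterrows()}
        sched = schedules[part.school_id]
        minute_frames.append(simulate_minutes(part, sched, truth_map, config, rng))
        row = {"participant_id": part.id}
        row.update(simulate_yap(part, latent_map, sched, config, rng))
        yap_rows.append(row)
    minutes = pd.concat(minute_frames, ignore_index=True)
    responses = pd.DataFrame(yap_rows)
    return SyntheticCohort(roster, schedules, truth, minutes, responses, config)
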
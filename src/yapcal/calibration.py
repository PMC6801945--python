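"""Quantile-regression calibration of composite recall scores to percent time.

The model regresses device-derived percent time in a behaviour (MVPA or SB)
within a segment group on school stage, sex, and the group composite score:

    percent ~ intercept_primary*1[primary] + intercept_secondary*1[secondary]
              + sex_coef*sex + slope_primary*(score*1[primary])
              + slope_secondary*(score*1[secondary])

with no global intercept, fitted at the median (tau = 0.5) by minimising the
asymmetric check loss.  Sex is coded 0 = boy, 1 = girl.  Predictions are
clipped to [0, 100] percent and converted to weekly minutes through the
scheduled group duration, then to daily minutes with a 5-day school week or
a 2-day weekend.

A published English coefficient set for the four groups ships with the
package (``data/english_coefficients.json``); fitting your own set from a
calibration sample is the other supported source.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ModelError
from .types import SCHOOL_WEEK_GROUPS, Group, Participant, Stage

COEF_NAMES = (
    "intercept_primary",
    "intercept_secondary",
    "sex_coef",
    "yap_by_primary",
    "yap_by_secondary",
)


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Per-outcome calibration coefficients, in percent-time units."""

    outcome: Group
    intercept_primary: float
    intercept_secondary: float
    sex_coef: float
    yap_by_primary: float
    yap_by_secondary: float

    def __post_init__(self) -> None:
        vals = [getattr(self, n) for n in COEF_NAMES]
        if not all(np.isfinite(vals)):
            raise ValueError("all coefficients must be finite")
        if not isinstance(self.outcome, Group):
            object.__setattr__(self, "outcome", Group(self.outcome))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["outcome"] = self.outcome.value
        return d


@dataclass
class FitReport:
    """Result of one quantile-regression calibration fit."""

    coefficients: CalibrationCoefficients
    standard_errors: dict[str, float]
    rmse: float
    n_used: int
    tau: float = 0.5


def _design(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    stage = data["stage"].map(lambda s: Stage(s).value)
    primary = (stage == "primary").to_numpy(dtype=float)
    secondary = (stage == "secondary").to_numpy(dtype=float)
    sex = data["sex"].to_numpy(dtype=float)
    comp = data["composite"].to_numpy(dtype=float)
    X = np.column_stack([primary, secondary, sex, comp * primary, comp * secondary])
    y = data["percent_time"].to_numpy(dtype=float)
    return X, y


def fit_median_regression(
    data: pd.DataFrame, outcome: Group | str, tau: float = 0.5
) -> FitReport:
    """Fit the stage/sex/composite calibration model at quantile ``tau``.

    ``data`` needs columns ``percent_time``, ``composite``, ``stage``,
    ``sex``.  Raises :class:`ModelError` when the design is deficient: fewer
    than 10 rows, a school stage absent, or a constant composite within a
    stage (no identifiable slope).
    """
    data = data.dropna(subset=["percent_time", "composite", "stage", "sex"])
    if len(data) < 10:
        raise ModelError(f"need at least 10 complete rows, got {len(data)}")
    X, y = _design(data)
    if X[:, 0].sum() == 0 or X[:, 1].sum() == 0:
        missing = "primary" if X[:, 0].sum() == 0 else "secondary"
        raise ModelError(f"no unique solution: {missing} stage absent from calibration data")
    for stage_col, slope_col, name in ((0, 3, "primary"), (1, 4, "secondary")):
        comp_vals = X[X[:, stage_col] == 1, slope_col]
        if np.ptp(comp_vals) == 0:
            raise ModelError(f"no unique solution: composite constant within {name} stage")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QuantReg warns on exact fits
        model = sm.QuantReg(y, X)
        res = model.fit(q=tau, max_iter=5000)
        params = np.asarray(res.params, dtype=float)
        try:
            bse = np.asarray(res.bse, dtype=float)
        except Exception:  # degenerate (noiseless) designs have no finite SE
            bse = np.full(5, np.nan)

    coeffs = CalibrationCoefficients(Group(outcome), *params)
    fitted = X @ params
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    ses = dict(zip(COEF_NAMES, bse))
    return FitReport(coeffs, ses, rmse, len(data), tau)


def check_loss(residuals: np.ndarray, tau: float = 0.5) -> float:
    """Asymmetric absolute (pinball) loss: sum of tau-weighted residuals."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))


def predict_percent(
    coeffs: CalibrationCoefficients,
    participant: Participant,
    composite: float,
    clip: tuple[float, float] = (0.0, 100.0),
) -> float:
    """Evaluate the linear predictor for one participant; clip to [0, 100].

    An undefined (NaN) composite propagates to a NaN prediction.
    """
    if composite is None or (isinstance(composite, float) and np.isnan(composite)):
        return float("nan")
    if participant.stage is Stage.PRIMARY:
        pred = coeffs.intercept_primary + coeffs.yap_by_primary * composite
    else:
        pred = coeffs.intercept_secondary + coeffs.yap_by_secondary * composite
    pred += coeffs.sex_coef * participant.sex
    return float(np.clip(pred, *clip))


def percent_to_minutes(
    percent_time: float, weekly_duration_min: float, group: Group | str
) -> tuple[float, float]:
    """Convert percent time to (weekly, daily) minutes for a segment group.

    Weekly = percent/100 x scheduled weekly duration; daily divides by 5 for
    school-week groups and by 2 for the weekend.
    """
    group = Group(group)
    if not weekly_duration_min > 0:
        raise ValueError(f"weekly duration must be positive, got {weekly_duration_min}")
    weekly = percent_time / 100.0 * weekly_duration_min
    days = 5.0 if group in SCHOOL_WEEK_GROUPS else 2.0
    return weekly, weekly / days


def weekly_to_daily(weekly_minutes: float, group: Group | str) -> float:
    """Weekly -> daily minutes with the group's day divisor (5 or 2)."""
    return weekly_minutes / (5.0 if Group(group) in SCHOOL_WEEK_GROUPS else 2.0)


def apply_per_question(
    percent_fn: Callable[[int, int, Participant], float],
    items: Mapping[int, int],
    item_durations: Mapping[int, float],
    participant: Participant,
) -> float:
    """Generic per-question calibration pathway: weekly minutes for a group.

    ``percent_fn(question, score, participant)`` supplies percent time for
    one question (pluggable coefficient sets, e.g. externally published
    per-question algorithms); each question's percent is applied to its own
    weekly duration and the minutes are summed.  Questions with score 0 or
    zero duration contribute nothing.
    """
    total = 0.0
    for q, score in items.items():
        dur = item_durations.get(q, 0.0)
        if score == 0 or dur <= 0:
            continue
        total += percent_fn(q, score, participant) / 100.0 * dur
    return total


def load_coefficients(path=None) -> dict[Group, CalibrationCoefficients]:
    """Load a coefficient set from JSON (default: the shipped English set)."""
    if path is None:
        text = resources.files("yapcal.data").joinpath("english_coefficients.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    payload = json.loads(text)
    out = {}
    for entry in payload["coefficients"]:
        c = CalibrationCoefficients(
            Group(entry["outcome"]),
            *[entry["values"][n] for n in COEF_NAMES],
        )
        out[c.outcome] = c
    return out


def save_coefficients(
    reports: Mapping[Group, FitReport] | Mapping[Group, CalibrationCoefficients], path
) -> None:
    """Serialise a coefficient set (with SEs when available) to JSON."""
    entries = []
    for group, obj in reports.items():
        if isinstance(obj, FitReport):
            coeffs, ses, tau = obj.coefficients, obj.standard_errors, obj.tau
        else:
            coeffs, ses, tau = obj, None, 0.5
        entries.append(
            {
                "outcome": Group(group).value,
                "values": {n: getattr(coeffs, n) for n in COEF_NAMES},
                "standard_errors": ses,
                "tau": tau,
            }
        )
    with open(path, "w") as fh:
        json.dump({"version": 1, "coefficients": entries}, fh, indent=2)
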
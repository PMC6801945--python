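"""Guideline-compliance classification from predicted and device MVPA.

Participants are flagged as meeting an MVPA guideline (60 min/day overall,
30 min/school-day) from both the calibrated predictions and the device
criterion; agreement is summarised with percent agreement, Cohen's kappa,
sensitivity and specificity, treating the device flags as the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .types import Group

GUIDELINE_WHOLE_DAY = 60.0  # min MVPA per day
GUIDELINE_SCHOOL_DAY = 30.0  # min MVPA per school day


@dataclass
class ClassificationReport:
    """Confusion-matrix summary of guideline compliance vs the criterion."""

    threshold_min_per_day: float
    n: int
    prevalence_pred: float  # percent flagged active by prediction
    prevalence_obs: float  # percent flagged active by the criterion
    percent_agreement: float
    kappa: float
    sensitivity: float  # percent; NaN when no criterion positives
    specificity: float  # percent; NaN when no criterion negatives
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)


def daily_averages(
    weekly: pd.DataFrame,
    value_col: str = "weekly_minutes",
    whole_day_divisor: float = 7.0,
) -> pd.DataFrame:
    """Per-participant whole-day and school-day MVPA minutes per day.

    ``weekly`` holds one row per (participant_id, group) with weekly MVPA
    minutes and a ``valid`` flag.  whole_day = (in-school + out-of-school +
    weekend) / 7; school_day = in-school / 5.  Participants with any
    required group invalid are excluded from the corresponding average.
    """
    piv = weekly.pivot_table(
        index="participant_id", columns="group", values=value_col, aggfunc="first"
    )
    valid = weekly.pivot_table(
        index="participant_id", columns="group", values="valid", aggfunc="first"
    ).fillna(False).astype(bool)
    mvpa_groups = [Group.IN_SCHOOL.value, Group.OUT_OF_SCHOOL.value, Group.WEEKEND.value]
    for g in mvpa_groups:
        if g not in piv.columns:
            piv[g] = np.nan
            valid[g] = False
    whole_ok = valid[mvpa_groups].all(axis=1)
    school_ok = valid[Group.IN_SCHOOL.value]
    out = pd.DataFrame(index=piv.index)
    out["whole_day"] = piv[mvpa_groups].sum(axis=1).where(whole_ok) / whole_day_divisor
    out["school_day"] = piv[Group.IN_SCHOOL.value].where(school_ok) / 5.0
    return out.reset_index()


def classification_report(
    pred_daily: np.ndarray, obs_daily: np.ndarray, threshold: float
) -> ClassificationReport:
    """Compare guideline flags (value >= threshold) against the criterion.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from marginal
    products; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), computed
    with the device flags as truth.
    """
    if threshold <= 0:
        raise DataError(f"threshold must be positive, got {threshold}")
    pred = np.asarray(pred_daily, dtype=float)
    obs = np.asarray(obs_daily, dtype=float)
    if pred.shape != obs.shape:
        raise DataError("pred and obs must be paired")
    keep = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[keep], obs[keep]
    n = len(pred)
    if n == 0:
        raise DataError("no complete pairs to classify")
    pf = pred >= threshold
    of = obs >= threshold
    tp = int(np.sum(pf & of))
    fp = int(np.sum(pf & ~of))
    fn = int(np.sum(~pf & of))
    tn = int(np.sum(~pf & ~of))
    p_o = (tp + tn) / n
    p_e = ((tp + fp) / n) * ((tp + fn) / n) + ((fn + tn) / n) * ((fp + tn) / n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return ClassificationReport(
        threshold_min_per_day=float(threshold),
        n=n,
        prevalence_pred=100.0 * (tp + fp) / n,
        prevalence_obs=100.0 * (tp + fn) / n,
        percent_agreement=100.0 * p_o,
        kappa=float(kappa),
        sensitivity=sens,
        specificity=spec,
        confusion=(tp, fp, fn, tn),
    )
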
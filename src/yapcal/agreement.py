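"""Student- and school-level agreement between predicted and device minutes.

Student-level agreement is summarised by the Pearson correlation and the
mean absolute percentage error (MAPE, computed over pairs with a nonzero
device value).  School-level agreement uses the mean bias across per-school
means.  Equivalence testing asks whether the 90% CI of the predicted values
lies inside a +/-z% zone around the device mean, expanding z from 10% in
5-point steps until equivalence is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

ZONE_GRID = tuple(range(10, 55, 5))


@dataclass
class AgreementReport:
    """Student-level agreement for one segment group."""

    group: str
    pearson_r: float
    mape_percent: float
    n: int
    n_mape: int
    r_defined: bool = True


@dataclass
class SchoolBiasReport:
    """School-level bias for one segment group."""

    group: str
    school_means: pd.DataFrame  # columns: school_id, predicted_mean, observed_mean
    bias_mean: float
    bias_sd: float
    n_schools: int


@dataclass(frozen=True)
class EquivalenceResult:
    """CI-vs-zone verdict at one percent zone."""

    group: str
    zone_percent: int
    ci90: tuple[float, float]
    zone: tuple[float, float]
    equivalent: bool


def student_agreement(pred: np.ndarray, obs: np.ndarray, group: str = "") -> AgreementReport:
    """Pearson r and MAPE over paired student-level weekly minutes."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    complete = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[complete], obs[complete]
    if len(pred) < 3:
        raise DataError(f"need at least 3 complete pairs, got {len(pred)}")
    r_defined = np.ptp(pred) > 0 and np.ptp(obs) > 0
    r = float(stats.pearsonr(pred, obs).statistic) if r_defined else float("nan")
    nonzero = obs > 0
    mape = float(100.0 * np.mean(np.abs(pred[nonzero] - obs[nonzero]) / obs[nonzero]))
    return AgreementReport(group, r, mape, int(len(pred)), int(nonzero.sum()), r_defined)


def school_bias(
    pred: np.ndarray, obs: np.ndarray, school_ids: np.ndarray, group: str = ""
) -> SchoolBiasReport:
    """Unweighted per-school means; bias mean and SD across schools."""
    df = pd.DataFrame({"pred": pred, "obs": obs, "school_id": school_ids}).dropna()
    if not len(df):
        raise DataError("no complete (pred, obs) pairs in any school")
    means = (
        df.groupby("school_id", as_index=False)
        .agg(predicted_mean=("pred", "mean"), observed_mean=("obs", "mean"))
    )
    diffs = means["predicted_mean"] - means["observed_mean"]
    bias_mean = float(diffs.mean())
    bias_sd = float(diffs.std(ddof=1)) if len(means) > 1 else float("nan")
    return SchoolBiasReport(group, means, bias_mean, bias_sd, len(means))


def equivalence_zone_search(
    pred: np.ndarray,
    reference_mean: float,
    group: str = "",
    start_percent: int = 10,
    step: int = 5,
    max_percent: int = 50,
) -> tuple[list[EquivalenceResult], int | None]:
    """Expanding-zone equivalence test of predicted values against a reference.

    The 90% CI of the predicted values is mean +/- t(0.95, n-1) * SE.  The
    zone at z% is reference*(1 -/+ z/100); containment is closed at the
    boundaries.  Returns all grid results plus the smallest equivalent zone
    (``None`` when no zone up to ``max_percent`` contains the CI).
    """
    pred = np.asarray(pred, dtype=float)
    pred = pred[np.isfinite(pred)]
    if len(pred) < 2:
        raise DataError(f"need at least 2 predicted values, got {len(pred)}")
    if not reference_mean > 0:
        raise DataError(f"reference mean must be positive, got {reference_mean}")
    n = len(pred)
    mean = float(pred.mean())
    se = float(pred.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.95, n - 1))
    ci = (mean - tcrit * se, mean + tcrit * se)
    results = []
    smallest: int | None = None
    for z in range(start_percent, max_percent + 1, step):
        zone = (reference_mean * (1 - z / 100.0), reference_mean * (1 + z / 100.0))
        ok = zone[0] <= ci[0] and ci[1] <= zone[1]
        results.append(EquivalenceResult(group, z, ci, zone, ok))
        if ok and smallest is None:
            smallest = z
    return results, smallest


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root mean squared residual of paired values."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) == 0 or len(pred) != len(obs):
        raise DataError("rmse needs at least one pair of equal-length vectors")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def validation_report(
    paired: pd.DataFrame, group: str
) -> dict:
    """Full agreement summary for one group from a paired student table.

    ``paired`` needs columns ``pred``, ``obs``, ``school_id``.  Mirrors the
    usual cross-validation report layout: predicted/observed school-level
    mean (SD), bias (SD), and the smallest equivalence zone, plus the
    student-level r and MAPE.
    """
    paired = paired.dropna(subset=["pred", "obs"])
    stu = student_agreement(paired["pred"].to_numpy(), paired["obs"].to_numpy(), group)
    sch = school_bias(
        paired["pred"].to_numpy(), paired["obs"].to_numpy(),
        paired["school_id"].to_numpy(), group,
    )
    results, zone = equivalence_zone_search(
        paired["pred"].to_numpy(), float(paired["obs"].mean()), group
    )
    return {
        "group": group,
        "n_students": stu.n,
        "pearson_r": stu.pearson_r,
        "mape_percent": stu.mape_percent,
        "rmse_min_week": rmse(paired["pred"].to_numpy(), paired["obs"].to_numpy()),
        "predicted_mean": float(sch.school_means["predicted_mean"].mean()),
        "predicted_sd": float(sch.school_means["predicted_mean"].std(ddof=1))
        if sch.n_schools > 1 else float("nan"),
        "observed_mean": float(sch.school_means["observed_mean"].mean()),
        "observed_sd": float(sch.school_means["observed_mean"].std(ddof=1))
        if sch.n_schools > 1 else float("nan"),
        "bias_mean": sch.bias_mean,
        "bias_sd": sch.bias_sd,
        "n_schools": sch.n_schools,
        "equivalence_zone_percent": zone,
        "ci90_low": results[0].ci90[0],
        "ci90_high": results[0].ci90[1],
    }
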
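"""End-to-end orchestration: simulate/load -> segment -> score -> calibrate
-> predict -> validate -> classify.

The school sample is split, stratified by stage, into calibration schools
(used to fit the four quantile-regression models) and cross-validation
schools (used for the agreement and equivalence analyses); guideline
classification uses the full analytic sample.  Every run can write its
tables plus a manifest carrying the configuration hash, seed and split, so
a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .agreement import validation_report
from .calibration import (
    CalibrationCoefficients,
    FitReport,
    fit_median_regression,
    load_coefficients,
    predict_percent,
)
from .classification import (
    GUIDELINE_SCHOOL_DAY,
    GUIDELINE_WHOLE_DAY,
    classification_report,
    daily_averages,
)
from .errors import ConfigurationError
from .scoring import score_responses
from .segments import ComplianceRule, device_weekly_estimates
from .simulate import GeneratorConfig, SyntheticCohort, generate_dataset
from .types import Group, Participant, Stage

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; either file inputs or a simulation block."""

    simulation: GeneratorConfig | None = None
    minutes_path: str | None = None
    schedules_path: str | None = None
    roster_path: str | None = None
    yap_path: str | None = None
    coefficient_source: str = "fit"  # "fit" | "file"
    coefficient_file: str | None = None
    compliance: ComplianceRule = field(default_factory=ComplianceRule)
    calibration_fraction: float = 2 / 3
    whole_day_divisor: float = 7.0
    whole_day_threshold: float = GUIDELINE_WHOLE_DAY
    school_day_threshold: float = GUIDELINE_SCHOOL_DAY
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.coefficient_source not in ("fit", "file"):
            raise ConfigurationError("coefficient_source must be 'fit' or 'file'")
        if self.simulation is None:
            missing = [
                name
                for name in ("minutes_path", "schedules_path", "roster_path", "yap_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ConfigurationError(
                    f"no simulation block and missing input path(s): {missing}"
                )
        if not 0 < self.calibration_fraction < 1:
            raise ConfigurationError("calibration_fraction must lie in (0, 1)")

    def hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return str(obj)

        payload = json.dumps(enc(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Report bundle of one pipeline run."""

    device_weekly: pd.DataFrame
    scores: pd.DataFrame
    exclusions: pd.DataFrame
    analytic: pd.DataFrame  # merged per (participant, group) analysis rows
    split: dict[str, str]  # school_id -> "calibration" | "cross_validation"
    fit_reports: dict[Group, FitReport]
    coefficients: dict[Group, CalibrationCoefficients]
    validation: pd.DataFrame  # one row per group (cross-validation sample)
    classification: dict[str, dict]
    manifest: dict


def split_schools(
    roster: list[Participant], fraction: float, seed: int
) -> dict[str, str]:
    """Seeded stage-stratified school split into calibration / cross-validation.

    Within each stage at least one school goes to each arm when the stage
    has two or more schools.
    """
    rng = np.random.default_rng(seed)
    by_stage: dict[Stage, list[str]] = {}
    for p in roster:
        by_stage.setdefault(p.stage, [])
        if p.school_id not in by_stage[p.stage]:
            by_stage[p.stage].append(p.school_id)
    split: dict[str, str] = {}
    for stage, schools in sorted(by_stage.items(), key=lambda kv: kv[0].value):
        schools = sorted(schools)
        order = rng.permutation(len(schools))
        n_cal = int(round(len(schools) * fraction))
        n_cal = min(max(n_cal, 1), max(len(schools) - 1, 1))
        for i, idx in enumerate(order):
            split[schools[idx]] = "calibration" if i < n_cal else "cross_validation"
    return split


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full calibration-and-validation pipeline."""
    config.validate()

    # ---- inputs -------------------------------------------------------
    quarantined = pd.DataFrame()
    if config.simulation is not None:
        cohort = generate_dataset(config.simulation)
        roster, schedules = cohort.roster, cohort.schedules
        minutes, responses = cohort.minutes, cohort.responses
    else:
        cohort = None
        minutes, quarantined = _io.read_minutes(config.minutes_path)
        schedules = _io.read_schedules(config.schedules_path)
        roster = _io.read_roster(config.roster_path)
        responses = _io.read_yap(config.yap_path)
    if len(quarantined):
        logger.warning("quarantined %d malformed minute rows", len(quarantined))
    logger.info("inputs: %d participants, %d minute rows", len(roster), len(minutes))

    # ---- segmentation (per school, that school's schedule) ------------
    by_school: dict[str, list[Participant]] = {}
    for p in roster:
        by_school.setdefault(p.school_id, []).append(p)
    weekly_frames = []
    for school_id, members in sorted(by_school.items()):
        pids = [p.id for p in members]
        sub = minutes[minutes["participant_id"].isin(pids)]
        weekly_frames.append(
            device_weekly_estimates(
                sub, schedules[school_id], config.compliance, participants=pids
            )
        )
    device_weekly = pd.concat(weekly_frames, ignore_index=True)
    n_valid = device_weekly[device_weekly["valid"]]["participant_id"].nunique()
    logger.info("segmentation: %d participants with >=1 valid group", n_valid)

    # ---- questionnaire scoring ---------------------------------------
    roster_frame = pd.DataFrame(
        {
            "participant_id": [p.id for p in roster],
            "school_id": [p.school_id for p in roster],
            "stage": [p.stage.value for p in roster],
            "sex": [p.sex for p in roster],
        }
    )
    scores, exclusions = score_responses(responses, schedules, roster_frame)
    logger.info("scoring: %d responses excluded", len(exclusions))

    # ---- analytic sample ---------------------------------------------
    analytic = device_weekly.merge(scores, on=["participant_id", "group"], how="inner")
    analytic = analytic.merge(roster_frame, on="participant_id", how="left")
    analytic["row_valid"] = analytic["valid"] & analytic["defined"]

    # ---- school split and calibration --------------------------------
    split = split_schools(roster, config.calibration_fraction, config.seed)
    analytic["arm"] = analytic["school_id"].map(split)
    fit_reports: dict[Group, FitReport] = {}
    if config.coefficient_source == "file":
        coefficients = load_coefficients(config.coefficient_file)
    else:
        cal = analytic[(analytic["arm"] == "calibration") & analytic["row_valid"]]
        stages_present = set(cal["stage"].unique())
        if stages_present != {"primary", "secondary"}:
            raise ConfigurationError(
                f"calibration arm must contain both stages, found {sorted(stages_present)}"
            )
        coefficients = {}
        for group in Group:
            rows = cal[cal["group"] == group.value].rename(columns={"score": "composite"})
            report = fit_median_regression(
                rows[["percent_time", "composite", "stage", "sex"]], group
            )
            fit_reports[group] = report
            coefficients[group] = report.coefficients
            logger.info("fit %s: n=%d rmse=%.2f", group.value, report.n_used, report.rmse)

    # ---- prediction (all analytic rows) ------------------------------
    part_of = {p.id: p for p in roster}

    def _predict(row) -> float:
        if not row["row_valid"]:
            return np.nan
        pct = predict_percent(
            coefficients[Group(row["group"])], part_of[row["participant_id"]], row["score"]
        )
        return pct / 100.0 * row["weekly_duration_min_score"]

    analytic = analytic.rename(
        columns={
            "weekly_duration_min_x": "weekly_duration_min_device",
            "weekly_duration_min_y": "weekly_duration_min_score",
        }
    )
    analytic["predicted_weekly_minutes"] = analytic.apply(_predict, axis=1)

    # ---- cross-validation agreement ----------------------------------
    cv = analytic[(analytic["arm"] == "cross_validation") & analytic["row_valid"]]
    val_rows = []
    for group in Group:
        sub = cv[cv["group"] == group.value]
        paired = pd.DataFrame(
            {
                "pred": sub["predicted_weekly_minutes"].to_numpy(),
                "obs": sub["weekly_minutes"].to_numpy(),
                "school_id": sub["school_id"].to_numpy(),
            }
        )
        val_rows.append(validation_report(paired, group.value))
    validation = pd.DataFrame(val_rows)

    # ---- guideline classification (full analytic sample) -------------
    valid_rows = analytic[analytic["row_valid"]]
    obs_daily = daily_averages(
        valid_rows, "weekly_minutes", config.whole_day_divisor
    ).set_index("participant_id")
    pred_daily = daily_averages(
        valid_rows.assign(weekly_minutes=valid_rows["predicted_weekly_minutes"]),
        "weekly_minutes",
        config.whole_day_divisor,
    ).set_index("participant_id")
    joined = obs_daily.join(pred_daily, lsuffix="_obs", rsuffix="_pred")
    classification = {
        "whole_day": dataclasses.asdict(
            classification_report(
                joined["whole_day_pred"].to_numpy(),
                joined["whole_day_obs"].to_numpy(),
                config.whole_day_threshold,
            )
        ),
        "school_day": dataclasses.asdict(
            classification_report(
                joined["school_day_pred"].to_numpy(),
                joined["school_day_obs"].to_numpy(),
                config.school_day_threshold,
            )
        ),
    }

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "split": split,
        "n_participants": len(roster),
        "n_quarantined_minutes": int(len(quarantined)),
        "n_excluded_responses": int(len(exclusions)),
        "n_analytic_rows": int(analytic["row_valid"].sum()),
    }

    result = PipelineResult(
        device_weekly=device_weekly,
        scores=scores,
        exclusions=exclusions,
        analytic=analytic,
        split=split,
        fit_reports=fit_reports,
        coefficients=coefficients,
        validation=validation,
        classification=classification,
        manifest=manifest,
    )
    if config.output_dir is not None:
        write_bundle(result, config, cohort)
    return result


def write_bundle(
    result: PipelineResult, config: PipelineConfig, cohort: SyntheticCohort | None
) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.device_weekly.to_csv(out / "device_weekly.csv", index=False)
    result.scores.to_csv(out / "composite_scores.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    result.analytic.to_csv(out / "analytic_rows.csv", index=False)
    result.validation.to_csv(out / "validation.csv", index=False)
    with open(out / "classification.json", "w") as fh:
        json.dump(result.classification, fh, indent=2, default=float)
    if result.fit_reports:
        payload = {
            g.value: {
                "coefficients": r.coefficients.as_dict(),
                "standard_errors": r.standard_errors,
                "rmse": r.rmse,
                "n_used": r.n_used,
                "tau": r.tau,
            }
            for g, r in result.fit_reports.items()
        }
        with open(out / "fit_reports.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
    if cohort is not None:
        _io.write_minutes(cohort.minutes, out / "minutes.csv")
        _io.write_roster(cohort.roster, out / "roster.csv")
        _io.write_yap(cohort.responses, out / "yap.csv")
        _io.write_schedules(cohort.schedules, out / "schedules.yaml")
        cohort.truth.to_csv(out / "truth.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
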
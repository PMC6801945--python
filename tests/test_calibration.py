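"""Quantile-regression fitting, prediction, and minute conversion."""

import numpy as np
import pandas as pd
import pytest

from yapcal.calibration import (
    COEF_NAMES,
    CalibrationCoefficients,
    apply_per_question,
    check_loss,
    fit_median_regression,
    load_coefficients,
    percent_to_minutes,
    predict_percent,
    save_coefficients,
    weekly_to_daily,
)
from yapcal.errors import ModelError
from yapcal.simulate import simulate_regression_rows
from yapcal.types import Group, Participant, Stage


def make_rows(n, rng, intercept=10.0, slope=2.0, sex_coef=0.0, noise=0.0):
    stage = np.where(rng.random(n) < 0.5, "primary", "secondary")
    sex = rng.integers(0, 2, size=n)
    comp = rng.uniform(1, 5, size=n)
    y = intercept + slope * comp + sex_coef * sex
    if noise:
        y = y + rng.normal(0, noise, size=n)
    return pd.DataFrame({"percent_time": y, "composite": comp, "stage": stage, "sex": sex})


class TestFit:
    def test_noiseless_data_interpolated_exactly(self):
        rows = make_rows(60, np.random.default_rng(0))
        rep = fit_median_regression(rows, Group.IN_SCHOOL)
        c = rep.coefficients
        assert c.intercept_primary == pytest.approx(10.0, abs=1e-6)
        assert c.intercept_secondary == pytest.approx(10.0, abs=1e-6)
        assert c.yap_by_primary == pytest.approx(2.0, abs=1e-6)
        assert c.yap_by_secondary == pytest.approx(2.0, abs=1e-6)
        assert c.sex_coef == pytest.approx(0.0, abs=1e-6)
        assert rep.rmse == pytest.approx(0.0, abs=1e-6)

    def test_constant_outcome_gives_flat_fit(self):
        rows = make_rows(40, np.random.default_rng(1), intercept=40.0, slope=0.0)
        rep = fit_median_regression(rows, Group.IN_SCHOOL)
        c = rep.coefficients
        assert c.intercept_primary == pytest.approx(40.0, abs=1e-6)
        assert c.intercept_secondary == pytest.approx(40.0, abs=1e-6)
        assert abs(c.yap_by_primary) < 1e-6 and abs(c.yap_by_secondary) < 1e-6

    def test_recovers_generating_coefficients_within_two_se(self, english_coefficients):
        truth = english_coefficients[Group.IN_SCHOOL]
        rows = simulate_regression_rows(truth, 200, 10.0, 1)
        rep = fit_median_regression(rows, Group.IN_SCHOOL)
        for name in COEF_NAMES:
            err = abs(getattr(rep.coefficients, name) - getattr(truth, name))
            assert err <= 2 * rep.standard_errors[name], name

    def test_missing_stage_is_a_model_error(self):
        rows = make_rows(40, np.random.default_rng(2))
        rows["stage"] = "primary"
        with pytest.raises(ModelError, match="secondary"):
            fit_median_regression(rows, Group.IN_SCHOOL)

    def test_constant_composite_is_a_model_error(self):
        rows = make_rows(40, np.random.default_rng(3))
        rows["composite"] = 3.0
        with pytest.raises(ModelError, match="composite"):
            fit_median_regression(rows, Group.IN_SCHOOL)

    def test_too_few_rows_is_a_model_error(self):
        rows = make_rows(6, np.random.default_rng(4))
        with pytest.raises(ModelError, match="10"):
            fit_median_regression(rows, Group.IN_SCHOOL)

    def test_median_fit_beats_least_squares_on_check_loss(self):
        rng = np.random.default_rng(5)
        rows = make_rows(150, rng, sex_coef=-4.0, noise=8.0)
        rep = fit_median_regression(rows, Group.IN_SCHOOL)
        X = np.column_stack(
            [
                (rows["stage"] == "primary").astype(float),
                (rows["stage"] == "secondary").astype(float),
                rows["sex"],
                rows["composite"] * (rows["stage"] == "primary"),
                rows["composite"] * (rows["stage"] == "secondary"),
            ]
        )
        y = rows["percent_time"].to_numpy()
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        beta_qr = np.array([getattr(rep.coefficients, n) for n in COEF_NAMES])
        assert check_loss(y - X @ beta_qr) <= check_loss(y - X @ beta_ols) + 1e-9

    def test_residual_signs_balanced_at_median(self):
        rng = np.random.default_rng(6)
        rows = make_rows(201, rng, noise=5.0)
        rep = fit_median_regression(rows, Group.IN_SCHOOL)
        X = np.column_stack(
            [
                (rows["stage"] == "primary").astype(float),
                (rows["stage"] == "secondary").astype(float),
                rows["sex"],
                rows["composite"] * (rows["stage"] == "primary"),
                rows["composite"] * (rows["stage"] == "secondary"),
            ]
        )
        resid = rows["percent_time"].to_numpy() - X @ np.array(
            [getattr(rep.coefficients, n) for n in COEF_NAMES]
        )
        pos = int((resid > 1e-9).sum())
        neg = int((resid < -1e-9).sum())
        assert abs(pos - neg) <= 5  # parameter count


class TestPredict:
    def test_secondary_boy_composite_three(self, english_coefficients):
        p = Participant("x", "s", Stage.SECONDARY, sex=0)
        pct = predict_percent(english_coefficients[Group.IN_SCHOOL], p, 3.0)
        assert pct == pytest.approx(13.72 + 7.31 * 3)  # 35.65

    def test_sex_coefficient_shifts_girls(self, english_coefficients):
        p = Participant("x", "s", Stage.SECONDARY, sex=1)
        pct = predict_percent(english_coefficients[Group.IN_SCHOOL], p, 3.0)
        assert pct == pytest.approx(35.65 - 11.34)  # 24.31

    def test_negative_predictor_clips_to_zero(self):
        c = CalibrationCoefficients(Group.WEEKEND, -50, -50, 0, 1, 1)
        p = Participant("x", "s", Stage.PRIMARY, sex=0)
        assert predict_percent(c, p, 2.0) == 0.0

    def test_undefined_composite_propagates_nan(self, english_coefficients):
        p = Participant("x", "s", Stage.PRIMARY, sex=0)
        assert np.isnan(predict_percent(english_coefficients[Group.WEEKEND], p, float("nan")))

    def test_affine_and_monotone_in_composite(self, english_coefficients):
        c = english_coefficients[Group.OUT_OF_SCHOOL]
        p = Participant("x", "s", Stage.SECONDARY, sex=0)
        vals = [predict_percent(c, p, comp) for comp in (1, 2, 3, 4, 5)]
        diffs = np.diff(vals)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, diffs[0])  # constant increment: affine


class TestMinuteConversion:
    def test_weekend_percent_to_minutes(self):
        weekly, daily = percent_to_minutes(35.0, 1800.0, Group.WEEKEND)
        assert (weekly, daily) == (630.0, 315.0)

    def test_school_week_daily_divisor(self):
        assert weekly_to_daily(17.2, Group.IN_SCHOOL) == pytest.approx(3.44)

    def test_zero_percent_is_zero_minutes(self):
        assert percent_to_minutes(0.0, 1200.0, Group.IN_SCHOOL)[0] == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            percent_to_minutes(10.0, 0.0, Group.IN_SCHOOL)


def test_per_question_pathway_sums_item_minutes():
    p = Participant("x", "s", Stage.PRIMARY, sex=0)
    percents = {1: 10.0, 2: 20.0, 3: 50.0}
    weekly = apply_per_question(
        lambda q, score, part: percents[q] * score / 3.0,
        items={1: 3, 2: 3, 3: 0},
        item_durations={1: 300.0, 2: 150.0, 3: 100.0},
        participant=p,
    )
    assert weekly == pytest.approx(0.10 * 300 + 0.20 * 150)  # item 3 scored 0


def test_coefficient_round_trip(tmp_path, english_coefficients):
    path = tmp_path / "coeffs.json"
    save_coefficients(english_coefficients, path)
    loaded = load_coefficients(path)
    for group, coeffs in english_coefficients.items():
        for name in COEF_NAMES:
            assert getattr(loaded[group], name) == getattr(coeffs, name)
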
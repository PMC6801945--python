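# yapcal

Calibration and validation of a 15-item youth activity-recall questionnaire
(the Youth Activity Profile structure) against minute-level wearable MET
estimates, for school-based physical-activity surveillance.

Self-reported activity in young people is systematically overestimated.  A
practical fix is *calibration*: regress device-measured behaviour on the
self-report so that questionnaire scores can stand in for devices at scale.
This package implements that pipeline end to end:

- **Segmentation** — minute-level MET records are classified (MVPA at
  ≥ 4.0 METs, sedentary at ≤ 2.0 METs), allocated to ten schedule-derived
  clock windows of the week (travel, break, PE, lunch, after-school,
  evening, Saturday, Sunday), filtered by wear compliance (≥ 70 % of the
  segment worn on ≥ 3 days; 1 day for PE and weekends), and aggregated to
  weekly minutes and percent time per segment group.
- **Scoring** — 15 Likert items (1–5; 0 = "did not occur" for break/PE/lunch)
  reduce to four composite scores: in-school (items 1–5), out-of-school
  (6–8), weekend (9–10), and out-of-school sedentary behaviour (11–15).
- **Calibration** — median (τ = 0.5) quantile regression of device percent
  time on school stage, sex, and composite score:

  `percent ~ β_P·1[primary] + β_S·1[secondary] + β_sex·sex + β_YAP×P·(score·1[primary]) + β_YAP×S·(score·1[secondary])`

  A published English coefficient set ships with the package; fitting your
  own from a calibration sample is the default pathway.
- **Validation** — student-level r and MAPE, school-level bias, and
  expanding ±10 %, 15 %, 20 %… equivalence zones on 90 % confidence
  intervals for predicted weekly minutes.
- **Classification** — compliance with the 60 min·day⁻¹ and
  30 min·school-day⁻¹ MVPA guidelines, summarised by percent agreement,
  Cohen's κ, sensitivity and specificity against the device criterion.
- **Synthetic cohorts** — a generator producing rosters, timetables,
  minute-level MET streams and questionnaire responses with exactly the
  statistical structure the calibration assumes, so every stage is testable
  without field data.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1     # 324 participants, 9 schools
python analysis/02_segment_and_score.py
python analysis/03_fit_calibration.py --seed 1
python analysis/04_validate_agreement.py
python analysis/05_classify_guidelines.py
```

The final two steps print (seed 1):

```
           group  n_students  pearson_r  mape_percent  bias_mean  bias_sd  equivalence_zone_percent
       in_school         108       0.83         25.11       3.32    14.33                        10
   out_of_school         108       0.61         64.01     -27.40     9.34                        15
         weekend         108       0.31        106.50      10.41    54.70                        10
sb_out_of_school         108       0.91         15.38     -10.89    42.58                        10
whole_day_60min: ... agreement=94.4%  kappa=0.28  sens=99%  spec=22%
school_day_30min: ... agreement=95.4%  kappa=0.70  sens=98%  spec=67%
```

Read this as: on a held-out third of schools, school-level weekly-minute
bias is small relative to the observed means and the predictions sit inside
a 10–15 % equivalence zone, while *student-level* error (MAPE) is large —
calibrated self-report is a group-level surveillance instrument, not an
individual-level measure.  The guideline classifier shows the
characteristic pattern of high sensitivity and modest specificity in an
active cohort.  `analysis/06_parameter_recovery.py` additionally shows that
median regression recovers a known generating coefficient set to well
within two standard errors at realistic noise.

The same chain is available as a CLI (`yapcal simulate|segment|score|
calibrate|predict|validate|classify|run-all`) and as a single library call
(`yapcal.run_pipeline`).

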
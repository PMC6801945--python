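# Methods

## The calibration problem

A 15-item, 7-day-recall questionnaire asks young people about their
activity in specific clock segments of the week.  A body-worn monitor
provides minute-level MET estimates over the same week.  Calibration maps
the questionnaire's composite segment scores onto the device-measured
percent of segment time spent in MVPA (≥ 4.0 METs) or sedentary behaviour
(≤ 2.0 METs), so that, once calibrated, the questionnaire alone yields
weekly minute estimates.

Both cut-points are inclusive and configurable; 4.0/2.0 METs are the
conventional youth thresholds and the defaults throughout.

## Temporal matching

Each school day contributes eight windows anchored to the school timetable:
the 30 minutes before school start (travel to school), the hour before that
(before travel), break/PE/lunch as timetabled, the 30 minutes after school
end (travel from school), travel end to 18:00 (after school), and
18:00–22:00 (evening).  Weekend days contribute one 07:00–22:00 window
each.  Windows are half-open `[start, end)` on minute boundaries so that
adjacent windows (e.g. at 18:00) never double-count an epoch.  Travel
windows are anchored to school start/end rather than to a reported travel
time; an after-school window emptied by a late school end is omitted with a
warning.  Minutes absent from the record are treated as off-body — there is
no imputation; the wear-compliance rule is the only guard against
undercounting.

**Compliance.**  A segment-day is valid when the device was worn for at
least 70 % of the window's duration (boundary inclusive).  A participant's
segment enters the weekly estimate only with ≥ 3 valid days, relaxed to
≥ 1 day for PE and each weekend day, which occur at most once or twice per
week.  Weekly segment minutes are the mean over valid days multiplied by
the scheduled weekly occurrences; valid partial-wear days are *not*
rescaled to full duration (a sensitivity-analysis candidate).  Segment
groups (in-school = items 1–5, out-of-school = 6–8, weekend = 9–10) are
valid only when every scheduled member segment survived compliance; percent
time divides pooled weekly minutes by the pooled scheduled duration.

**Sedentary group windows.**  The sedentary items (11–15) carry no clock
windows of their own.  The device-side criterion counts SB minutes in the
weekday out-of-school windows (travel-from-school, after-school, evening) —
the same windows as the out-of-school MVPA group.  This is a design choice:
typical out-of-school SB levels (~55 % of a ~1,950-minute weekday
out-of-school week) are consistent with observed weekly SB magnitudes,
whereas folding in the 1,800-minute weekend would imply implausibly low SB
percentages.

## Questionnaire scoring

Items are Likert 1–5; items 3–5 (break, PE, lunch) may be 0 when the
opportunity did not occur that week.  Responses with missing, non-integer,
out-of-range, or illegally zero items are excluded (with reasons), not
errors.  A group composite is the unweighted mean of its member items with
0-items dropped from both the mean and the matched weekly duration: an
opportunity that never occurred contributes neither score nor time.  The
sedentary composite uses all five SB items equally, including the
overall-SB item.  A composite whose member items are all 0 is flagged
undefined and propagates as a missing prediction, never as a silent zero.

## The calibration model

Per segment group, device percent time is regressed on school stage,
sex, and the composite score with stage-specific intercepts and
stage-specific composite slopes and no global intercept:

    percent = β_P·1[primary] + β_S·1[secondary] + β_sex·sex
              + β_YAP×P·score·1[primary] + β_YAP×S·score·1[secondary] + ε

fitted by quantile regression at τ = 0.5 (median), i.e. minimising the
check loss Σ ρ_τ(residual).  The median is the standard calibration choice:
it balances positive and negative residuals (to within the parameter
count) and is robust to the floor/ceiling clipping that percent outcomes
exhibit.  Sex is coded 0 = boy, 1 = girl, so the usual lower girls' MVPA
appears as a negative β_sex.  Composites enter raw (uncentred).  The solver
is statsmodels `QuantReg` (IRLS), with kernel-based standard errors; model
accuracy is summarised by the RMSE of fitted vs observed percent.  Designs
with a missing stage, a within-stage constant composite, or fewer than 10
rows raise a model error naming the deficiency rather than returning a
non-unique solution.

Predictions clip to [0, 100] percent (the model itself can stray outside on
extreme scores).  Percent converts to weekly minutes through the
participant's scheduled group duration, and to daily minutes by dividing by
5 for school-week groups and 2 for the weekend.  A generic per-question
pathway (apply a pluggable per-question percent function, then the same
duration arithmetic) supports externally published per-question coefficient
sets; none ship with the package.  The published English four-group set
ships as `yapcal/data/english_coefficients.json`.

## Validation and classification

Schools are split, stratified by stage, into calibration (2/3) and
cross-validation (1/3) arms by a seeded draw recorded in the run manifest.
Student-level agreement is the Pearson correlation plus MAPE (over pairs
with nonzero device minutes only).  School-level bias is the mean and SD of
per-school (predicted − observed) unweighted means.  Equivalence testing
computes the 90 % t-interval of student-level predicted minutes in the
cross-validation arm (mean ± t₀.₉₅,ₙ₋₁·SE — the CI construction is our
choice; the convention is not fixed in the surrounding literature) and asks
whether it lies inside ±z % of the observed mean, expanding z from 10 % in
5-point steps to at most 50 %; containment is closed at the boundaries.

Guideline classification averages predicted and observed MVPA to
min·day⁻¹ (whole-day: in-school + out-of-school + weekend weekly minutes
over 7 days — the divisor is configurable) and min·school-day⁻¹ (in-school
over 5), flags compliance at 60 and 30 min respectively (≥, attainment
counts), and reports percent agreement, Cohen's κ with chance agreement
from marginal products, sensitivity and specificity with device flags as
the criterion.

## The synthetic cohort generator

The generator exists so that every stage can be exercised, and the whole
pipeline round-tripped, without field data.  Defaults mirror the motivating
study design: 9 schools (4 primary, 5 secondary), 36 pupils per school, a
5-weekday + Saturday + Sunday recall week, timetables with per-school start
and end times, daily break and lunch, and two PE lessons per week.

Per participant and segment group, a latent composite is drawn uniformly on
[1, 5] (`composite_grid=True` restricts to the integers 1–5, making Likert
rounding lossless — used for exactness checks).  True percent time is the
generating coefficient set's linear predictor plus Gaussian noise
(`percent_noise_sd`, default 8 percent points), clipped to [0, 100].
Because out-of-school MVPA and SB occupy the same clock windows, the two
latents are redrawn until their noiseless linear predictors sum to ≤ 100 %,
and the noisy SB percent is capped at the remaining share — activity and
sitting compete for the same minutes, and the redraw encodes that negative
dependence while keeping the retained truth exactly linear.

Minute streams realise the truth by **quota (error-diffusion) allocation**:
within each group, cumulative MVPA (and SB) minute counts track
`fraction × window length` to within one minute across the week, while the
placement of active minutes inside each window is randomised.  The
expected worn-minute MVPA fraction therefore equals the target exactly and
the realised weekly total differs from it only by integer rounding —
i.i.d. Bernoulli draws would instead leave ~binomial noise of several
minutes per week, swamping exactness checks.  MET values are drawn
uniformly within class-respecting ranges (MVPA 4–9, light 2.2–3.8, SB
0.9–2.0); unsegmented minutes get a fixed mostly-sedentary background
mixture; non-wear is i.i.d. per minute at `nonwear_rate` (default 5 %).
Questionnaire items equal the group latent plus Gaussian noise
(`likert_noise_sd`, default 0.5), rounded and truncated to {1..5};
break/PE/lunch items are 0 when the week's timetable lacks the window.

What the generator does **not** emulate: bout structure and within-day
autocorrelation of activity, structured (e.g. overnight or swimming-lesson)
non-wear, seasonal variation, recall biases that correlate with activity
level, and school-level clustering beyond the shared timetable.  Passing
tests therefore demonstrate that the pipeline arithmetic, model fitting and
reporting are correct under the assumed structure — not that the published
coefficient values are accurate for any real population.

## Numerical choices and degenerate inputs

- Duplicate (participant, date, minute) records and negative or non-finite
  METs are data errors, never silently cleaned.
- Division by a zero scheduled duration flags the estimate invalid instead
  of propagating NaN.
- An all-identical criterion in classification leaves sensitivity or
  specificity NaN (flagged), not an exception.
- Zero-variance vectors make Pearson r undefined (flagged).
- QuantReg is run with `max_iter=5000`; exact-fit warnings on noiseless
  data are suppressed, and missing standard errors on degenerate designs
  become NaN.

## Problem sizes

The analysis scripts and acceptance runs use the default 9 × 36 cohort
(~3.3 million minute rows, a few seconds end to end); parameter-recovery
studies use 200 rows per outcome, matching the scale at which the
calibration sample sizes make the model identifiable.

## Known limitations

- The composite construction (unweighted mean, 0-items dropped) and the
  sedentary-group window choice are conventions; alternative weightings
  would change fitted coefficients.
- The equivalence CI is a plain t-interval on student-level predictions;
  no clustering adjustment by school is applied.
- Whole-day guideline averaging uses a 7-day divisor by default; 5-day
  conventions exist and the divisor is exposed in configuration.
- Reported agreement statistics on synthetic cohorts characterise the
  method, not any real population.
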
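"""Guideline-compliance classification of predicted vs device daily MVPA.

Computes average MVPA min/day (whole day, over 7) and min/school-day (over
5) for predicted and device estimates on the full analytic sample, flags
compliance with the 60 min/day and 30 min/school-day recommendations, and
reports percent agreement, kappa, sensitivity and specificity with the
device flags as criterion.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from yapcal.classification import classification_report, daily_averages

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

rows = pd.read_csv(args.out / "predictions.csv", dtype={"participant_id": str})
obs_daily = daily_averages(rows).set_index("participant_id")
pred_daily = daily_averages(
    rows.assign(weekly_minutes=rows["predicted_weekly_minutes"])
).set_index("participant_id")
joined = obs_daily.join(pred_daily, lsuffix="_obs", rsuffix="_pred")

report = {
    "whole_day_60min": dataclasses.asdict(classification_report(
        joined["whole_day_pred"], joined["whole_day_obs"], 60.0)),
    "school_day_30min": dataclasses.asdict(classification_report(
        joined["school_day_pred"], joined["school_day_obs"], 30.0)),
}
(args.out / "classification.json").write_text(json.dumps(report, indent=2, default=float))

for label, rep in report.items():
    print(f"{label}: n={rep['n']} prevalence pred/obs = "
          f"{rep['prevalence_pred']:.1f}%/{rep['prevalence_obs']:.1f}%  "
          f"agreement={rep['percent_agreement']:.1f}%  kappa={rep['kappa']:.2f}  "
          f"sens={rep['sensitivity']:.0f}%  spec={rep['specificity']:.0f}%")
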
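"""Cross-validate the fitted equations: predictions, bias, equivalence zones.

Applies the fitted coefficient set to the cross-validation arm, converts
percent predictions to weekly minutes through each participant's scheduled
durations, and reports student-level (r, MAPE) and school-level (bias,
expanding equivalence zone) agreement per segment group.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from yapcal import io as _io
from yapcal.agreement import validation_report
from yapcal.calibration import load_coefficients, predict_percent
from yapcal.types import Group

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

roster = {p.id: p for p in _io.read_roster(args.cohort / "roster.csv")}
device = pd.read_csv(args.out / "device_weekly.csv", dtype={"participant_id": str})
scores = pd.read_csv(args.out / "composites.csv", dtype={"participant_id": str})
split = json.loads((args.out / "school_split.json").read_text())
coeffs = load_coefficients(args.out / "fitted_coefficients.json")

rows = device.merge(scores, on=["participant_id", "group"], suffixes=("_device", "_score"))
rows["school_id"] = rows["participant_id"].map(lambda p: roster[p].school_id)
rows["arm"] = rows["school_id"].map(split)
rows = rows[rows["valid"] & rows["defined"]]
rows["predicted_weekly_minutes"] = [
    predict_percent(coeffs[Group(r["group"])], roster[r["participant_id"]], r["score"])
    / 100.0 * r["weekly_duration_min_score"]
    for _, r in rows.iterrows()
]
rows.to_csv(args.out / "predictions.csv", index=False)

cv = rows[rows["arm"] == "cross_validation"]
table = []
for group in Group:
    sub = cv[cv["group"] == group.value]
    paired = pd.DataFrame({"pred": sub["predicted_weekly_minutes"],
                           "obs": sub["weekly_minutes"],
                           "school_id": sub["school_id"]})
    table.append(validation_report(paired, group.value))
validation = pd.DataFrame(table)
validation.to_csv(args.out / "validation.csv", index=False)

cols = ["group", "n_students", "pearson_r", "mape_percent",
        "bias_mean", "bias_sd", "equivalence_zone_percent"]
print(validation[cols].to_string(index=False,
      float_format=lambda v: f"{v:.2f}"))
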
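"""Split schools and fit the four quantile-regression calibration equations.

Schools are allocated, stratified by stage, into calibration (2/3) and
cross-validation (1/3) arms; median regression of device percent time on
stage, sex and the composite score is fitted per segment group on the
calibration arm only.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from yapcal import io as _io
from yapcal.calibration import fit_median_regression, save_coefficients
from yapcal.pipeline import split_schools
from yapcal.types import Group

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

roster = _io.read_roster(args.cohort / "roster.csv")
device = pd.read_csv(args.out / "device_weekly.csv")
scores = pd.read_csv(args.out / "composites.csv", dtype={"participant_id": str})
roster_df = pd.read_csv(args.cohort / "roster.csv", dtype={"participant_id": str})

split = split_schools(roster, 2 / 3, args.seed)
(args.out / "school_split.json").write_text(json.dumps(split, indent=2))
print("school split:", {arm: sorted(s for s, a in split.items() if a == arm)
                        for arm in ("calibration", "cross_validation")})

rows = device.merge(scores, on=["participant_id", "group"], suffixes=("_device", "_score"))
rows = rows.merge(roster_df, on="participant_id")
rows["arm"] = rows["school_id"].map(split)
cal = rows[(rows["arm"] == "calibration") & rows["valid"] & rows["defined"]]

reports = {}
for group in Group:
    sub = cal[cal["group"] == group.value].rename(columns={"score": "composite"})
    rep = fit_median_regression(sub[["percent_time", "composite", "stage", "sex"]], group)
    reports[group] = rep
    print(f"{group.value:18s} n={rep.n_used:3d} rmse={rep.rmse:5.2f}%  "
          + "  ".join(f"{k}={v:7.2f}" for k, v in rep.coefficients.as_dict().items()
                      if k != "outcome"))
save_coefficients(reports, args.out / "fitted_coefficients.json")
print(f"wrote coefficient set -> {args.out/'fitted_coefficients.json'}")
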
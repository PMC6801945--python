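"""Segment minute records into weekly device estimates and score the questionnaires.

Applies the MET cut-points (MVPA >= 4.0, SB <= 2.0), the schedule windows,
and the wear-compliance rule (>= 70% of segment duration on >= 3 days;
1 day for PE and weekend), then aggregates to weekly segment-group
estimates.  Questionnaire responses are validated and reduced to composite
scores with their matched weekly durations.
"""

import argparse
from pathlib import Path

import pandas as pd

from yapcal import io as _io
from yapcal.scoring import score_responses
from yapcal.segments import ComplianceRule, device_weekly_estimates

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

minutes, quarantined = _io.read_minutes(args.cohort / "minutes.csv")
schedules = _io.read_schedules(args.cohort / "schedules.yaml")
roster = _io.read_roster(args.cohort / "roster.csv")
responses = _io.read_yap(args.cohort / "yap.csv")

frames = []
for school_id in sorted(schedules):
    pids = [p.id for p in roster if p.school_id == school_id]
    sub = minutes[minutes["participant_id"].isin(pids)]
    frames.append(device_weekly_estimates(sub, schedules[school_id],
                                          ComplianceRule(), participants=pids))
device_weekly = pd.concat(frames, ignore_index=True)
device_weekly.to_csv(args.out / "device_weekly.csv", index=False)

roster_df = pd.read_csv(args.cohort / "roster.csv")
scores, exclusions = score_responses(responses, schedules, roster_df)
scores.to_csv(args.out / "composites.csv", index=False)
exclusions.to_csv(args.out / "exclusions.csv", index=False)

n_valid = device_weekly[device_weekly["valid"]]["participant_id"].nunique()
print(f"segmented {len(minutes):,} minute rows ({len(quarantined)} quarantined)")
print(f"{n_valid}/{len(roster)} participants retain >= 1 valid segment group")
print(f"scored {scores['participant_id'].nunique()} questionnaires; "
      f"{len(exclusions)} excluded")
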
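"""Generate the synthetic study cohort and write its raw input files.

Emulates the field design: 9 schools (4 primary, 5 secondary), ~36 pupils
per school, one recall week of minute-level MET records, school timetables,
a roster, and 15-item questionnaire responses.  Downstream scripts read
these files exactly as they would read field data.
"""

import argparse
from pathlib import Path

from yapcal import io as _io
from yapcal.simulate import GeneratorConfig, generate_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

cohort = generate_dataset(GeneratorConfig(seed=args.seed))
args.out.mkdir(parents=True, exist_ok=True)
_io.write_minutes(cohort.minutes, args.out / "minutes.csv")
_io.write_roster(cohort.roster, args.out / "roster.csv")
_io.write_yap(cohort.responses, args.out / "yap.csv")
_io.write_schedules(cohort.schedules, args.out / "schedules.yaml")
cohort.truth.to_csv(args.out / "truth.csv", index=False)

n_primary = sum(1 for p in cohort.roster if p.stage.value == "primary")
print(f"cohort: {len(cohort.roster)} participants "
      f"({n_primary} primary, {len(cohort.roster) - n_primary} secondary) "
      f"across {len(cohort.schedules)} schools")
print(f"minute records: {len(cohort.minutes):,} rows -> {args.out/'minutes.csv'}")
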
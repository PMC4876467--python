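#!/usr/bin/env python
"""Baseline characteristics of injured vs uninjured patients.

Crude injury rate and the conventional group-comparison table (chi-square
when expected counts allow, Fisher's exact otherwise; Welch's t for age).
"""

import argparse
from pathlib import Path

from tli_ntcp import read_cohort, cohort_to_frame, crude_rate
from tli_ntcp.stats import baseline_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

df = cohort_to_frame(read_cohort(args.outdir / "cohort.csv"))
patients = df.groupby("patient_id")["event"].max()
print(f"crude injury rate: {int(patients.sum())}/{patients.size} patients "
      f"= {crude_rate(int(patients.sum()), int(patients.size))}%")

table = baseline_table(df)
table.to_csv(args.outdir / "baseline_table.csv", index=False)
print(table.round(3).to_string(index=False))
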
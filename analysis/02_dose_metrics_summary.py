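#!/usr/bin/env python
"""Summarise the dose-volume variables by injury status.

Reproduces the conventional per-variable mean/min/max table for lobes with
and without injury, plus the Spearman rank-correlation matrix of all 19
candidate predictors that motivates penalized (grouped) selection.
"""

import argparse
from pathlib import Path

import pandas as pd

from tli_ntcp import read_cohort, cohort_to_frame
from tli_ntcp.coxnet import PredictorMatrix, spearman_matrix
from tli_ntcp.dvh import DoseMetrics

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

df = cohort_to_frame(read_cohort(args.outdir / "cohort.csv"))
rows = []
for var in DoseMetrics.COLUMNS:
    for label, sub in (("without_tli", df[df.event == 0]),
                       ("with_tli", df[df.event == 1])):
        rows.append({"variable": var, "group": label, "mean": sub[var].mean(),
                     "min": sub[var].min(), "max": sub[var].max()})
summary = pd.DataFrame(rows)
summary.to_csv(args.outdir / "dose_metrics_summary.csv", index=False)

rho = spearman_matrix(PredictorMatrix.from_cohort(df))
rho.to_csv(args.outdir / "spearman_matrix.csv")

hot = rho.loc["d_max", ["d_0.1cc", "d_1cc", "d_5cc"]]
print(f"wrote {args.outdir/'dose_metrics_summary.csv'} and spearman_matrix.csv")
print("hot-spot rank correlations with d_max:",
      ", ".join(f"{k} = {v:.2f}" for k, v in hot.items()))
wide = summary.pivot(index="variable", columns="group", values="mean").round(1)
print(wide.loc[["d_max", "d_1cc", "mean_dose", "v_40"]])
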
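"""Variance partitioning: repeatability, predictability, correlations.

Summarizes the posterior into per-trait repeatability and predictability-CV
with 95% credible intervals, per-calf behavioral types and rIIV, and the 15
among-individual correlations (flagging those whose CrI excludes zero).
"""

import argparse
from pathlib import Path

import pandas as pd

from calfvar import metrics
from calfvar.dhglm import PosteriorDraws

ap = argparse.ArgumentParser()
ap.add_argument("--draws", type=Path, default=Path("results/draws"))
ap.add_argument("--daily", type=Path, default=Path("results/daily_features.csv"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

draws = PosteriorDraws.load(args.draws)
daily = pd.read_csv(args.daily)
report = metrics.VarianceReport(draws, daily=daily)
report.to_json(args.out / "variance_report.json")
report.summary_table().to_csv(args.out / "summary_table.csv", index=False)

print(report.summary_table().to_string(index=False))
sig = report.correlations[report.correlations["significant"]]
if len(sig):
    print("\ncorrelations whose 95% CrI excludes zero:")
    for _, row in sig.iterrows():
        print(f"  {row.effect_1} x {row.effect_2}: "
              f"{row['median']:.2f} [{row.cri_low:.2f}, {row.cri_high:.2f}]")
else:
    print("\nno correlation CrI excludes zero")
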
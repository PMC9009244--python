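"""Ridge figures of behavioral types and rIIV, and the rate-meals correlation."""

import argparse
from pathlib import Path

import pandas as pd

from calfvar import metrics, report
from calfvar.dhglm import PosteriorDraws

ap = argparse.ArgumentParser()
ap.add_argument("--draws", type=Path, default=Path("results/draws"))
ap.add_argument("--daily", type=Path, default=Path("results/daily_features.csv"))
ap.add_argument("--out", type=Path, default=Path("results/figures"))
args = ap.parse_args()

draws = PosteriorDraws.load(args.draws)
rep = metrics.VarianceReport(draws, daily=pd.read_csv(args.daily))
args.out.mkdir(parents=True, exist_ok=True)
for component in ("behavioral_type", "riiv"):
    p = report.make_ridge_figure(rep, args.out / f"{component}.png", component)
    print("wrote", p)
p = report.make_correlation_figure(
    draws, ("alpha_feeding_rate", "alpha_total_meals"),
    args.out / "correlation_rate_meals.png")
print("wrote", p)
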
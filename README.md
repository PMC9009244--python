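# calfvar

Between- and within-individual variation in the feeding behavior of
pre-weaned dairy calves, quantified from automatic-milk-feeder visit logs.

Computerized milk feeders log every visit a calf makes (identity, entry and
exit times, entitlement, milk consumed, feeding rate). From such logs one
can ask two questions that matter for precision-livestock monitoring and
for animal-personality research: do calves differ consistently in their
*average* feeding behavior (behavioral types), and do they differ in how
*variable* they are around their own average (predictability)? `calfvar`
answers both with a multivariate double-hierarchical Gaussian model (DHGLM)
fitted by MCMC, on synthetic feeder logs with known ground truth.

The pipeline:

1. **simulate** (`calfvar.feeder_sim`) — visit logs for 4 cohorts × 16
   calves × 35 days under the real feeder's mechanics (2-L portions, 2-h
   entitlement lockout, 10-L daily allowance), driven by a latent daily
   trait layer with calf effects in both means and residual SDs;
2. **preprocess** (`calfvar.meals`) — estimate the meal criterion from the
   trimodal log inter-visit-interval distribution (Gaussian mixture +
   density-intersection solving), cluster visits into meals, compute daily
   feeding behaviors, apply exclusion filters (first 2 days, 33-day window,
   health score ≥ 5, impossible rows);
3. **transform** (`calfvar.transforms`) — log for total meals, ordered
   quantile normalization for meal size, z-scaling for all traits;
4. **fit** (`calfvar.dhglm`) — the multivariate DHGLM, sampled by a blocked
   Gibbs/slice scheme with split-R̂ and ESS diagnostics;
5. **report** (`calfvar.metrics`, `calfvar.report`) — repeatability
   `Rpt = V_CalfID / (V_CalfID + V_residual)`, coefficient of variation in
   predictability `CVp = sqrt(exp(ω²) − 1)`, per-calf behavioral types and
   rIIV, and the 6×6 among-individual correlation matrix, all with 95%
   credible intervals; ridge and correlation figures.

See `docs/methods.md` for the model, priors, sampler and generator details.

## Worked example

The numbered scripts under `analysis/` run the pipeline stage by stage:

```sh
python analysis/01_simulate.py --seed 0 --out results/data
python analysis/02_preprocess.py --data results/data --out results
python analysis/03_fit.py --daily results/daily_features.csv --out results --seed 0
python analysis/04_variance_report.py
python analysis/05_figures.py
```

A run with `--seed 0` (here with a reduced 2-chain fit) prints, after
preprocessing:

```
filters: 16 sick calves removed, 4 non-sensical rows, 48 calves retained
meal criterion estimated at 89 s (density intersections: [89, 1686] s)
17266 meals -> 1584 calf-day records written to results/daily_features.csv
```

— the criterion estimator found the two density intersections of the
log-interval mixture (≈ 100 s separates within-meal from between-meal
returns; ≈ 1,600 s separates short returns from post-lockout returns) —
and, after fitting:

```
       trait        mean      median       iqr  rpt   rpt_cri  cvp   cvp_cri
feeding_rate  831.744407  835.711364   769-898 0.57 0.45-0.70 0.27 0.21-0.37
 total_meals   10.900253   10.000000      8-13 0.44 0.33-0.56 0.10 0.02-0.17
   meal_size 1889.297607 1921.616667 1858-1963 0.04 0.01-0.08 0.02 0.00-0.08

correlations whose 95% CrI excludes zero:
  alpha_feeding_rate x alpha_total_meals: 0.39 [0.13, 0.65]
```

Reading the table: calves drink ~830 mL/min on average and take ~10 meals
a day. Feeding rate is highly repeatable (Rpt ≈ 0.5: half the variance is
between-calf) and calves differ in predictability (CVp ≈ 0.27); meal size
is barely repeatable (the feeder's portion cap and daily allowance leave
little room for preference); and calves that drink faster also take more
meals (positive behavioral-type correlation whose credible interval
excludes zero). The generator's true values are Rpt = (0.50, 0.42, 0.03),
CVp = (0.27, 0.13, 0.07) and correlation 0.29.

`python analysis/06_correlation_coverage.py` re-runs the correlation
recovery over 10 replicate studies and reports credible-interval coverage.

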
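# Methods

## The scientific question

Pre-weaned dairy calves feeding from a computerized milk feeder differ from
each other in two statistically separable ways: in their *average* behavior
(their **behavioral type**, the calf-level random intercept of a mixed
model) and in how *variable* they are around that average (their
**predictability**, the calf-level residual SD, often called residual
intra-individual variation or rIIV). This package quantifies both for three
daily feeding behaviors — feeding rate (mL/min), total meals per day, and
mean meal size (mL) — together with the among-individual correlations
between them, on synthetic feeder logs whose ground truth is known.

## The model

For trait `t`, calf `i`, cohort `c`, day `d`, with `y` the transformed and
z-scaled daily value:

```
y_tid  = x_id' β_t + g_tc + α_ti + ε_tid        ε_tid ~ N(0, σ_tid²)
log σ_tid = x_id' β_d,t + h_tc + δ_ti
```

where `x_id` holds an intercept, age at grouping, day number and the
age × day interaction (covariates standardized), `g`/`h` are cohort effects,
and the six calf effects `(α_i1, α_i2, α_i3, δ_i1, δ_i2, δ_i3)` are jointly
multivariate normal with SDs `(σ_α,1..3, ω_1..3)` and an unstructured 6×6
correlation matrix. This is a multivariate double-hierarchical generalized
linear model (DHGLM): random effects appear in both the mean sub-model and
the residual-variance (dispersion) sub-model. All response distributions are
Gaussian on the transformed scale.

Derived quantities, computed per posterior draw and summarized by the
median and equal-tailed 95% credible interval:

* **Repeatability** `Rpt_t = σ_α,t² / (σ_α,t² + V_res,t)` with
  `V_res,t = exp(β_d0,t)²` (the dispersion-model population intercept taken
  through its exponent and squared).
* **Coefficient of variation in predictability**
  `CVp_t = sqrt(exp(ω_t²) − 1)` — the CV of the lognormally distributed
  calf residual SDs. `ω² = 0` gives `CVp = 0`; the measure is unbounded
  above (values stay below 1 only while `ω² < ln 2 ≈ 0.69`), so we do not
  clamp it.
* **Among-individual correlations** are read from the 6×6 correlation-matrix
  parameter, never recomputed from point estimates of the calf effects —
  point-estimate correlations discard the uncertainty of the effects and
  overstate significance.
* **rIIV** per calf: `exp(β_d0,t + δ_ti)`.

### Transformations

Feeding rate is approximately Gaussian and enters untransformed. Total
meals is natural-log transformed; days with zero meals would map to −∞ and
are treated as missing (a configurable +1 offset is available; zero-meal
days essentially never occur under the default feeder settings). Meal size
is passed through an ordered quantile (rank-based inverse normal) transform
`Φ⁻¹((rank − 0.5)/n)` with average ranks for ties; the fitted monotone
mapping is stored so new values are transformed by interpolation and results
can be back-transformed. After transformation each trait is z-scaled
(mean 0, SD 1, n−1 denominator) globally over the analysis set. Rpt, CVp and
the correlations are invariant to this affine scaling.

### Priors and sampler

Priors are weakly informative on the standardized scale: N(0, 5²) on all
fixed effects, half-Student-t(3, 0, 2.5) on every SD, and a jointly uniform
prior over valid 6×6 correlation matrices.

No general-purpose probabilistic-programming backend is used; the package
ships its own blocked Metropolis-within-Gibbs sampler, built around the
model's structure:

* mean-part fixed effects, cohort effects and the per-calf 3-vector of
  behavioral types have conjugate Gaussian full conditionals given the
  current residual SDs (the behavioral-type update conditions on the
  dispersion effects through the 6-D joint prior);
* dispersion-part fixed effects, cohort effects and calf effects are
  updated by univariate slice sampling (stepping-out/shrinkage). The calf
  dispersion effects have sufficient statistics (per-calf counts and
  weighted residual sums of squares), so all calves update in one
  vectorized slice pass;
* effect SDs are slice-sampled on the log scale; correlation entries are
  slice-sampled one at a time under a positive-definiteness indicator,
  which together with the flat density realizes the jointly uniform prior
  exactly;
* two families of exact auxiliary moves break the posterior ridges that
  otherwise cripple mixing: *translation* moves between each intercept (and
  the age coefficient, which is constant within calf) and the random
  effects it is confounded with — likelihood-invariant shifts whose full
  conditionals are Gaussian in the priors alone — and *interweaved*
  (ancillarity-sufficiency) scale updates that resample every SD with the
  standardized effects held fixed. The hyperparameter block is cheap and
  runs twice per sweep.

Defaults are 4 chains × 2,000 iterations with 1,000 warmup (kept draws:
4 × 1,000); `long_mcmc()` preserves the long-run preset of 4 chains ×
12,000 iterations, 4,000 warmup, thinning 4. Convergence is monitored by
split-R̂ and bulk ESS (via arviz) with thresholds 1.01 and 400; parameters
violating them are listed in the returned diagnostics rather than silenced.
At the default settings the core parameters (fixed effects, σ_α, ω) satisfy
R̂ < 1.01 on the 48 × 33 design; correlation entries involving the weakly
identified dispersion effects have genuinely diffuse posteriors and mix more
slowly (R̂ up to ≈ 1.1) — they are flagged. There is no notion of divergent
transitions in a Gibbs/slice scheme; the diagnostics rely on R̂/ESS and
posterior-predictive summaries (moments and quantiles of replicated vs
observed data per trait). The total log-likelihood is stored per draw; the
per-observation matrix is not retained (it would dominate storage) and
posterior-predictive checks recompute what they need from the stored
parameters.

## The synthetic-data generator

The generator has two layers.

**Latent daily layer** — exactly the model above, with defaults chosen so
the implied truths equal the headline estimates being recovered:
`Rpt = (0.50, 0.42, 0.03)`, `CVp = (0.27, 0.13, 0.07)`, and a 0.29
correlation between the feeding-rate and total-meals behavioral types
(all other effect correlations zero). Concretely: residual-SD intercepts
(0.70, 0.20, 1.0 on the latent scales), `σ_α = (0.70, 0.170, 0.176)`,
`ω² = ln(1 + CVp²)`. Cohort SDs default to 0.10 (mean part) and 0.05
(dispersion part); age/day fixed-effect coefficients are small non-zero
values so the fixed-effect machinery is exercised. Latent values map to
feeder units monotonically: rate = 831 + 94·x mL/min, meals =
round(exp(x)) with a floor of 1 (x on the log scale, mean log 10), size =
2045 + 55·x + 8·x³ mL. Because Rpt, CVp and the correlations are invariant
to monotone/affine recoding plus the analysis-side transforms, the truths
survive the round trip to feeder units and back.

Calf effects are drawn with their *sample* moments matched exactly to the
target covariance (the `mvrnorm(empirical = TRUE)` convention, disabled
automatically for ≤ 6 calves and by `empirical_effects=False`). With 48
calves, an iid draw realizes a between-calf SD that wanders ±7% and a
correlation that wanders ±0.13 from the target; exact-moment draws make
recovery experiments measure estimator error rather than effect-realization
noise. Day-level residuals remain genuinely iid, so the dispersion part is
still estimated from noisy data.

**Mechanical visit layer** — each calf-day's latent total-meals value sets
the number of meal bouts; bouts are placed on the clock with exit-to-entry
gaps drawn from the between-meal components of a three-component lognormal
mixture, compressed proportionally on the rare days the plan would spill
past midnight; each bout is split into 1–3 visits (probabilities 0.50 /
0.35 / 0.15) with within-meal gaps from the first mixture component. The
feeder logic follows the real device: a bout is entitled when the calf is
outside the 2-h lockout and daily allowance (10 L) remains; an entitled
bout consumes up to one 2-L portion, scaled by a drain fraction tied to
the latent meal-size value; other bouts are zero-consumption unentitled
visits. Feeding rate is attached per consuming visit as the day's latent
rate with 2% measurement jitter. A quarter of calves receive a health score
≥ 5 (the exclusion threshold) and 4 rows are corrupted (exit before entry,
or negative consumption); corruption is injected outside the acclimatization
days and into healthy calves so the sanity rules — not the windowing or
health filter — see it.

The default gap mixture (log₁₀ means 1.04 / 2.75 / 3.63, SDs 0.35 / 0.28 /
0.28, weights 0.45 / 0.30 / 0.25) was solved numerically so its adjacent
weighted densities cross at ≈ 100 s and ≈ 1,600 s — the two intersections
the meal-criterion estimator is expected to find.

What the visit layer does *not* emulate: social displacement at the feeder
(competition appears only implicitly through unentitled visits), diurnal
feeding rhythms, day-to-day carryover, and drift in feeder calibration. One
emergent mechanic is worth knowing: after five full portions only ~0–300 mL
of allowance remains, so calves with many well-spaced bouts can collect a
small sixth entitled meal, which induces a *negative* mechanical correlation
between realized total meals and realized mean meal size in the visit-level
pipeline. This mirrors the constraint structure of the real feeder (which
is why meal-size repeatability is expected to be near zero) but means the
visit-level pipeline is not a clean recovery instrument for the meal-size
trait; recovery experiments therefore run on the latent daily layer, and
the visit layer is validated against its own ground-truth sidecar (bout
counts, filters, conservation of milk volume).

## Preprocessing

The meal criterion — the largest inter-visit gap still counted as
within-meal — is estimated by fitting a 3-component Gaussian mixture to
log₁₀ gap seconds (scikit-learn, 5 restarts) and solving numerically for
the gaps where adjacent weighted component densities are equal; the
criterion is the smallest intersection. This automates what is usually done
by eye on the log-interval histogram. Clustering is a greedy single pass:
a visit joins the open meal of the same calf iff its gap is *strictly*
below the criterion (a gap exactly at the criterion starts a new meal).
Daily features follow the field's definitions: total meals counts all
meals, entitled or not; meal size averages total consumption over entitled
consuming meals only; feeding rate averages visit-level rates over entitled
consuming visits (unweighted by default, consumption-weighted optionally).
Exclusion filters drop the first 2 days per cohort, keep the next 33,
remove calves whose health score reaches 5, and drop rows that are
physically impossible (exit before entry, negative consumption, more than
one 2,000-mL portion in a single visit, rate outside (0, 5,000] mL/min).
Missing daily values propagate as missing into the model — each trait's
likelihood term is dropped for that calf-day only.

## Problem sizes and numerical choices

Recovery experiments use the study design: 48 calves × 33 days × 4 cohorts,
fitted with 4 chains × 1,000 post-warmup draws (≈ 2 min on one CPU);
replicate and calibration checks in the test suite use reduced designs
(12–24 calves, 10–20 days, 2 chains) so the whole suite stays desk-scale.
Slice samplers use fixed initial widths (0.2–0.7 by block) — slice sampling
is robust to width misspecification, so no adaptation phase is needed.
Chains are initialized from least-squares fits with per-chain jitter.
Density intersections are solved with `brentq` at 1e−12 on the log₁₀ scale.
Degenerate cases: Rpt draws with both variances exactly zero are excluded
with a logged count; all-identical inputs to the ordered quantile transform
raise; a rank-deficient fixed-effect design raises an error naming the
collinear columns.

## Known limitations

* CVp recovery for weakly heterogeneous traits is shrunk toward zero: with
  33 days the per-calf information on log residual SD (SE ≈ 1/√(2·33) ≈
  0.12) is comparable to ω itself for total meals (0.13), and the posterior
  median of a weakly identified scale parameter sits below its mode. The
  effect is within the recovery tolerances but visible.
* Observation-level residuals are independent across traits given the calf
  effects; residual cross-trait correlations are not modeled (per-trait
  heteroscedastic residuals make them ill-defined here).
* The uniform prior over 6×6 correlation matrices concentrates pairwise
  marginals mildly toward zero (the PD constraint), which adds a little
  shrinkage to weakly identified correlation entries.
* Simulation-based calibration is run as a credible-interval coverage check
  at reduced scale rather than full rank-statistic SBC, which would require
  drawing hyperparameters from the (very diffuse) prior.
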
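"""Synthetic automatic-milk-feeder visit logs with known behavioral structure.

The generator has two layers:

* a latent daily layer — for every calf-day, three feeding traits (feeding
  rate, total meals, meal size) are drawn from a multivariate
  double-hierarchical Gaussian process: each calf carries a 6-vector of
  correlated random effects, three shifting its trait means ("behavioral
  types") and three shifting its log residual SDs ("predictability"), on top
  of cohort effects and age/day fixed effects;
* a mechanical visit layer — daily trait values are realized as feeder visit
  rows obeying the feeder's entitlement rules (2-L portions, 2-h lockout,
  10-L daily allowance), with meal bouts split into 1–3 visits and
  inter-visit gaps drawn from a three-component lognormal mixture.

Because the latent layer is recorded in a ground-truth sidecar, every
downstream stage (meal clustering, daily features, model fitting, variance
partitioning) can be tested against known values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

TRAITS = ("feeding_rate", "total_meals", "meal_size")

SECONDS_PER_DAY = 86_400

# covariate standardization constants used by the latent layer (age uniform
# on [21, 54] has mean 37.5, SD 33/sqrt(12))
_AGE_CENTER = 37.5
_AGE_SCALE = 33.0 / np.sqrt(12.0)


@dataclass(frozen=True)
class GapMixture:
    """Three-component lognormal mixture of inter-visit intervals.

    Parameterized on the log10-seconds scale. Component 0 holds within-meal
    gaps; components 1–2 hold short and long between-meal gaps (the long
    component reflects the 2-h entitlement lockout). Components must be
    ordered by median interval.
    """

    log10_means: tuple[float, ...] = (1.04, 2.75, 3.63)
    log10_sds: tuple[float, ...] = (0.35, 0.28, 0.28)
    weights: tuple[float, ...] = (0.45, 0.30, 0.25)

    def __post_init__(self) -> None:
        if not (len(self.log10_means) == len(self.log10_sds) == len(self.weights)):
            raise ValueError("gap mixture component lengths differ")
        if any(s <= 0 for s in self.log10_sds):
            raise ValueError("gap mixture SDs must be positive")
        if any(w <= 0 for w in self.weights):
            raise ValueError("gap mixture weights must be positive")
        if list(self.log10_means) != sorted(self.log10_means):
            raise ValueError("gap mixture components must be ordered by median interval")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def sample(self, n: int, rng: np.random.Generator,
               components: tuple[int, ...] | None = None) -> np.ndarray:
        """Draw ``n`` gaps in seconds, optionally restricted to a component subset."""
        idx = tuple(range(self.n_components)) if components is None else components
        w = np.array([self.weights[i] for i in idx], float)
        w /= w.sum()
        comp = rng.choice(len(idx), size=n, p=w)
        mu = np.array([self.log10_means[i] for i in idx])[comp]
        sd = np.array([self.log10_sds[i] for i in idx])[comp]
        return 10.0 ** rng.normal(mu, sd)

    def density_crossings(self) -> list[float]:
        """Seconds at which adjacent weighted component densities are equal.

        Solved numerically between adjacent component means; used as the
        analytic reference for the meal-criterion estimator.
        """
        w = np.asarray(self.weights, float) / np.sum(self.weights)
        out = []
        for j in range(self.n_components - 1):
            f = lambda x: (w[j] * norm.pdf(x, self.log10_means[j], self.log10_sds[j])
                           - w[j + 1] * norm.pdf(x, self.log10_means[j + 1], self.log10_sds[j + 1]))
            lo, hi = self.log10_means[j], self.log10_means[j + 1]
            if f(lo) * f(hi) < 0:
                out.append(float(10.0 ** brentq(f, lo, hi, xtol=1e-12)))
        return out


def _default_re_correlation() -> np.ndarray:
    # identity except a 0.29 correlation between the feeding-rate and
    # total-meals behavioral types (effect order: 3 means then 3 dispersions)
    r = np.eye(6)
    r[0, 1] = r[1, 0] = 0.29
    return r


@dataclass
class SimConfig:
    """Study conditions for the synthetic feeder experiment.

    Defaults emulate a 4-cohort barn of 16 calves each observed over 35 days
    of group housing, with a quarter of the calves flagged sick, a 10-L daily
    milk allowance dispensed in 2-L entitlements with a 2-h lockout, and trait
    variance components chosen so that the latent layer carries repeatability
    (0.50, 0.42, 0.03), predictability CV (0.27, 0.13, 0.07) and a 0.29
    among-calf correlation between the feeding-rate and total-meals
    behavioral types.
    """

    n_cohorts: int = 4
    calves_per_cohort: int = 16
    n_days: int = 35
    seed: int = 0

    # latent scale means: feeding rate / ORQ-size are centered at 0; total
    # meals lives on the natural-log scale (exp(2.30) ~ 10 meals/day)
    trait_means: tuple[float, ...] = (0.0, 2.3026, 0.0)
    # per trait: (age, day, age x day) coefficients on standardized covariates
    fixed_effect_coefs: tuple[tuple[float, ...], ...] = (
        (0.10, 0.05, 0.02),
        (0.08, -0.04, 0.01),
        (0.05, 0.03, 0.00),
    )
    dispersion_fixed_effect_coefs: tuple[tuple[float, ...], ...] = (
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
    )
    cohort_sd: float = 0.10
    cohort_sd_dispersion: float = 0.05
    # sigma_alpha per trait: SD of calf behavioral types
    between_sd: tuple[float, ...] = (0.70, 0.1702549, 0.1758640)
    # beta_d0 per trait: population intercept of log residual SD
    within_sd_intercept: tuple[float, ...] = (np.log(0.70), np.log(0.20), 0.0)
    # omega^2 per trait: variance of calf dispersion effects on the log-SD
    # scale; ln(1 + CVp^2) for CVp = (0.27, 0.13, 0.07)
    omega_sq: tuple[float, ...] = (
        float(np.log(1 + 0.27 ** 2)),
        float(np.log(1 + 0.13 ** 2)),
        float(np.log(1 + 0.07 ** 2)),
    )
    re_correlation: np.ndarray = field(default_factory=_default_re_correlation)

    sick_fraction: float = 0.25
    n_nonsense: int = 4
    # draw calf effects with their sample moments matched exactly to the
    # target covariance (the mvrnorm(empirical=TRUE) convention), so recovery
    # checks measure estimator error rather than effect-realization noise
    empirical_effects: bool = True
    gap_mixture: GapMixture = field(default_factory=GapMixture)

    age_range: tuple[int, int] = (21, 54)
    daily_allowance_ml: float = 10_000.0
    portion_ml: float = 2_000.0
    lockout_s: float = 2 * 3600.0
    visits_per_bout_probs: tuple[float, ...] = (0.50, 0.35, 0.15)
    rate_noise_cv: float = 0.02

    # observable mappings (latent -> feeder units)
    rate_loc_ml_min: float = 831.0
    rate_scale_ml_min: float = 94.0
    size_loc_ml: float = 2045.0
    size_scale_ml: float = 55.0

    def __post_init__(self) -> None:
        self.re_correlation = np.asarray(self.re_correlation, float)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_days < 3:
            raise ValueError("n_days < 3: cannot separate within-individual variance")
        if self.n_cohorts < 1 or self.calves_per_cohort < 1:
            raise ValueError("need at least one cohort and one calf")
        r = self.re_correlation
        if r.shape != (6, 6):
            raise ValueError("re_correlation must be 6x6")
        if not np.allclose(r, r.T):
            raise ValueError("re_correlation must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("re_correlation must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError("re_correlation is not positive semi-definite")
        for name, vals in (("between_sd", self.between_sd),
                           ("omega_sq", self.omega_sq)):
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} entries must be >= 0")
        if self.cohort_sd < 0 or self.cohort_sd_dispersion < 0:
            raise ValueError("cohort SDs must be >= 0")
        if not 0 <= self.sick_fraction <= 1:
            raise ValueError("sick_fraction must be in [0, 1]")

    # -- ground truth implied by the configuration --------------------------
    @property
    def effect_sds(self) -> np.ndarray:
        """SDs of the 6 calf effects: (sigma_alpha x3, omega x3)."""
        return np.concatenate([np.asarray(self.between_sd, float),
                               np.sqrt(np.asarray(self.omega_sq, float))])

    def true_rpt(self) -> dict[str, float]:
        out = {}
        for t, trait in enumerate(TRAITS):
            vb = self.between_sd[t] ** 2
            vw = np.exp(self.within_sd_intercept[t]) ** 2
            out[trait] = vb / (vb + vw) if (vb + vw) > 0 else float("nan")
        return out

    def true_cvp(self) -> dict[str, float]:
        return {trait: float(np.sqrt(np.exp(self.omega_sq[t]) - 1.0))
                for t, trait in enumerate(TRAITS)}


# ---------------------------------------------------------------------------
# latent daily layer
# ---------------------------------------------------------------------------

def _draw_calves(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_total = config.n_cohorts * config.calves_per_cohort
    n_sick = int(round(config.sick_fraction * n_total))
    sick_idx = set(rng.choice(n_total, size=n_sick, replace=False).tolist())
    k = 0
    for c in range(config.n_cohorts):
        for j in range(config.calves_per_cohort):
            age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
            score = int(rng.integers(5, 13)) if k in sick_idx else int(rng.integers(0, 5))
            rows.append({"calf_id": f"C{c + 1}-{j + 1:02d}",
                         "cohort_id": f"G{c + 1}",
                         "age_at_grouping": age,
                         "max_health_score": score})
            k += 1
    return pd.DataFrame(rows)


def simulate_daily(config: SimConfig, seed: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw the latent daily trait layer.

    Returns ``(daily, meta, truth)`` where ``daily`` has one row per calf-day
    with the three traits in feeder units (mL/min, meals/day, mL) plus
    covariates, ``meta`` is the calf table and ``truth`` records every latent
    quantity including the per-trait repeatability and predictability CV
    implied by the configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    meta = _draw_calves(config, rng)
    n_calves = len(meta)
    n_days = config.n_days

    # cohort effects, mean and dispersion part
    coh_mean = rng.normal(0.0, config.cohort_sd, size=(config.n_cohorts, 3))
    coh_disp = rng.normal(0.0, config.cohort_sd_dispersion, size=(config.n_cohorts, 3))

    # correlated calf effects: 3 behavioral types + 3 dispersion deviations
    sds = config.effect_sds
    cov = np.outer(sds, sds) * config.re_correlation
    u = rng.multivariate_normal(np.zeros(6), cov, size=n_calves,
                                method="svd")
    if config.empirical_effects and n_calves > 6:
        # rescale so the sample mean is 0 and the sample covariance equals
        # the target exactly (recovery-study convention)
        z = rng.standard_normal((n_calves, 6))
        z -= z.mean(axis=0)
        ec = np.cov(z, rowvar=False, ddof=1)
        z = z @ np.linalg.inv(np.linalg.cholesky(ec)).T
        jitter = 1e-10 * np.eye(6)
        u = z @ np.linalg.cholesky(config.re_correlation + jitter).T * sds
    alpha, delta = u[:, :3], u[:, 3:]

    age_z = (meta["age_at_grouping"].to_numpy() - _AGE_CENTER) / _AGE_SCALE
    day = np.arange(1, n_days + 1)
    day_z = (day - (n_days + 1) / 2.0) / (n_days / np.sqrt(12.0))
    coh_idx = meta["cohort_id"].str.slice(1).astype(int).to_numpy() - 1

    beta = np.asarray(config.fixed_effect_coefs, float)          # (3 traits, 3 coefs)
    beta_d = np.asarray(config.dispersion_fixed_effect_coefs, float)
    mean0 = np.asarray(config.trait_means, float)
    wsd0 = np.asarray(config.within_sd_intercept, float)

    # (calf, day, trait) latent values
    A = age_z[:, None, None]
    D = day_z[None, :, None]
    mu = (mean0[None, None, :] + beta[:, 0] * A + beta[:, 1] * D
          + beta[:, 2] * A * D
          + coh_mean[coh_idx][:, None, :] + alpha[:, None, :])
    log_sd = (wsd0[None, None, :] + beta_d[:, 0] * A + beta_d[:, 1] * D
              + beta_d[:, 2] * A * D
              + coh_disp[coh_idx][:, None, :] + delta[:, None, :])
    latent = mu + np.exp(log_sd) * rng.standard_normal((n_calves, n_days, 3))

    x_rate, x_meals, x_size = latent[..., 0], latent[..., 1], latent[..., 2]
    feeding_rate = np.maximum(50.0, config.rate_loc_ml_min
                              + config.rate_scale_ml_min * x_rate)
    total_meals = np.maximum(1, np.rint(np.exp(x_meals))).astype(int)
    meal_size = config.size_loc_ml + config.size_scale_ml * x_size + 8.0 * x_size ** 3

    base = pd.Timestamp("2021-06-01")
    frames = []
    for i in range(n_calves):
        frames.append(pd.DataFrame({
            "calf_id": meta["calf_id"].iloc[i],
            "cohort_id": meta["cohort_id"].iloc[i],
            "day_number": day,
            "date": [(base + pd.Timedelta(days=int(40 * coh_idx[i] + d - 1))).date().isoformat()
                     for d in day],
            "age_at_grouping": meta["age_at_grouping"].iloc[i],
            "feeding_rate": feeding_rate[i],
            "total_meals": total_meals[i],
            "meal_size": meal_size[i],
        }))
    daily = pd.concat(frames, ignore_index=True)

    truth = {
        "traits": list(TRAITS),
        "true_rpt": config.true_rpt(),
        "true_cvp": config.true_cvp(),
        "re_correlation": config.re_correlation.tolist(),
        "alpha": {meta["calf_id"].iloc[i]: alpha[i].tolist() for i in range(n_calves)},
        "delta": {meta["calf_id"].iloc[i]: delta[i].tolist() for i in range(n_calves)},
        "cohort_mean_effects": coh_mean.tolist(),
        "cohort_dispersion_effects": coh_disp.tolist(),
        "latent_mean_meals": float(np.mean(np.exp(x_meals))),
        "latent_daily": latent,       # ndarray (calf, day, trait); not JSON-serialized
    }
    return daily, meta, truth


# ---------------------------------------------------------------------------
# mechanical visit layer
# ---------------------------------------------------------------------------

def _realize_day(rng, config, day_start, n_bouts, rate_ml_min, frac_loc):
    """Place one calf-day's bouts on the clock under entitlement mechanics.

    Returns (visit rows, realized bout count).
    """
    gm = config.gap_mixture
    t0 = float(rng.uniform(0, 2 * 3600.0))
    between = gm.sample(max(n_bouts - 1, 0), rng, components=(1, 2)) if n_bouts > 1 else np.array([])
    # compress the exit-to-entry gap plan if it would spill past midnight
    # (keeps the bout count; ~200 s per bout is spent inside the feeder)
    budget = SECONDS_PER_DAY - t0 - 200.0 * n_bouts
    if between.size and between.sum() > budget:
        between *= max(budget, 3600.0) / between.sum()

    allowance = config.daily_allowance_ml
    next_entitled_at = 0.0
    rows = []
    t = t0
    for b in range(n_bouts):
        entitled = allowance > 0 and t >= next_entitled_at
        if entitled:
            frac = float(np.clip(frac_loc + 0.05 * rng.standard_normal(), 0.3, 1.0))
            consumed = float(min(config.portion_ml * frac, config.portion_ml, allowance))
            allowance -= consumed
        else:
            consumed = 0.0
        n_visits = 1 + rng.choice(len(config.visits_per_bout_probs),
                                  p=config.visits_per_bout_probs)
        shares = rng.dirichlet(np.ones(n_visits) * 4.0) if consumed > 0 else np.zeros(n_visits)
        within = gm.sample(n_visits - 1, rng, components=(0,)) if n_visits > 1 else np.array([])
        tv = t
        bout_end = t
        for v in range(n_visits):
            ml = consumed * shares[v] if consumed > 0 else 0.0
            rate = rate_ml_min * (1.0 + config.rate_noise_cv * rng.standard_normal()) if ml > 0 else 0.0
            dur = (ml / rate * 60.0 if ml > 0 and rate > 0 else 0.0) + float(rng.uniform(5, 45))
            rows.append((day_start + pd.Timedelta(seconds=tv),
                         day_start + pd.Timedelta(seconds=tv + dur),
                         bool(entitled), ml, max(rate, 0.0)))
            bout_end = tv + dur
            if v < n_visits - 1:
                tv += dur + float(within[v])
        if entitled and consumed > 0:
            next_entitled_at = bout_end + config.lockout_s
        if b < n_bouts - 1:
            t = bout_end + float(between[b])
    return rows, n_bouts


def simulate_dataset(config: SimConfig, seed: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the full visit-level feeder log.

    Builds on :func:`simulate_daily`: each calf-day's latent total-meals value
    sets the number of meal bouts, bouts are placed on the clock under the
    feeder's entitlement mechanics, each bout is split into 1–3 visits, and
    ``n_nonsense`` rows are corrupted to exercise the sanity filters.
    """
    daily, meta, truth = simulate_daily(config, seed)
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1_000_003)

    base = pd.Timestamp("2021-06-01")
    coh_idx = {g: i for i, g in enumerate(sorted(meta["cohort_id"].unique()))}
    records = []
    bout_counts = []
    for row in daily.itertuples(index=False):
        day_start = (base + pd.Timedelta(days=40 * coh_idx[row.cohort_id]
                                         + row.day_number - 1))
        # latent meal size sets how completely the calf drains its portions
        frac_loc = float(np.clip(0.97 + 0.03 * (row.meal_size - config.size_loc_ml)
                                 / config.size_scale_ml, 0.5, 1.0))
        visits, n_bouts = _realize_day(rng, config, day_start, int(row.total_meals),
                                       float(row.feeding_rate), frac_loc)
        bout_counts.append({"calf_id": row.calf_id, "date": row.date,
                            "n_bouts": n_bouts})
        for entry, exit_, entitled, ml, rate in visits:
            records.append({
                "calf_id": row.calf_id, "cohort_id": row.cohort_id,
                "date": row.date, "entry_time": entry, "exit_time": exit_,
                "entitled": entitled, "consumption": np.floor(ml * 10) / 10,
                "feeding_rate": round(rate, 1),
            })
    visits = pd.DataFrame(records)
    visits = visits.sort_values(["calf_id", "entry_time"], kind="mergesort").reset_index(drop=True)

    # corrupt a handful of rows to exercise the sanity filters; candidates are
    # restricted to healthy calves outside the first two (acclimatization)
    # days so the corrupted rows reach the sanity rules rather than being
    # removed earlier by the windowing or health filters
    healthy = set(meta.loc[meta["max_health_score"] < 5, "calf_id"])
    dates = pd.to_datetime(visits["date"])
    first = dates.groupby(visits["cohort_id"]).transform("min")
    candidates = visits.index[((dates - first).dt.days >= 2)
                              & visits["calf_id"].isin(healthy)].to_numpy()
    n_bad = min(config.n_nonsense, candidates.size)
    bad_idx = rng.choice(candidates, size=n_bad, replace=False)
    for j, i in enumerate(bad_idx):
        if j % 2 == 0:
            e, x = visits.at[i, "entry_time"], visits.at[i, "exit_time"]
            visits.at[i, "entry_time"] = x + pd.Timedelta(seconds=60)
        else:
            visits.at[i, "consumption"] = -100.0
    truth["bout_counts"] = pd.DataFrame(bout_counts)
    truth["n_bouts_total"] = int(sum(b["n_bouts"] for b in bout_counts))
    truth["nonsense_rows"] = sorted(int(i) for i in bad_idx)
    return visits, meta, truth


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

VISIT_COLUMNS = ["calf_id", "cohort_id", "date", "entry_time", "exit_time",
                 "entitled", "consumption", "feeding_rate"]


def write_dataset(outdir: str | Path, visits: pd.DataFrame, meta: pd.DataFrame,
                  truth: dict) -> None:
    """Write visits/metadata as CSV (ISO-8601 timestamps) and truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    v = visits.copy()
    for col in ("entry_time", "exit_time"):
        v[col] = pd.to_datetime(v[col]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    v[VISIT_COLUMNS].to_csv(outdir / "visits.csv", index=False)
    meta.to_csv(outdir / "calves.csv", index=False)
    clean = {}
    for k, val in truth.items():
        if isinstance(val, np.ndarray):
            continue
        if isinstance(val, pd.DataFrame):
            clean[k] = val.to_dict(orient="list")
        else:
            clean[k] = val
    (outdir / "truth.json").write_text(json.dumps(clean, indent=1, default=str))


def read_dataset(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    outdir = Path(outdir)
    visits = pd.read_csv(outdir / "visits.csv",
                         parse_dates=["entry_time", "exit_time"])
    meta = pd.read_csv(outdir / "calves.csv")
    truth = json.loads((outdir / "truth.json").read_text())
    return visits, meta, truth
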
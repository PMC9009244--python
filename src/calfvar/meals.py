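"""Meal clustering and daily feeding behaviors.

Feeder visits are noisy: the RFID reader can lose and regain contact within
a single feeding event, splitting one meal across several rows. Visits by
the same calf separated by less than a meal criterion (default 100 s) are
merged into meals. The criterion itself is estimated from the log-interval
distribution of consecutive visits, which is multimodal: a Gaussian mixture
is fitted on the log10 scale and the criterion taken as the lowest gap at
which adjacent weighted component densities are equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

DEFAULT_CRITERION_S = 100.0


# ---------------------------------------------------------------------------
# inter-visit intervals and criterion estimation
# ---------------------------------------------------------------------------

def compute_intervals(visits: pd.DataFrame) -> pd.DataFrame:
    """Gaps (seconds) between consecutive visits of the same calf.

    ``gap = next entry_time - previous exit_time``. Negative gaps
    (overlapping records) are dropped with a logged count; calves with a
    single visit contribute nothing.
    """
    v = visits.sort_values(["calf_id", "entry_time"], kind="mergesort")
    prev_exit = v.groupby("calf_id")["exit_time"].shift(1)
    gap = (v["entry_time"] - prev_exit).dt.total_seconds()
    out = pd.DataFrame({"calf_id": v["calf_id"], "gap_seconds": gap}).dropna()
    n_neg = int((out["gap_seconds"] < 0).sum())
    if n_neg:
        log.info("dropped %d negative (overlapping) inter-visit gaps", n_neg)
    return out[out["gap_seconds"] >= 0].reset_index(drop=True)


class MealCriterionError(RuntimeError):
    """Mixture fit failed to converge; carries the fitted parameters."""

    def __init__(self, msg: str, params: dict):
        super().__init__(msg)
        self.params = params


def estimate_meal_criterion(gaps, n_components: int = 3, seed: int = 0
                            ) -> tuple[float, list[float]]:
    """Estimate the meal criterion from positive inter-visit gaps.

    Fits an ``n_components`` Gaussian mixture to log10(gap seconds), then
    numerically solves for the gaps where adjacent weighted component
    densities are equal (searched between adjacent component means).

    Returns ``(criterion_s, intersections)`` where ``criterion_s`` is the
    smallest intersection, on the seconds scale.
    """
    gaps = np.asarray(gaps, float)
    gaps = gaps[np.isfinite(gaps) & (gaps > 0)]
    if gaps.size < 500:
        raise ValueError(f"need >= 500 positive gaps, got {gaps.size}")
    x = np.log10(gaps).reshape(-1, 1)
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         n_init=5, random_state=seed, max_iter=500)
    gm.fit(x)
    if not gm.converged_:
        raise MealCriterionError("Gaussian mixture did not converge",
                                 {"means": gm.means_.ravel().tolist(),
                                  "weights": gm.weights_.tolist()})
    order = np.argsort(gm.means_.ravel())
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.reshape(-1)[order])
    w = gm.weights_[order]

    intersections: list[float] = []
    for j in range(n_components - 1):
        f = lambda t: (w[j] * norm.pdf(t, mu[j], sd[j])
                       - w[j + 1] * norm.pdf(t, mu[j + 1], sd[j + 1]))
        lo, hi = mu[j], mu[j + 1]
        if hi - lo < 1e-9 or f(lo) * f(hi) >= 0:
            continue  # overlapping modes: no usable crossing between them
        intersections.append(float(10.0 ** brentq(f, lo, hi, xtol=1e-12)))
    if not intersections:
        raise MealCriterionError("no density intersections between component means",
                                 {"means": mu.tolist(), "sds": sd.tolist(),
                                  "weights": w.tolist()})
    return intersections[0], intersections


# ---------------------------------------------------------------------------
# clustering visits into meals
# ---------------------------------------------------------------------------

def cluster_meals(visits: pd.DataFrame,
                  criterion_s: float = DEFAULT_CRITERION_S) -> pd.DataFrame:
    """Greedy single-pass merge of same-calf visits into meals.

    A visit joins the open meal iff its gap to the previous visit is
    strictly below ``criterion_s``; a gap exactly equal to the criterion
    starts a new meal. Every visit belongs to exactly one meal.
    """
    v = visits.sort_values(["calf_id", "entry_time"], kind="mergesort").copy()
    prev_exit = v.groupby("calf_id")["exit_time"].shift(1)
    gap = (v["entry_time"] - prev_exit).dt.total_seconds()
    new_meal = gap.isna() | (gap >= criterion_s)
    v["meal_id"] = new_meal.cumsum().astype(int)

    consuming = v["consumption"] > 0
    rate = v["feeding_rate"].where(consuming)
    g = v.groupby("meal_id")
    meals = pd.DataFrame({
        "calf_id": g["calf_id"].first(),
        "cohort_id": g["cohort_id"].first(),
        "date": g["date"].first(),
        "start_time": g["entry_time"].min(),
        "end_time": g["exit_time"].max(),
        "n_visits": g.size(),
        "total_consumption": g["consumption"].sum(),
        "entitled": g["entitled"].any(),
        "mean_feeding_rate": rate.groupby(v["meal_id"]).mean(),
    }).reset_index()
    return meals


def daily_features(meals: pd.DataFrame, visits: pd.DataFrame,
                   meta: pd.DataFrame,
                   weighted_rate: bool = False) -> pd.DataFrame:
    """Per calf-day feeding behaviors.

    total_meals
        Count of all meals that day, entitled or not.
    meal_size
        Total milk consumed in qualifying meals (entitled, consumption > 0)
        divided by the number of qualifying meals; missing if none qualify.
    feeding_rate
        Mean of visit-level feeding rate over entitled consuming visits
        (consumption-weighted if ``weighted_rate``); missing if none.
    """
    missing = set(meals["calf_id"]) - set(meta["calf_id"])
    if missing:
        raise ValueError(f"calves present in meals but absent in metadata: {sorted(missing)}")

    total = (meals.groupby(["calf_id", "date"]).size()
             .rename("total_meals").reset_index())

    qual = meals[meals["entitled"] & (meals["total_consumption"] > 0)]
    size = (qual.groupby(["calf_id", "date"])["total_consumption"].mean()
            .rename("meal_size").reset_index())

    cv = visits[visits["entitled"] & (visits["consumption"] > 0)]
    if weighted_rate:
        rate = (cv.groupby(["calf_id", "date"])
                .apply(lambda d: np.average(d["feeding_rate"], weights=d["consumption"]),
                       include_groups=False)
                .rename("feeding_rate").reset_index())
    else:
        rate = (cv.groupby(["calf_id", "date"])["feeding_rate"].mean()
                .rename("feeding_rate").reset_index())

    # full calf x cohort-date grid so zero-meal days appear with total_meals=0
    cohort_dates = (visits.groupby("cohort_id")["date"].unique()
                    .rename("date").explode().reset_index())
    grid = meta[["calf_id", "cohort_id", "age_at_grouping"]].merge(
        cohort_dates, on="cohort_id")

    out = grid.merge(total, how="left", on=["calf_id", "date"])
    out["total_meals"] = out["total_meals"].fillna(0).astype(int)
    out = out.merge(size, how="left", on=["calf_id", "date"])
    out = out.merge(rate, how="left", on=["calf_id", "date"])
    # day_number: 1-based within cohort from the first retained day
    first = out.groupby("cohort_id")["date"].transform("min")
    out["day_number"] = ((pd.to_datetime(out["date"]) - pd.to_datetime(first))
                         .dt.days + 1)
    cols = ["calf_id", "cohort_id", "date", "day_number", "age_at_grouping",
            "total_meals", "meal_size", "feeding_rate"]
    return out[cols].sort_values(["calf_id", "date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    """Row/calf counts removed by each exclusion rule."""
    sanity_exit_before_entry: int = 0
    sanity_negative_consumption: int = 0
    sanity_consumption_over_portion: int = 0
    sanity_feeding_rate_out_of_range: int = 0
    acclimatization_rows: int = 0
    window_rows: int = 0
    sick_calves: int = 0
    sick_calf_rows: int = 0

    def total_sanity(self) -> int:
        return (self.sanity_exit_before_entry + self.sanity_negative_consumption
                + self.sanity_consumption_over_portion
                + self.sanity_feeding_rate_out_of_range)

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def sanity_filter(visits: pd.DataFrame, flog: FilterLog | None = None,
                  portion_ml: float = 2000.0,
                  max_rate_ml_min: float = 5000.0) -> pd.DataFrame:
    """Drop physically impossible rows (assumed measurement errors)."""
    flog = flog if flog is not None else FilterLog()
    v = visits
    bad_time = v["exit_time"] < v["entry_time"]
    bad_cons = v["consumption"] < 0
    bad_portion = v["consumption"] > portion_ml
    bad_rate = (v["consumption"] > 0) & (
        (v["feeding_rate"] <= 0) | (v["feeding_rate"] > max_rate_ml_min))
    flog.sanity_exit_before_entry = int(bad_time.sum())
    flog.sanity_negative_consumption = int((bad_cons & ~bad_time).sum())
    flog.sanity_consumption_over_portion = int((bad_portion & ~bad_time & ~bad_cons).sum())
    flog.sanity_feeding_rate_out_of_range = int(
        (bad_rate & ~bad_time & ~bad_cons & ~bad_portion).sum())
    return v[~(bad_time | bad_cons | bad_portion | bad_rate)].reset_index(drop=True)


def apply_filters(visits: pd.DataFrame, meta: pd.DataFrame,
                  first_k_days: int = 2, window_days: int = 33,
                  health_cutoff: float = 5,
                  portion_ml: float = 2000.0,
                  max_rate_ml_min: float = 5000.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame, FilterLog]:
    """Apply the study's exclusion rules to a visit log.

    Per cohort, the first ``first_k_days`` calendar days are dropped
    (acclimatization) and the next ``window_days`` kept; calves whose maximum
    health score reaches ``health_cutoff`` are removed entirely; impossible
    rows are removed by the sanity rules.

    Returns ``(visits, meta, FilterLog)`` for the retained calves.
    """
    flog = FilterLog()
    stage = "input"
    v = visits.copy()
    if len(v) == 0:
        raise ValueError("empty visit log at stage: input")

    # windowing first, by contract
    v["date"] = pd.to_datetime(v["date"])
    first = v.groupby("cohort_id")["date"].transform("min")
    day_idx = (v["date"] - first).dt.days  # 0-based within cohort
    in_window = (day_idx >= first_k_days) & (day_idx < first_k_days + window_days)
    flog.acclimatization_rows = int((day_idx < first_k_days).sum())
    flog.window_rows = int((day_idx >= first_k_days + window_days).sum())
    v = v[in_window]
    if len(v) == 0:
        raise ValueError(f"empty visit log after windowing (last non-empty stage: {stage})")
    stage = "window"

    sick = meta[meta["max_health_score"] >= health_cutoff]["calf_id"]
    flog.sick_calves = int(sick.size)
    flog.sick_calf_rows = int(v["calf_id"].isin(sick).sum())
    v = v[~v["calf_id"].isin(sick)]
    meta_out = meta[~meta["calf_id"].isin(sick)].reset_index(drop=True)
    if len(v) == 0:
        raise ValueError(f"empty visit log after health filter (last non-empty stage: {stage})")
    stage = "health"

    v = sanity_filter(v, flog, portion_ml=portion_ml, max_rate_ml_min=max_rate_ml_min)
    if len(v) == 0:
        raise ValueError(f"empty visit log after sanity rules (last non-empty stage: {stage})")
    v["date"] = v["date"].dt.date.astype(str)
    return v.reset_index(drop=True), meta_out, flog
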
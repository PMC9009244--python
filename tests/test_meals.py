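"""Meal criterion estimation, visit clustering, daily features, filters."""

import numpy as np
import pandas as pd
import pytest

from calfvar import meals
from calfvar.feeder_sim import GapMixture
from conftest import toy_visits


# ---------------------------------------------------------------------------
# inter-visit intervals
# ---------------------------------------------------------------------------

def test_interval_computation_on_toy_examples():
    v = toy_visits([
        ("A", 0, 36000, 36010, True, 500, 800),   # ends 10:00:10
        ("A", 0, 36060, 36100, True, 500, 800),   # starts 10:01:00 -> gap 50
        ("B", 0, 1000, 1100, True, 300, 700),     # single visit: no gap
    ])
    gaps = meals.compute_intervals(v)
    assert len(gaps) == 1
    assert gaps["gap_seconds"].iloc[0] == pytest.approx(50.0)


def test_interval_count_matches_brute_force(small_dataset):
    _, visits, meta, truth = small_dataset
    v = meals.sanity_filter(visits)
    gaps = meals.compute_intervals(v)
    # oracle: enumerate consecutive same-calf pairs directly
    n_expected, n_negative = 0, 0
    for _, grp in v.sort_values("entry_time").groupby("calf_id"):
        ent = grp["entry_time"].to_numpy()
        exi = grp["exit_time"].to_numpy()
        for i in range(1, len(grp)):
            g = (ent[i] - exi[i - 1]) / np.timedelta64(1, "s")
            if g >= 0:
                n_expected += 1
            else:
                n_negative += 1
    assert len(gaps) == n_expected


# ---------------------------------------------------------------------------
# meal criterion
# ---------------------------------------------------------------------------

def test_symmetric_two_component_mixture_crosses_at_100s():
    # equal weights and SDs with log10 means 1 and 3: crossing at 10^2 by symmetry
    rng = np.random.default_rng(0)
    n = 20000
    comp = rng.integers(0, 2, n)
    x = 10.0 ** rng.normal(np.where(comp == 0, 1.0, 3.0), 0.3)
    crit, inters = meals.estimate_meal_criterion(x, n_components=2)
    assert crit == pytest.approx(100.0, rel=0.08)
    # analytic crossing of the generating mixture is exactly 100 s
    gm = GapMixture(log10_means=(1.0, 3.0), log10_sds=(0.3, 0.3),
                    weights=(0.5, 0.5))
    assert gm.density_crossings()[0] == pytest.approx(100.0, abs=1e-6)


def test_estimator_recovers_default_mixture_intersections():
    gm = GapMixture()
    analytic = gm.density_crossings()
    assert 80 < analytic[0] < 125 and 1000 < analytic[1] < 2200
    rng = np.random.default_rng(12)
    crit, inters = meals.estimate_meal_criterion(gm.sample(50_000, rng), seed=0)
    assert 80 <= crit <= 125
    assert len(inters) == 2
    assert inters[1] == pytest.approx(analytic[1], rel=0.25)


def test_estimator_converges_with_sample_size():
    gm = GapMixture()
    target = gm.density_crossings()[0]
    rng = np.random.default_rng(3)
    err = []
    for n in (10_000, 100_000):
        crit, _ = meals.estimate_meal_criterion(gm.sample(n, rng), seed=0)
        err.append(abs(crit - target))
    assert err[1] <= err[0] + 2.0  # larger sample at least as close (2 s slack)
    assert err[1] < 10.0


def test_criterion_requires_enough_gaps():
    with pytest.raises(ValueError, match="500"):
        meals.estimate_meal_criterion(np.ones(100) * 50)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_clustering_boundary_is_strict_and_partitions_visits():
    v = toy_visits([
        ("A", 0, 0, 10, True, 400, 800),
        ("A", 0, 60, 70, True, 400, 800),     # gap 50 -> same meal
        ("A", 0, 220, 230, True, 400, 800),   # gap 150 -> new meal
        ("B", 0, 0, 10, True, 400, 800),
        ("B", 0, 110, 120, True, 400, 800),   # gap exactly 100 -> new meal
    ])
    m = meals.cluster_meals(v, criterion_s=100.0)
    assert m[m.calf_id == "A"]["n_visits"].tolist() == [2, 1]
    assert m[m.calf_id == "B"]["n_visits"].tolist() == [1, 1]
    assert m["n_visits"].sum() == len(v)
    assert m["total_consumption"].sum() == pytest.approx(v["consumption"].sum())


def test_clustering_is_idempotent_and_conserves_consumption(small_dataset):
    _, visits, meta, truth = small_dataset
    v = meals.sanity_filter(visits)
    m1 = meals.cluster_meals(v, 100.0)
    # feeding a shuffled copy gives the same meals after sorting
    m2 = meals.cluster_meals(v.sample(frac=1, random_state=0), 100.0)
    pd.testing.assert_frame_equal(
        m1.drop(columns="meal_id").reset_index(drop=True),
        m2.drop(columns="meal_id").reset_index(drop=True))
    assert m1["total_consumption"].sum() == pytest.approx(v["consumption"].sum())


def test_meal_count_tracks_true_bouts(full_dataset):
    cfg, visits, meta, truth = full_dataset
    v = meals.sanity_filter(visits)
    m = meals.cluster_meals(v, 100.0)
    n_true = truth["n_bouts_total"]
    # between-bout gaps below 100 s merge bouts; within-bout gaps above split
    # them; both tails are small for the default mixture
    assert abs(len(m) - n_true) / n_true < 0.06


# ---------------------------------------------------------------------------
# daily features
# ---------------------------------------------------------------------------

def _meta(calves):
    return pd.DataFrame({"calf_id": calves, "cohort_id": "G1",
                         "age_at_grouping": 30, "max_health_score": 0})


def test_daily_feature_arithmetic():
    v = toy_visits(
        [("A", 0, i * 1000, i * 1000 + 120, True, ml, 900)
         for i, ml in enumerate((2000, 1800))] +
        [("A", 0, 10_000 + i * 1000, 10_000 + i * 1000 + 30, False, 0, 0)
         for i in range(3)])
    m = meals.cluster_meals(v, 100.0)
    rec = meals.daily_features(m, v, _meta(["A"]))
    assert rec.loc[0, "total_meals"] == 5
    assert rec.loc[0, "meal_size"] == pytest.approx(1900.0)
    assert rec.loc[0, "feeding_rate"] == pytest.approx(900.0)


def test_day_without_qualifying_meals_has_missing_size():
    v = toy_visits([("A", 0, 0, 30, False, 0, 0),
                    ("A", 0, 500, 530, False, 0, 0)])
    m = meals.cluster_meals(v, 100.0)
    rec = meals.daily_features(m, v, _meta(["A"]))
    assert rec.loc[0, "total_meals"] == 2
    assert np.isnan(rec.loc[0, "meal_size"])
    assert np.isnan(rec.loc[0, "feeding_rate"])


def test_unknown_calf_in_meals_is_an_error():
    v = toy_visits([("A", 0, 0, 30, True, 500, 800)])
    m = meals.cluster_meals(v, 100.0)
    with pytest.raises(ValueError, match="absent in metadata"):
        meals.daily_features(m, v, _meta(["B"]))


def test_daily_mean_meals_tracks_latent_mean(full_dataset):
    cfg, visits, meta, truth = full_dataset
    v = meals.sanity_filter(visits)
    m = meals.cluster_meals(v, 100.0)
    rec = meals.daily_features(m, v, meta)
    assert rec["total_meals"].mean() == pytest.approx(
        truth["latent_mean_meals"], rel=0.10)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_filters_mirror_study_counts(full_dataset):
    cfg, visits, meta, truth = full_dataset
    v, m, flog = meals.apply_filters(visits, meta)
    assert len(m) == 48                       # 64 enrolled, 16 sick
    assert flog.sick_calves == 16
    assert flog.total_sanity() == 4           # corrupted rows reach the rules
    # retained window spans exactly 33 days per cohort
    spans = (pd.to_datetime(v["date"]).groupby(v["cohort_id"])
             .agg(lambda d: (d.max() - d.min()).days + 1))
    assert (spans <= 33).all()


def test_health_cutoff_infinite_drops_no_calves(full_dataset):
    cfg, visits, meta, truth = full_dataset
    _, m, flog = meals.apply_filters(visits, meta, health_cutoff=np.inf)
    assert len(m) == len(meta) and flog.sick_calves == 0


def test_filter_order_does_not_change_the_outcome(small_dataset):
    """Health and sanity rules are pure row predicates: applying them in
    either order after windowing keeps the same rows."""
    _, visits, meta, truth = small_dataset
    v1, m1, _ = meals.apply_filters(visits, meta)
    # alternative order: sanity first, then the standard chain
    pre = meals.sanity_filter(visits.copy())
    v2, m2, _ = meals.apply_filters(pre, meta)
    a = v1.sort_values(["calf_id", "entry_time"]).reset_index(drop=True)
    b = v2.sort_values(["calf_id", "entry_time"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_empty_result_raises_with_stage_name():
    v = toy_visits([("A", 0, 0, 30, True, 500, 800)])
    with pytest.raises(ValueError, match="windowing"):
        meals.apply_filters(v, _meta(["A"]), first_k_days=2, window_days=33)
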
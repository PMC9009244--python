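"""Synthetic feeder-log generator: determinism, mechanics, latent structure."""

import numpy as np
import pytest

from calfvar.feeder_sim import (GapMixture, SimConfig, simulate_daily,
                                simulate_dataset, write_dataset, read_dataset)


def test_identical_config_and_seed_give_byte_identical_output(tmp_path):
    cfg = SimConfig(n_cohorts=2, calves_per_cohort=4, n_days=6, seed=5)
    for d in ("a", "b"):
        write_dataset(tmp_path / d, *simulate_dataset(cfg))
    for name in ("visits.csv", "calves.csv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
               (tmp_path / "b" / name).read_bytes()
    v, m, t = read_dataset(tmp_path / "a")
    assert len(v) > 0 and len(m) == 8


def test_visit_invariants_and_allowance_conservation(small_dataset):
    cfg, visits, meta, truth = small_dataset
    clean = visits.drop(index=truth["nonsense_rows"])
    # corrupted rows aside, exit >= entry and consumption only when entitled
    assert (clean["exit_time"] >= clean["entry_time"]).all()
    assert (clean.loc[~clean["entitled"], "consumption"] == 0).all()
    assert (clean["consumption"] >= 0).all()
    # per calf-day total consumption never exceeds the daily allowance
    daily_ml = clean.groupby(["calf_id", "date"])["consumption"].sum()
    assert (daily_ml <= cfg.daily_allowance_ml + 1e-9).all()
    # consuming visits have positive feeding rate
    consuming = clean["consumption"] > 0
    assert (clean.loc[consuming, "feeding_rate"] > 0).all()


def test_truth_carries_configured_repeatability_and_cvp():
    # equal between and within SD -> Rpt exactly 0.5
    cfg = SimConfig(between_sd=(0.7, 0.3, 0.5),
                    within_sd_intercept=(np.log(0.7), np.log(0.3), np.log(0.5)),
                    omega_sq=(0.0, 0.0, 0.0))
    assert cfg.true_rpt() == pytest.approx(
        {"feeding_rate": 0.5, "total_meals": 0.5, "meal_size": 0.5})
    # no dispersion heterogeneity -> CVp exactly 0
    assert all(v == 0 for v in cfg.true_cvp().values())


def test_row_count_matches_bout_and_visit_process(full_dataset):
    cfg, visits, meta, truth = full_dataset
    n_calves = cfg.n_cohorts * cfg.calves_per_cohort
    mean_visits_per_bout = 1 + np.arange(3) @ np.array(cfg.visits_per_bout_probs)
    expected = n_calves * cfg.n_days * 10 * mean_visits_per_bout
    assert expected / 2 < len(visits) < expected * 2
    # realized bouts drive the row count exactly through the visit split
    assert truth["n_bouts_total"] <= len(visits) <= 3 * truth["n_bouts_total"]


def test_sick_and_corrupted_counts_match_config(full_dataset):
    cfg, visits, meta, truth = full_dataset
    assert (meta["max_health_score"] >= 5).sum() == round(
        cfg.sick_fraction * len(meta))
    assert len(truth["nonsense_rows"]) == cfg.n_nonsense


def test_config_validation_errors():
    bad = np.eye(6)
    bad[0, 1] = bad[1, 0] = 1.2  # not positive semi-definite
    with pytest.raises(ValueError, match="positive semi-definite"):
        SimConfig(re_correlation=bad).validate()
    with pytest.raises(ValueError, match="n_days"):
        SimConfig(n_days=2).validate()
    with pytest.raises(ValueError, match="ordered"):
        GapMixture(log10_means=(3.0, 2.0, 1.0))


def test_empirical_effects_pin_sample_moments(study_daily):
    cfg, daily, meta, truth = study_daily
    alpha = np.array([truth["alpha"][c] for c in meta["calf_id"]])
    delta = np.array([truth["delta"][c] for c in meta["calf_id"]])
    u = np.hstack([alpha, delta])
    sds = u.std(axis=0, ddof=1)
    assert sds == pytest.approx(cfg.effect_sds, abs=1e-8)
    corr = np.corrcoef(u, rowvar=False)
    assert corr[0, 1] == pytest.approx(0.29, abs=1e-8)


def test_between_calf_variance_follows_law_of_total_variance():
    """Empirical variance of per-calf daily means ~ sigma_alpha^2 + sigma_w^2/n
    over seeds (plain iid effect draws, no cohort/fixed-effect variance)."""
    zeros3 = ((0.0, 0.0, 0.0),) * 3
    est = []
    for seed in range(20):
        cfg = SimConfig(n_cohorts=4, calves_per_cohort=10, n_days=30,
                        cohort_sd=0.0, fixed_effect_coefs=zeros3,
                        sick_fraction=0.0, n_nonsense=0, seed=seed,
                        empirical_effects=False,
                        between_sd=(0.5, 0.1702549, 0.1758640))
        daily, meta, truth = simulate_daily(cfg)
        lat = (daily["feeding_rate"] - cfg.rate_loc_ml_min) / cfg.rate_scale_ml_min
        est.append(lat.groupby(daily["calf_id"]).mean().var(ddof=1))
    # mean within-variance is slightly above exp(beta_d0)^2 because of the
    # lognormal dispersion effects: E[exp(2 delta)] = exp(2 omega^2)
    expected = 0.5 ** 2 + (0.7 ** 2) * np.exp(2 * cfg.omega_sq[0]) / 30
    assert np.mean(est) == pytest.approx(expected, rel=0.15)
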
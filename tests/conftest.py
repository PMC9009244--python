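import pandas as pd
import pytest

from calfvar.feeder_sim import SimConfig, simulate_dataset, simulate_daily


@pytest.fixture(scope="session")
def full_dataset():
    """One full study-condition visit log: 4 cohorts x 16 calves x 35 days,
    16 sick calves, 4 corrupted rows."""
    cfg = SimConfig(seed=202)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, quick visit log for unit tests of the preprocessing chain."""
    cfg = SimConfig(n_cohorts=2, calves_per_cohort=5, n_days=8,
                    sick_fraction=0.2, n_nonsense=2, seed=77)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def study_daily():
    """Latent daily records at the study design (48 calves x 33 days)."""
    cfg = SimConfig(calves_per_cohort=12, n_days=33, sick_fraction=0.0,
                    n_nonsense=0, seed=101)
    daily, meta, truth = simulate_daily(cfg)
    return cfg, daily, meta, truth


def toy_visits(rows):
    """Build a visit frame from (calf, date, entry_s, exit_s, entitled, ml, rate)."""
    base = pd.Timestamp("2021-06-01")
    recs = []
    for calf, date, entry_s, exit_s, entitled, ml, rate in rows:
        day0 = base + pd.Timedelta(days=int(date))
        recs.append({
            "calf_id": calf, "cohort_id": "G1",
            "date": (day0).date().isoformat(),
            "entry_time": day0 + pd.Timedelta(seconds=entry_s),
            "exit_time": day0 + pd.Timedelta(seconds=exit_s),
            "entitled": bool(entitled), "consumption": float(ml),
            "feeding_rate": float(rate),
        })
    return pd.DataFrame(recs)
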
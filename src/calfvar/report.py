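"""Figures and the end-to-end pipeline driver.

Figures mirror the study's presentation: per-trait ridge panels of per-calf
posterior intervals (behavioral types or rIIV, calves ordered by posterior
median and colored by cohort, with Rpt or CVp annotated), and a scatter of
two behavioral types with credible-interval bars and the among-individual
regression line. Figures are informational; nothing downstream depends on
rendering.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import feeder_sim, meals, transforms, dhglm, metrics

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

_COHORT_COLORS = ("#4477AA", "#EE6677", "#228833", "#CCBB44", "#66CCEE",
                  "#AA3377")


def make_ridge_figure(report: metrics.VarianceReport, out_path: str | Path,
                      component: str = "behavioral_type"):
    """Per-trait panels of per-calf 95% credible intervals.

    ``component`` is ``behavioral_type`` (mean-part random intercepts, with
    Rpt annotated) or ``riiv`` (calf residual SDs, with CVp annotated).
    """
    if component not in ("behavioral_type", "riiv"):
        raise ValueError(f"unknown component {component!r}")
    table = report.behavioral_types if component == "behavioral_type" else report.riiv
    if table.empty or len(report.calf_ids) == 0:
        raise ValueError("no calves to plot")
    annot = report.rpt if component == "behavioral_type" else report.cvp
    annot_name = "Rpt" if component == "behavioral_type" else "CVp"

    cohort_of = {}
    for calf in report.calf_ids:
        cohort_of[calf] = str(calf).split("-")[0].replace("C", "G")
    colors = {g: _COHORT_COLORS[i % len(_COHORT_COLORS)]
              for i, g in enumerate(sorted(set(cohort_of.values())))}

    fig, axes = plt.subplots(1, len(report.traits), figsize=(4 * len(report.traits), 6),
                             sharey=False)
    axes = np.atleast_1d(axes)
    for ax, trait in zip(axes, report.traits):
        sub = table[table["trait"] == trait].sort_values("median").reset_index(drop=True)
        for y, row in sub.iterrows():
            col = colors[cohort_of[row["calf_id"]]]
            ax.plot([row["cri_low"], row["cri_high"]], [y, y], color=col, lw=1.2)
            ax.plot(row["median"], y, "o", color=col, ms=2.5)
        ax.set_title(trait.replace("_", " "))
        ax.set_xlabel("z scale" if component == "behavioral_type" else "residual SD")
        ax.text(0.95, 0.02, f"{annot_name} = {annot[trait]['median']:.2f}",
                transform=ax.transAxes, ha="right")
    axes[0].set_ylabel("calves (ordered by posterior median)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def make_correlation_figure(draws: dhglm.PosteriorDraws,
                            pair: tuple[str, str], out_path: str | Path):
    """Scatter of two behavioral types with CrI bars and the among-individual
    regression line implied by the posterior-median correlation."""
    rho = metrics.correlation_posterior(draws, *pair)  # raises on unknown pair
    t1 = metrics.EFFECT_LABELS.index(pair[0])
    t2 = metrics.EFFECT_LABELS.index(pair[1])
    if t1 >= 3 or t2 >= 3:
        raise ValueError("correlation figure is defined over behavioral types")
    alpha = draws.stacked("alpha")
    x_m, y_m = alpha[:, :, t1].mean(axis=0), alpha[:, :, t2].mean(axis=0)
    x_lo, x_hi = np.quantile(alpha[:, :, t1], [0.025, 0.975], axis=0)
    y_lo, y_hi = np.quantile(alpha[:, :, t2], [0.025, 0.975], axis=0)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(x_m, y_m, xerr=[x_m - x_lo, x_hi - x_m],
                yerr=[y_m - y_lo, y_hi - y_m], fmt="o", ms=3, lw=0.6,
                color="#4477AA", alpha=0.8)
    r_med = float(np.median(rho))
    sx = draws.stacked("sigma_alpha")[:, t1].mean()
    sy = draws.stacked("sigma_alpha")[:, t2].mean()
    xs = np.linspace(x_m.min(), x_m.max(), 50)
    ax.plot(xs, r_med * sy / sx * xs, "k-", lw=1.5,
            label=f"r = {r_med:.2f}")
    ax.set_xlabel(pair[0])
    ax.set_ylabel(pair[1])
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run settings; every default is the study's choice."""

    outdir: str = "results/run"
    seed: int = 0
    # simulation
    sim: dict = field(default_factory=dict)      # SimConfig overrides
    # preprocessing
    criterion_s: float | None = None             # None: estimate from the data
    first_k_days: int = 2
    window_days: int = 33
    health_cutoff: int = 5
    # mcmc
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    thin: int = 1
    stages: tuple[str, ...] = ("simulate", "preprocess", "fit", "report")
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """simulate -> preprocess -> transform -> fit -> metrics -> figures.

    Each stage persists its outputs (and a hash of its inputs) under
    ``config.outdir`` so any suffix of stages can be re-run from the cached
    intermediates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {}
    stage = "start"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            sim_cfg = feeder_sim.SimConfig(seed=config.seed, **config.sim)
            visits, meta, truth = feeder_sim.simulate_dataset(sim_cfg)
            feeder_sim.write_dataset(out / "data", visits, meta, truth)
        else:
            visits, meta, _ = feeder_sim.read_dataset(out / "data")
        provenance["visits_hash"] = _hash_df(visits)

        if "preprocess" in config.stages or "fit" in config.stages:
            stage = "preprocess"
            visits_f, meta_f, flog = meals.apply_filters(
                visits, meta, first_k_days=config.first_k_days,
                window_days=config.window_days,
                health_cutoff=config.health_cutoff)
            gaps = meals.compute_intervals(visits_f)
            if config.criterion_s is None:
                criterion, intersections = meals.estimate_meal_criterion(
                    gaps["gap_seconds"], seed=config.seed)
            else:
                criterion, intersections = float(config.criterion_s), []
            meal_table = meals.cluster_meals(visits_f, criterion)
            daily = meals.daily_features(meal_table, visits_f, meta_f)
            daily.to_csv(out / "daily_features.csv", index=False)
            (out / "filter_log.json").write_text(json.dumps(
                {**flog.as_dict(), "criterion_s": criterion,
                 "intersections_s": intersections}))
            provenance["daily_hash"] = _hash_df(daily)

        if "fit" in config.stages:
            stage = "transform"
            tspec, daily_t = transforms.fit_transforms(daily)
            tspec.to_json(out / "transforms.json")
            stage = "fit"
            model = dhglm.DHGLM(daily_t)
            mcmc = dhglm.MCMCConfig(chains=config.chains,
                                    iterations=config.iterations,
                                    warmup=config.warmup, thin=config.thin,
                                    seed=config.seed)
            draws, diagnostics = dhglm.fit(model, mcmc)
            draws.save(out / "draws")
            (out / "diagnostics.json").write_text(
                json.dumps(diagnostics, indent=1, default=str))
            stage = "metrics"
            report = metrics.VarianceReport(draws, daily=daily)
            report.to_json(out / "variance_report.json")
            report.summary_table().to_csv(out / "summary_table.csv", index=False)

            if "report" in config.stages and config.make_figures:
                stage = "figures"
                make_ridge_figure(report, out / "behavioral_types.png",
                                  "behavioral_type")
                make_ridge_figure(report, out / "riiv.png", "riiv")
                make_correlation_figure(
                    draws, ("alpha_feeding_rate", "alpha_total_meals"),
                    out / "correlation_rate_meals.png")
    except Exception:
        log.error("pipeline failed at stage %r; partial outputs kept in %s",
                  stage, out)
        raise
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out
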
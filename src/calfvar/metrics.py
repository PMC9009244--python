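"""Variance-partitioning quantities derived from the posterior.

All quantities are computed per posterior draw and then summarized
(posterior median, mean, and equal-tailed 95% credible interval), so the
uncertainty in the underlying variance components propagates into every
derived measure:

repeatability
    Rpt = V_CalfID / (V_CalfID + V_residual), with V_CalfID = sigma_alpha^2
    and V_residual the squared exponent of the dispersion-model population
    intercept.
coefficient of variation in predictability
    CVp = sqrt(exp(omega^2) - 1), the coefficient of variation of the
    lognormally distributed calf residual SDs.
behavioral types / rIIV
    per-calf posterior summaries of the mean-part random intercept alpha_i
    and of the calf residual SD exp(beta_d0 + delta_i).
among-individual correlations
    read directly from the model's 6x6 calf-effect correlation matrix,
    never recomputed from point estimates of the calf effects.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dhglm import PosteriorDraws

log = logging.getLogger(__name__)

EFFECT_LABELS = ("alpha_feeding_rate", "alpha_total_meals", "alpha_meal_size",
                 "riiv_feeding_rate", "riiv_total_meals", "riiv_meal_size")


def _summary(x: np.ndarray) -> dict:
    return {"median": float(np.median(x)), "mean": float(np.mean(x)),
            "cri_low": float(np.quantile(x, 0.025)),
            "cri_high": float(np.quantile(x, 0.975))}


def _trait_index(draws: PosteriorDraws, trait: str) -> int:
    try:
        return draws.traits.index(trait)
    except ValueError:
        raise KeyError(f"unknown trait {trait!r}; have {draws.traits}") from None


def repeatability(draws: PosteriorDraws, trait: str) -> np.ndarray:
    """Posterior of Rpt = V_CalfID / (V_CalfID + V_residual) for one trait.

    V_residual is ``exp(beta_d0)^2`` — the dispersion-model population
    intercept taken through its exponent and squared. Draws where both
    variances are exactly zero are excluded with a logged count.
    """
    t = _trait_index(draws, trait)
    v_calf = draws.stacked("sigma_alpha")[:, t] ** 2
    v_res = np.exp(draws.stacked("beta_d")[:, t, 0]) ** 2
    denom = v_calf + v_res
    ok = denom > 0
    if (~ok).any():
        log.info("repeatability(%s): %d degenerate 0/0 draws excluded",
                 trait, int((~ok).sum()))
    return v_calf[ok] / denom[ok]


def cv_predictability(draws: PosteriorDraws, trait: str) -> np.ndarray:
    """Posterior of CVp = sqrt(exp(omega^2) - 1) for one trait."""
    t = _trait_index(draws, trait)
    omega_sq = draws.stacked("omega")[:, t] ** 2
    return np.sqrt(np.exp(omega_sq) - 1.0)


def behavioral_types(draws: PosteriorDraws, trait: str | None = None) -> pd.DataFrame:
    """Per-calf posterior summaries of the mean-part random intercepts."""
    traits = draws.traits if trait is None else (trait,)
    alpha = draws.stacked("alpha")          # (draws, calves, traits)
    rows = []
    for tr in traits:
        t = _trait_index(draws, tr)
        for i, calf in enumerate(draws.calf_ids):
            rows.append({"calf_id": calf, "trait": tr,
                         **_summary(alpha[:, i, t])})
    return pd.DataFrame(rows)


def riiv(draws: PosteriorDraws, trait: str | None = None) -> pd.DataFrame:
    """Per-calf posterior summaries of the residual SD exp(beta_d0 + delta_i)."""
    traits = draws.traits if trait is None else (trait,)
    delta = draws.stacked("delta")
    bd0 = draws.stacked("beta_d")[:, :, 0]
    rows = []
    for tr in traits:
        t = _trait_index(draws, tr)
        sd_i = np.exp(bd0[:, t][:, None] + delta[:, :, t])
        for i, calf in enumerate(draws.calf_ids):
            rows.append({"calf_id": calf, "trait": tr, **_summary(sd_i[:, i])})
    return pd.DataFrame(rows)


def among_individual_correlations(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summaries of the 15 off-diagonal calf-effect correlations.

    ``significant`` flags entries whose 95% credible interval excludes 0.
    """
    corr = draws.stacked("corr")
    rows = []
    for j in range(6):
        for k in range(j + 1, 6):
            s = _summary(corr[:, j, k])
            rows.append({"effect_1": EFFECT_LABELS[j], "effect_2": EFFECT_LABELS[k],
                         **s, "significant": s["cri_low"] > 0 or s["cri_high"] < 0})
    return pd.DataFrame(rows)


def correlation_posterior(draws: PosteriorDraws, effect_1: str, effect_2: str
                          ) -> np.ndarray:
    """Posterior draws of one calf-effect correlation entry."""
    try:
        j, k = EFFECT_LABELS.index(effect_1), EFFECT_LABELS.index(effect_2)
    except ValueError:
        raise KeyError(f"unknown effect pair ({effect_1!r}, {effect_2!r}); "
                       f"labels are {EFFECT_LABELS}") from None
    return draws.stacked("corr")[:, j, k]


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------

class VarianceReport:
    """Per-trait Rpt and CVp with credible intervals, per-calf behavioral
    types and rIIV, and the calf-effect correlation summaries."""

    def __init__(self, draws: PosteriorDraws,
                 daily: pd.DataFrame | None = None):
        # every-draw invariants
        self.traits = draws.traits
        self.rpt = {}
        self.cvp = {}
        self.variance_components = {}
        for trait in draws.traits:
            r = repeatability(draws, trait)
            if not ((r >= 0) & (r <= 1)).all():
                raise AssertionError("repeatability draw outside [0, 1]")
            c = cv_predictability(draws, trait)
            if (c < 0).any():
                raise AssertionError("negative CVp draw")
            self.rpt[trait] = _summary(r)
            self.cvp[trait] = _summary(c)
            t = draws.traits.index(trait)
            self.variance_components[trait] = {
                "v_calf": _summary(draws.stacked("sigma_alpha")[:, t] ** 2),
                "v_residual": _summary(np.exp(draws.stacked("beta_d")[:, t, 0]) ** 2),
            }
        self.behavioral_types = behavioral_types(draws)
        self.riiv = riiv(draws)
        self.correlations = among_individual_correlations(draws)
        self.calf_ids = draws.calf_ids
        self.cohort_ids = draws.cohort_ids
        # raw-scale descriptives, Table-3 style, if daily features provided
        self.descriptives = {}
        if daily is not None:
            for trait in draws.traits:
                x = daily[trait].to_numpy(float)
                x = x[np.isfinite(x)]
                self.descriptives[trait] = {
                    "mean": float(np.mean(x)), "median": float(np.median(x)),
                    "iqr_low": float(np.quantile(x, 0.25)),
                    "iqr_high": float(np.quantile(x, 0.75))}

    def as_dict(self) -> dict:
        return {"traits": list(self.traits),
                "repeatability": self.rpt,
                "cv_predictability": self.cvp,
                "variance_components": self.variance_components,
                "descriptives": self.descriptives,
                "behavioral_types": self.behavioral_types.to_dict(orient="records"),
                "riiv": self.riiv.to_dict(orient="records"),
                "correlations": self.correlations.to_dict(orient="records")}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1, default=str))

    def summary_table(self) -> pd.DataFrame:
        """Traits x {mean, median, IQR, Rpt, Rpt CrI, CVp, CVp CrI}."""
        rows = []
        for trait in self.traits:
            d = self.descriptives.get(trait, {})
            rows.append({
                "trait": trait,
                "mean": d.get("mean"), "median": d.get("median"),
                "iqr": (f"{d['iqr_low']:.0f}-{d['iqr_high']:.0f}" if d else None),
                "rpt": round(self.rpt[trait]["median"], 2),
                "rpt_cri": f"{self.rpt[trait]['cri_low']:.2f}-{self.rpt[trait]['cri_high']:.2f}",
                "cvp": round(self.cvp[trait]["median"], 2),
                "cvp_cri": f"{self.cvp[trait]['cri_low']:.2f}-{self.cvp[trait]['cri_high']:.2f}",
            })
        return pd.DataFrame(rows)
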
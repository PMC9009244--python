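"""Response transformations applied before modeling.

Feeding rate is left on its natural scale (approximately Gaussian); total
meals is natural-log transformed; meal size goes through an ordered quantile
(rank-based inverse normal) transform. After transformation every trait is
standardized to mean 0, SD 1 on the analysis set, and the fitted mapping is
stored so new values can be transformed and results back-transformed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)

DEFAULT_TRANSFORMS = {"feeding_rate": "identity",
                      "total_meals": "log",
                      "meal_size": "ordered-quantile"}


def orq_scores(x: np.ndarray) -> np.ndarray:
    """Ordered quantile normalization: Phi^-1((rank - 0.5) / n), average ranks for ties."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("ordered quantile transform needs n >= 3")
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError("all values identical: rank-based transform undefined")
    r = rankdata(x, method="average")
    return norm.ppf((r - 0.5) / x.size)


@dataclass
class TraitTransform:
    """Fitted transform for one trait: a named map plus z-scaling constants."""

    name: str                       # identity | log | ordered-quantile
    mean: float = 0.0               # post-transform standardization constants
    sd: float = 1.0
    # ordered-quantile reference: sorted training values and their normal scores
    ref_x: np.ndarray | None = None
    ref_z: np.ndarray | None = None
    log_offset: float = 0.0         # optional +c before log (0 disables)
    n_dropped_nonpositive: int = 0

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.name == "identity":
            return x
        if self.name == "log":
            shifted = x + self.log_offset
            out = np.where(shifted > 0, np.log(np.maximum(shifted, 1e-300)), np.nan)
            return out
        if self.name == "ordered-quantile":
            # interpolate new values through the fitted monotone mapping
            return np.interp(x, self.ref_x, self.ref_z,
                             left=self.ref_z[0], right=self.ref_z[-1])
        raise ValueError(f"unknown transform {self.name!r}")

    def transform(self, x) -> np.ndarray:
        return (self._raw(x) - self.mean) / self.sd

    def inverse_transform(self, z) -> np.ndarray:
        y = np.asarray(z, float) * self.sd + self.mean
        if self.name == "identity":
            return y
        if self.name == "log":
            return np.exp(y) - self.log_offset
        if self.name == "ordered-quantile":
            return np.interp(y, self.ref_z, self.ref_x,
                             left=self.ref_x[0], right=self.ref_x[-1])
        raise ValueError(f"unknown transform {self.name!r}")


@dataclass
class TransformSpec:
    """Per-trait fitted transforms, serializable for exact reuse."""

    transforms: dict[str, TraitTransform] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for k, t in self.transforms.items():
            payload[k] = {"name": t.name, "mean": t.mean, "sd": t.sd,
                          "log_offset": t.log_offset,
                          "n_dropped_nonpositive": t.n_dropped_nonpositive,
                          "ref_x": None if t.ref_x is None else t.ref_x.tolist(),
                          "ref_z": None if t.ref_z is None else t.ref_z.tolist()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformSpec":
        payload = json.loads(Path(path).read_text())
        spec = cls()
        for k, d in payload.items():
            spec.transforms[k] = TraitTransform(
                name=d["name"], mean=d["mean"], sd=d["sd"],
                log_offset=d["log_offset"],
                n_dropped_nonpositive=d["n_dropped_nonpositive"],
                ref_x=None if d["ref_x"] is None else np.asarray(d["ref_x"]),
                ref_z=None if d["ref_z"] is None else np.asarray(d["ref_z"]))
        return spec


def standardize(x) -> np.ndarray:
    """z = (x - mean)/SD over non-missing values (n-1 SD); missings propagate."""
    x = np.asarray(x, float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=1)
    if not np.isfinite(s) or s == 0:
        raise ValueError("zero or undefined SD: cannot standardize")
    return (x - m) / s


def fit_transforms(daily: pd.DataFrame,
                   names: dict[str, str] | None = None,
                   log_offset: float = 0.0
                   ) -> tuple[TransformSpec, pd.DataFrame]:
    """Fit the per-trait transforms on the analysis set and apply them.

    Returns the fitted :class:`TransformSpec` and a copy of ``daily`` with
    added ``<trait>_z`` columns (mean 0, SD 1 over non-missing values).
    Zero-meal days under the plain log transform become missing with a
    logged count rather than -inf.
    """
    names = dict(DEFAULT_TRANSFORMS if names is None else names)
    out = daily.copy()
    spec = TransformSpec()
    for trait, name in names.items():
        x = out[trait].to_numpy(dtype=float)
        t = TraitTransform(name=name, log_offset=log_offset)
        if name == "ordered-quantile":
            obs = x[np.isfinite(x)]
            z = orq_scores(obs)
            order = np.argsort(obs, kind="mergesort")
            # collapse duplicate x to a strictly monotone reference mapping
            ref = pd.DataFrame({"x": obs[order], "z": z[order]}).groupby("x", as_index=False).mean()
            t.ref_x, t.ref_z = ref["x"].to_numpy(), ref["z"].to_numpy()
        raw = t._raw(x)
        if name == "log":
            n_bad = int(np.sum(np.isfinite(x) & ~np.isfinite(raw)))
            if n_bad:
                log.info("log transform of %s: %d non-positive values set missing",
                         trait, n_bad)
            t.n_dropped_nonpositive = n_bad
        finite = raw[np.isfinite(raw)]
        sd = np.std(finite, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"trait {trait!r} has zero variance after transform")
        t.mean, t.sd = float(np.mean(finite)), float(sd)
        out[trait + "_z"] = (raw - t.mean) / t.sd
        spec.transforms[trait] = t
    return spec, out
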
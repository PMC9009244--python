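"""Multivariate double-hierarchical Gaussian model (DHGLM) fitted by MCMC.

Three daily feeding traits are modeled jointly. For trait ``t`` on calf-day
``r`` (calf ``i``, cohort ``c``)::

    y_r      = x_r' beta_t + g_tc + alpha_it + eps_r,   eps_r ~ N(0, sigma_r^2)
    log sigma_r = x_r' beta_d_t + h_tc + delta_it

so the mean part carries a fixed-effect design (intercept, age at grouping,
day number, age x day), a cohort effect and a calf behavioral type
``alpha_it``, and the residual SD itself carries the same design, a cohort
effect and a calf "predictability" deviation ``delta_it``. The six calf
effects ``(alpha_i1..3, delta_i1..3)`` are jointly multivariate normal with
SDs ``(sigma_alpha_1..3, omega_1..3)`` and an unstructured 6x6 correlation
matrix — the object from which among-individual correlations between
behavioral types and predictabilities are read.

Priors: N(0, 5^2) on all fixed effects (standardized response scale),
half-Student-t(3, 0, 2.5) on all SDs, jointly uniform over valid correlation
matrices.

The sampler is a blocked Metropolis-within-Gibbs scheme: all mean-part
blocks (fixed effects, cohort effects, behavioral types) have conjugate
Gaussian full conditionals given the current residual SDs; dispersion-part
parameters, hierarchical SDs and correlation entries are updated by
univariate slice sampling (stepping-out/shrinkage). Calf dispersion effects
have log-concave full conditionals with cheap sufficient statistics
(per-calf residual counts and weighted sums of squares), so the 48 of them
update in a single vectorized slice pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

log = logging.getLogger(__name__)

DEFAULT_TRAITS = ("feeding_rate", "total_meals", "meal_size")
FIXED_EFFECT_NAMES = ("intercept", "age_at_grouping", "day_number", "age_x_day")

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Sampler settings. ``iterations`` includes warmup; kept draws per chain
    are ``(iterations - warmup) // thin``."""

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split-Rhat diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin


def long_mcmc(seed: int = 0) -> MCMCConfig:
    """The long-run preset: 4 chains, 12,000 iterations, 4,000 warmup, thin 4."""
    return MCMCConfig(chains=4, iterations=12_000, warmup=4_000, thin=4, seed=seed)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

class _TraitData:
    __slots__ = ("y", "X", "ci", "co", "n")

    def __init__(self, y, X, ci, co):
        self.y, self.X, self.ci, self.co = y, X, ci, co
        self.n = y.size


class DHGLM:
    """Joint model over the three transformed daily feeding traits.

    Parameters
    ----------
    daily : DataFrame with columns ``calf_id``, ``cohort_id``,
        ``age_at_grouping``, ``day_number`` and one ``<trait><suffix>``
        column per trait (standardized scale). Missing trait values drop only
        that trait's likelihood term for that calf-day.
    """

    def __init__(self, daily: pd.DataFrame,
                 traits: tuple[str, ...] = DEFAULT_TRAITS,
                 suffix: str = "_z"):
        self.traits = tuple(traits)
        if len(self.traits) != 3:
            raise ValueError("the joint model is defined over exactly 3 traits")
        self.calf_ids = np.array(sorted(daily["calf_id"].unique()))
        self.cohort_ids = np.array(sorted(daily["cohort_id"].unique()))
        self.n_calves = self.calf_ids.size
        self.n_cohorts = self.cohort_ids.size
        if self.n_calves < 2:
            raise ValueError("need at least 2 calves to separate between- from "
                             "within-individual variance")
        if self.n_cohorts < 2:
            raise ValueError("need at least 2 cohorts for cohort effects")

        calf_code = pd.Categorical(daily["calf_id"], categories=self.calf_ids).codes
        coh_code = pd.Categorical(daily["cohort_id"], categories=self.cohort_ids).codes

        age = daily["age_at_grouping"].to_numpy(float)
        day = daily["day_number"].to_numpy(float)
        age_z = (age - age.mean()) / (age.std() or 1.0)
        day_z = (day - day.mean()) / (day.std() or 1.0)
        X = np.column_stack([np.ones(len(daily)), age_z, day_z, age_z * day_z])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the offending columns for the error message
            bad = [FIXED_EFFECT_NAMES[j] for j in range(1, X.shape[1])
                   if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
            raise ValueError(f"rank-deficient fixed-effect design; collinear "
                             f"columns: {bad}")

        # per-calf age covariate (constant within calf) for translation moves
        self.age_z_calf = (pd.Series(age_z).groupby(calf_code).first()
                           .reindex(range(self.n_calves)).to_numpy())

        self.data: list[_TraitData] = []
        for trait in self.traits:
            y = daily[trait + suffix].to_numpy(float)
            m = np.isfinite(y)
            if m.sum() < 3:
                raise ValueError(f"trait {trait!r} has fewer than 3 observations")
            self.data.append(_TraitData(y[m], X[m], calf_code[m].astype(np.intp),
                                        coh_code[m].astype(np.intp)))
        self.n_obs = int(sum(d.n for d in self.data))

    # -- joint Gaussian log-likelihood at fixed parameter values -----------
    def loglik(self, params: dict) -> float:
        """Sum over traits and calf-days of the Gaussian log-density with
        mean ``X beta + g + alpha`` and SD ``exp(X beta_d + h + delta)``."""
        beta = np.asarray(params["beta"], float)
        beta_d = np.asarray(params["beta_d"], float)
        g = np.asarray(params["cohort_mean"], float)
        h = np.asarray(params["cohort_disp"], float)
        alpha = np.asarray(params["alpha"], float)
        delta = np.asarray(params["delta"], float)
        total = 0.0
        for t, d in enumerate(self.data):
            mu = d.X @ beta[t] + g[t, d.co] + alpha[d.ci, t]
            eta = d.X @ beta_d[t] + h[t, d.co] + delta[d.ci, t]
            z = (d.y - mu) * np.exp(-eta)
            total += float(np.sum(-0.5 * _LOG2PI - eta - 0.5 * z * z))
        return total


# ---------------------------------------------------------------------------
# slice sampling primitives (Neal 2003, stepping-out and shrinkage)
# ---------------------------------------------------------------------------

def _slice_scalar(x0, logp, rng, w=1.0, max_step=50):
    f0 = logp(x0)
    if not np.isfinite(f0):
        raise FloatingPointError("slice sampler started outside the support")
    logy = f0 + np.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_step):
        if logp(lo) <= logy:
            break
        lo -= w
    for _ in range(max_step):
        if logp(hi) <= logy:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logp(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _slice_vector(x0, logp, rng, w=1.0, max_step=30):
    """Elementwise-independent slice updates for a vector of coordinates."""
    x0 = np.asarray(x0, float)
    f0 = logp(x0)
    logy = f0 + np.log(rng.uniform(size=x0.shape))
    u = rng.uniform(size=x0.shape)
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_step):
        m = logp(lo) > logy
        if not m.any():
            break
        lo = np.where(m, lo - w, lo)
    for _ in range(max_step):
        m = logp(hi) > logy
        if not m.any():
            break
        hi = np.where(m, hi + w, hi)
    x1 = x0.copy()
    todo = np.ones(x0.shape, bool)
    for _ in range(100):
        prop = rng.uniform(lo, hi)
        acc = todo & (logp(prop) >= logy)
        x1 = np.where(acc, prop, x1)
        todo &= ~acc
        if not todo.any():
            break
        shrink_lo = todo & (prop < x0)
        lo = np.where(shrink_lo, prop, lo)
        hi = np.where(todo & ~shrink_lo, prop, hi)
    return x1


def _log_half_t(s, nu=3.0, scale=2.5):
    return -0.5 * (nu + 1.0) * np.log1p(s * s / (nu * scale * scale))


_FIXED_PRIOR_VAR = 25.0


# ---------------------------------------------------------------------------
# the Gibbs sweep
# ---------------------------------------------------------------------------

class _State:
    def __init__(self, model: DHGLM, rng: np.random.Generator):
        T, C, n = len(model.traits), model.n_cohorts, model.n_calves
        self.beta = np.zeros((T, 4))
        self.beta_d = np.zeros((T, 4))
        self.g = np.zeros((T, C))
        self.h = np.zeros((T, C))
        self.tau = np.full(T, 0.3)
        self.tau_d = np.full(T, 0.2)
        self.alpha = np.zeros((n, T))
        self.delta = np.zeros((n, T))
        self.s = np.full(6, 0.3)
        self.R = np.eye(6)
        # data-informed start, jittered per chain
        for t, d in enumerate(model.data):
            coef, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
            self.beta[t] = coef + 0.05 * rng.standard_normal(4)
            resid = d.y - d.X @ coef
            self.beta_d[t, 0] = np.log(max(resid.std(), 1e-3)) + 0.05 * rng.standard_normal()
            means = np.bincount(d.ci, resid, minlength=n) / np.maximum(
                np.bincount(d.ci, minlength=n), 1)
            self.alpha[:, t] = 0.5 * means
            self.s[t] = np.clip(means.std(), 0.05, 2.0)
        self.s[3:] = 0.15
        self.s *= np.exp(0.1 * rng.standard_normal(6))


def _sweep(model: DHGLM, st: _State, rng: np.random.Generator) -> None:
    T = len(model.traits)
    C, n = model.n_cohorts, model.n_calves
    eye4 = np.eye(4)

    # ---- mean part: fixed effects, cohort effects, their SDs -------------
    for t, d in enumerate(model.data):
        eta = d.X @ st.beta_d[t] + st.h[t, d.co] + st.delta[d.ci, t]
        w = np.exp(-2.0 * eta)

        r = d.y - st.g[t, d.co] - st.alpha[d.ci, t]
        Xw = d.X * w[:, None]
        P = d.X.T @ Xw + eye4 / _FIXED_PRIOR_VAR
        cf = cho_factor(P, lower=True)
        mean = cho_solve(cf, Xw.T @ r)
        L = np.linalg.cholesky(P)
        st.beta[t] = mean + np.linalg.solve(L.T, rng.standard_normal(4))

        r2 = d.y - d.X @ st.beta[t] - st.alpha[d.ci, t]
        sw = np.bincount(d.co, w, minlength=C)
        swr = np.bincount(d.co, w * r2, minlength=C)
        prec = sw + 1.0 / st.tau[t] ** 2
        st.g[t] = swr / prec + rng.standard_normal(C) / np.sqrt(prec)

        gsq = float(np.sum(st.g[t] ** 2))

        def lp_tau(x, gsq=gsq):
            tau = np.exp(x)
            return (-C * x - 0.5 * gsq / tau ** 2 + _log_half_t(tau) + x)

        st.tau[t] = float(np.exp(_slice_scalar(np.log(st.tau[t]), lp_tau, rng, w=0.7)))

    # ---- calf behavioral types (joint conjugate 3-vector per calf) -------
    S11 = np.outer(st.s[:3], st.s[:3]) * st.R[:3, :3]
    S12 = np.outer(st.s[:3], st.s[3:]) * st.R[:3, 3:]
    S22 = np.outer(st.s[3:], st.s[3:]) * st.R[3:, 3:]
    A = S12 @ np.linalg.inv(S22)              # regression of alpha on delta
    C_cond = S11 - A @ S12.T
    C_inv = np.linalg.inv((C_cond + C_cond.T) / 2.0)
    m_cond = st.delta @ A.T                   # (n, 3)

    W = np.zeros((n, T))
    B = np.zeros((n, T))
    for t, d in enumerate(model.data):
        eta = d.X @ st.beta_d[t] + st.h[t, d.co] + st.delta[d.ci, t]
        w = np.exp(-2.0 * eta)
        r3 = d.y - d.X @ st.beta[t] - st.g[t, d.co]
        W[:, t] = np.bincount(d.ci, w, minlength=n)
        B[:, t] = np.bincount(d.ci, w * r3, minlength=n)
    P = C_inv[None, :, :] + np.einsum("nt,ts->nts", W, np.eye(T))
    rhs = m_cond @ C_inv.T + B
    Lb = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
    z = rng.standard_normal((n, T, 1))
    st.alpha = mean + np.linalg.solve(np.transpose(Lb, (0, 2, 1)), z)[:, :, 0]

    # ---- dispersion part --------------------------------------------------
    Q = np.linalg.inv(np.outer(st.s, st.s) * st.R)   # joint calf-effect precision
    for t, d in enumerate(model.data):
        res = d.y - d.X @ st.beta[t] - st.g[t, d.co] - st.alpha[d.ci, t]
        res2 = res * res

        base = st.h[t, d.co] + st.delta[d.ci, t]
        for j in range(4):
            xj = d.X[:, j]
            other = d.X @ st.beta_d[t] - xj * st.beta_d[t, j] + base

            def lp_bd(bj, other=other, xj=xj, res2=res2):
                e = other + xj * bj
                return (-np.sum(e) - 0.5 * np.sum(res2 * np.exp(-2.0 * e))
                        - 0.5 * bj * bj / _FIXED_PRIOR_VAR)

            st.beta_d[t, j] = _slice_scalar(st.beta_d[t, j], lp_bd, rng, w=0.3)

        eta0 = d.X @ st.beta_d[t] + st.delta[d.ci, t]
        Sc = np.bincount(d.co, res2 * np.exp(-2.0 * eta0), minlength=C)
        nc = np.bincount(d.co, minlength=C).astype(float)
        taud2 = st.tau_d[t] ** 2

        def lp_h(hv, Sc=Sc, nc=nc, taud2=taud2):
            return -nc * hv - 0.5 * Sc * np.exp(-2.0 * hv) - 0.5 * hv * hv / taud2

        st.h[t] = _slice_vector(st.h[t], lp_h, rng, w=0.3)

        hsq = float(np.sum(st.h[t] ** 2))

        def lp_taud(x, hsq=hsq):
            tau = np.exp(x)
            return -C * x - 0.5 * hsq / tau ** 2 + _log_half_t(tau) + x

        st.tau_d[t] = float(np.exp(_slice_scalar(np.log(st.tau_d[t]), lp_taud, rng, w=0.7)))

        # calf dispersion effects: conditional normal prior from the joint
        # 6-D calf-effect distribution + log-concave likelihood
        k = T + t
        U = np.concatenate([st.alpha, st.delta], axis=1)
        m_c = -(U @ Q[k] - U[:, k] * Q[k, k]) / Q[k, k]
        v_c = 1.0 / Q[k, k]
        eta1 = d.X @ st.beta_d[t] + st.h[t, d.co]
        Si = np.bincount(d.ci, res2 * np.exp(-2.0 * eta1), minlength=n)
        ni = np.bincount(d.ci, minlength=n).astype(float)

        def lp_delta(dv, Si=Si, ni=ni, m_c=m_c, v_c=v_c):
            return (-ni * dv - 0.5 * Si * np.exp(-2.0 * dv)
                    - 0.5 * (dv - m_c) ** 2 / v_c)

        st.delta[:, t] = _slice_vector(st.delta[:, t], lp_delta, rng, w=0.25)

    # ---- calf-effect SDs, correlation matrix, reparameterization moves ----
    # this block is cheap relative to the O(n_obs) parts, so it runs twice
    # per sweep to speed mixing of the hyperparameters
    for _ in range(2):
        U = np.concatenate([st.alpha, st.delta], axis=1)
        M = U.T @ U
        QR = np.linalg.inv(st.R)
        QM = QR * M
        for k in range(6):
            def lp_s(x, k=k):
                sk = np.exp(x)
                v = 1.0 / st.s
                v[k] = 1.0 / sk
                quad = v @ QM @ v
                return -n * x - 0.5 * quad + _log_half_t(sk) + x

            st.s[k] = float(np.exp(_slice_scalar(np.log(st.s[k]), lp_s, rng, w=0.5)))

        Z = M / np.outer(st.s, st.s)
        for j in range(6):
            for k in range(j + 1, 6):
                # -n/2 log|R| - 1/2 tr(R^-1 Z); uniform prior, PD support
                def lp_r(r, j=j, k=k):
                    if not -1.0 < r < 1.0:
                        return -np.inf
                    R = st.R.copy()
                    R[j, k] = R[k, j] = r
                    try:
                        cf = cho_factor(R, lower=True)
                    except np.linalg.LinAlgError:
                        return -np.inf
                    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                    return -0.5 * n * logdet - 0.5 * np.trace(cho_solve(cf, Z))

                r_new = _slice_scalar(st.R[j, k], lp_r, rng, w=0.2)
                st.R[j, k] = st.R[k, j] = r_new

        _reparam_moves(model, st, rng)


def _reparam_moves(model: DHGLM, st: _State, rng: np.random.Generator) -> None:
    """Exact auxiliary Gibbs moves that break posterior ridges.

    Translation moves shift mass between an intercept and the mean of the
    random effects it is confounded with (likelihood-invariant, so the full
    conditional of the shift is Gaussian in the priors alone). Interweaved
    scale moves resample each calf-effect SD with the standardized effects
    held fixed (the non-centered parameterization), which decorrelates the
    SD from the effect magnitudes near zero.
    """
    T = len(model.traits)
    C, n = model.n_cohorts, model.n_calves
    Q = np.linalg.inv(np.outer(st.s, st.s) * st.R)
    a = model.age_z_calf
    a_sq = float(np.sum(a * a))

    def _shift_calf_effects(col_k, intercept_get, intercept_set, direction):
        """One translation draw along a likelihood-invariant direction:
        fixed effect += e, calf-effect column -= e * direction."""
        U = np.concatenate([st.alpha, st.delta], axis=1)
        d_sq = float(np.sum(direction * direction))
        P = 1.0 / _FIXED_PRIOR_VAR + d_sq * Q[col_k, col_k]
        m = (Q[col_k] @ (U.T @ direction) - intercept_get() / _FIXED_PRIOR_VAR) / P
        e = m + rng.standard_normal() / np.sqrt(P)
        intercept_set(e)
        return e

    ones = np.ones(n)
    for t in range(T):
        # intercept <-> cohort effects (mean part)
        P = 1.0 / _FIXED_PRIOR_VAR + C / st.tau[t] ** 2
        m = (st.g[t].sum() / st.tau[t] ** 2 - st.beta[t, 0] / _FIXED_PRIOR_VAR) / P
        e = m + rng.standard_normal() / np.sqrt(P)
        st.beta[t, 0] += e
        st.g[t] -= e
        # intercept <-> behavioral types
        e = _shift_calf_effects(t, lambda: st.beta[t, 0],
                                lambda e: None, ones)
        st.beta[t, 0] += e
        st.alpha[:, t] -= e
        # age coefficient <-> behavioral types (age is constant within calf)
        e = _shift_calf_effects(t, lambda: st.beta[t, 1],
                                lambda e: None, a)
        st.beta[t, 1] += e
        st.alpha[:, t] -= e * a
        # dispersion intercept <-> cohort dispersion effects
        P = 1.0 / _FIXED_PRIOR_VAR + C / st.tau_d[t] ** 2
        m = (st.h[t].sum() / st.tau_d[t] ** 2 - st.beta_d[t, 0] / _FIXED_PRIOR_VAR) / P
        e = m + rng.standard_normal() / np.sqrt(P)
        st.beta_d[t, 0] += e
        st.h[t] -= e
        # dispersion intercept <-> calf dispersion effects
        k = T + t
        e = _shift_calf_effects(k, lambda: st.beta_d[t, 0],
                                lambda e: None, ones)
        st.beta_d[t, 0] += e
        st.delta[:, t] -= e
        # dispersion age coefficient <-> calf dispersion effects
        e = _shift_calf_effects(k, lambda: st.beta_d[t, 1],
                                lambda e: None, a)
        st.beta_d[t, 1] += e
        st.delta[:, t] -= e * a

    # interweaved (non-centered) scale updates for the cohort-effect SDs
    for t, d in enumerate(model.data):
        tau_old = max(st.tau[t], 1e-12)
        zg = st.g[t] / tau_old
        eta = d.X @ st.beta_d[t] + st.h[t, d.co] + st.delta[d.ci, t]
        w = np.exp(-2.0 * eta)
        rg = d.y - d.X @ st.beta[t] - st.alpha[d.ci, t]
        zr = zg[d.co]
        a_g = float(np.sum(w * zr * zr))
        b_g = float(np.sum(w * rg * zr))

        def lp_tau_nc(x, a=a_g, b=b_g):
            tau = np.exp(x)
            return -0.5 * tau * tau * a + tau * b + _log_half_t(tau) + x

        st.tau[t] = float(np.exp(_slice_scalar(np.log(tau_old), lp_tau_nc, rng, w=0.5)))
        st.g[t] = st.tau[t] * zg

        taud_old = max(st.tau_d[t], 1e-12)
        zh = st.h[t] / taud_old
        base = d.X @ st.beta_d[t] + st.delta[d.ci, t]
        res = rg - st.g[t, d.co]
        cr = res * res * np.exp(-2.0 * base)
        zr = zh[d.co]
        zsum = float(zr.sum())

        def lp_taud_nc(x, zr=zr, cr=cr, zsum=zsum):
            tau = np.exp(x)
            return (-tau * zsum - 0.5 * float(np.sum(cr * np.exp(-2.0 * tau * zr)))
                    + _log_half_t(tau) + x)

        st.tau_d[t] = float(np.exp(_slice_scalar(np.log(taud_old), lp_taud_nc, rng, w=0.5)))
        st.h[t] = st.tau_d[t] * zh

    # interweaved (non-centered) scale updates: hold z = u_k / s_k fixed
    for t, d in enumerate(model.data):
        # mean-part SD: Gaussian likelihood is quadratic in s
        s_old = max(st.s[t], 1e-12)
        z = st.alpha[:, t] / s_old
        eta = d.X @ st.beta_d[t] + st.h[t, d.co] + st.delta[d.ci, t]
        w = np.exp(-2.0 * eta)
        r3 = d.y - d.X @ st.beta[t] - st.g[t, d.co]
        zr = z[d.ci]
        a = float(np.sum(w * zr * zr))
        b = float(np.sum(w * r3 * zr))

        def lp_s_mean(x, a=a, b=b):
            s = np.exp(x)
            return -0.5 * s * s * a + s * b + _log_half_t(s) + x

        st.s[t] = float(np.exp(_slice_scalar(np.log(s_old), lp_s_mean, rng, w=0.5)))
        st.alpha[:, t] = st.s[t] * z

        # dispersion-part SD: log-linear likelihood in s
        k = T + t
        s_old = max(st.s[k], 1e-12)
        z = st.delta[:, t] / s_old
        base = d.X @ st.beta_d[t] + st.h[t, d.co]
        res = r3 - st.alpha[d.ci, t]
        cr = res * res * np.exp(-2.0 * base)
        zr = z[d.ci]
        zsum = float(zr.sum())

        def lp_s_disp(x, zr=zr, cr=cr, zsum=zsum):
            s = np.exp(x)
            return (-s * zsum - 0.5 * float(np.sum(cr * np.exp(-2.0 * s * zr)))
                    + _log_half_t(s) + x)

        st.s[k] = float(np.exp(_slice_scalar(np.log(s_old), lp_s_disp, rng, w=0.5)))
        st.delta[:, t] = st.s[k] * z


# ---------------------------------------------------------------------------
# posterior container and fit driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC sample container: every array is (chains, draws, ...)."""

    params: dict[str, np.ndarray]
    traits: tuple[str, ...]
    calf_ids: np.ndarray
    cohort_ids: np.ndarray

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Chains and draws flattened into one leading axis."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def thin(self, k: int) -> "PosteriorDraws":
        return PosteriorDraws({n: a[:, ::k] for n, a in self.params.items()},
                              self.traits, self.calf_ids, self.cohort_ids)

    def validate(self) -> None:
        if (self.params["sigma_alpha"] < 0).any() or (self.params["omega"] < 0).any():
            raise AssertionError("negative SD draw")
        corr = self.params["corr"]
        if (np.abs(corr) > 1 + 1e-9).any():
            raise AssertionError("correlation draw outside [-1, 1]")
        if not np.allclose(corr, np.swapaxes(corr, -1, -2)):
            raise AssertionError("correlation draws not symmetric")

    def to_arviz(self, include_calf_effects: bool = False):
        import arviz as az
        keep = {"beta", "beta_d", "sigma_alpha", "omega", "tau", "tau_d",
                "corr", "loglik"}
        if include_calf_effects:
            keep |= {"alpha", "delta", "cohort_mean", "cohort_disp"}
        return az.from_dict({k: v for k, v in self.params.items() if k in keep})

    # -- persistence: CSV per chain + JSON metadata -------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flat_names: list[str] = []
        mats = []
        for name, a in self.params.items():
            flat = a.reshape(a.shape[0], a.shape[1], -1)
            mats.append(flat)
            extra = int(np.prod(a.shape[2:])) if a.ndim > 2 else 1
            flat_names += ([name] if extra == 1 else
                           [f"{name}[{i}]" for i in range(extra)])
        stacked = np.concatenate(mats, axis=2)
        for c in range(self.n_chains):
            pd.DataFrame(stacked[c], columns=flat_names).to_csv(
                outdir / f"chain_{c + 1}.csv", index=False)
        meta = {"traits": list(self.traits),
                "calf_ids": self.calf_ids.tolist(),
                "cohort_ids": self.cohort_ids.tolist(),
                "shapes": {k: list(v.shape[2:]) for k, v in self.params.items()},
                "n_chains": self.n_chains, "n_draws": self.n_draws}
        (outdir / "draws_meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, outdir: str | Path) -> "PosteriorDraws":
        outdir = Path(outdir)
        meta = json.loads((outdir / "draws_meta.json").read_text())
        chains = [pd.read_csv(outdir / f"chain_{c + 1}.csv")
                  for c in range(meta["n_chains"])]
        params: dict[str, np.ndarray] = {}
        col = 0
        all_vals = np.stack([c.to_numpy() for c in chains])
        for name, shp in meta["shapes"].items():
            k = int(np.prod(shp)) if shp else 1
            block = all_vals[:, :, col:col + k]
            params[name] = block.reshape(meta["n_chains"], meta["n_draws"], *shp)
            col += k
        return cls(params, tuple(meta["traits"]), np.asarray(meta["calf_ids"]),
                   np.asarray(meta["cohort_ids"]))


def _store(model: DHGLM, st: _State, out: dict, c: int, k: int) -> None:
    out["beta"][c, k] = st.beta
    out["beta_d"][c, k] = st.beta_d
    out["cohort_mean"][c, k] = st.g
    out["cohort_disp"][c, k] = st.h
    out["tau"][c, k] = st.tau
    out["tau_d"][c, k] = st.tau_d
    out["alpha"][c, k] = st.alpha
    out["delta"][c, k] = st.delta
    out["sigma_alpha"][c, k] = st.s[:3]
    out["omega"][c, k] = st.s[3:]
    out["corr"][c, k] = st.R
    out["loglik"][c, k] = model.loglik({
        "beta": st.beta, "beta_d": st.beta_d, "cohort_mean": st.g,
        "cohort_disp": st.h, "alpha": st.alpha, "delta": st.delta})


def fit(model: DHGLM, mcmc: MCMCConfig | None = None
        ) -> tuple[PosteriorDraws, dict]:
    """Run the sampler and return draws plus convergence diagnostics.

    Diagnostics contain split-R-hat and bulk ESS per monitored parameter, a
    list of parameters violating the configured thresholds, and a posterior
    predictive summary (mean, SD and five quantiles of replicated vs observed
    data per trait).
    """
    import arviz as az

    mcmc = mcmc or MCMCConfig()
    T, C, n = len(model.traits), model.n_cohorts, model.n_calves
    kept = mcmc.kept_per_chain
    out = {
        "beta": np.empty((mcmc.chains, kept, T, 4)),
        "beta_d": np.empty((mcmc.chains, kept, T, 4)),
        "cohort_mean": np.empty((mcmc.chains, kept, T, C)),
        "cohort_disp": np.empty((mcmc.chains, kept, T, C)),
        "tau": np.empty((mcmc.chains, kept, T)),
        "tau_d": np.empty((mcmc.chains, kept, T)),
        "alpha": np.empty((mcmc.chains, kept, n, T)),
        "delta": np.empty((mcmc.chains, kept, n, T)),
        "sigma_alpha": np.empty((mcmc.chains, kept, T)),
        "omega": np.empty((mcmc.chains, kept, T)),
        "corr": np.empty((mcmc.chains, kept, 6, 6)),
        "loglik": np.empty((mcmc.chains, kept)),
    }
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        st = _State(model, rng)
        k = 0
        for it in range(mcmc.iterations):
            _sweep(model, st, rng)
            if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0 and k < kept:
                _store(model, st, out, c, k)
                k += 1
        log.info("chain %d/%d finished (%d kept draws)", c + 1, mcmc.chains, k)

    draws = PosteriorDraws(out, model.traits, np.asarray(model.calf_ids),
                           np.asarray(model.cohort_ids))
    draws.validate()

    idata = draws.to_arviz()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    flagged = []
    for name in ("beta", "beta_d", "sigma_alpha", "omega", "corr"):
        r = np.asarray(rhat[name]).ravel()
        e = np.asarray(ess[name]).ravel()
        for i, (ri, ei) in enumerate(zip(r, e)):
            if np.isfinite(ri) and ri > mcmc.rhat_threshold:
                flagged.append({"param": f"{name}[{i}]", "rhat": float(ri)})
            if np.isfinite(ei) and ei < mcmc.ess_threshold:
                flagged.append({"param": f"{name}[{i}]", "ess": float(ei)})
    diagnostics = {
        "max_rhat": float(np.nanmax([np.nanmax(np.asarray(rhat[v]))
                                     for v in ("beta", "beta_d", "sigma_alpha",
                                               "omega")])),
        "min_ess": float(np.nanmin([np.nanmin(np.asarray(ess[v]))
                                    for v in ("beta", "beta_d", "sigma_alpha",
                                              "omega")])),
        "flagged": flagged,
        "ppc": posterior_predictive_summary(model, draws),
    }
    return draws, diagnostics


def posterior_predictive_summary(model: DHGLM, draws: PosteriorDraws,
                                 n_rep: int = 50, seed: int = 0) -> dict:
    """Mean, SD and five quantiles of replicated vs observed data per trait."""
    rng = np.random.default_rng(seed)
    total = draws.n_chains * draws.n_draws
    idx = np.linspace(0, total - 1, min(n_rep, total)).astype(int)
    beta = draws.stacked("beta")[idx]
    beta_d = draws.stacked("beta_d")[idx]
    g = draws.stacked("cohort_mean")[idx]
    h = draws.stacked("cohort_disp")[idx]
    alpha = draws.stacked("alpha")[idx]
    delta = draws.stacked("delta")[idx]
    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    out = {}
    for t, trait in enumerate(model.traits):
        d = model.data[t]
        reps = np.empty((idx.size, d.n))
        for r in range(idx.size):
            mu = d.X @ beta[r, t] + g[r, t, d.co] + alpha[r, d.ci, t]
            sd = np.exp(d.X @ beta_d[r, t] + h[r, t, d.co] + delta[r, d.ci, t])
            reps[r] = mu + sd * rng.standard_normal(d.n)
        out[trait] = {
            "observed": {"mean": float(d.y.mean()), "sd": float(d.y.std(ddof=1)),
                         "quantiles": [float(q) for q in np.quantile(d.y, qs)]},
            "replicated": {"mean": float(reps.mean()), "sd": float(reps.std(ddof=1)),
                           "quantiles": [float(q) for q in np.quantile(reps, qs)]},
        }
    return out
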
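"""Hierarchical Bayesian estimation of the diffusion-model variants.

Subjects' diffusion parameters are partially pooled: each subject's drift in a
condition x morph cell is normal around the group cell mean; boundary
separation, starting point and nondecision time live on unconstrained scales
(log a, logit z, log t0) with normal group hierarchies, which respects the
parameter domains and yields conjugate Gibbs updates for the group means and
variances.  Subject-level parameters are updated by adaptive single-site
random-walk Metropolis (proposal scales tuned toward 44% acceptance during
burn-in and frozen afterwards).  The per-iteration deviance (-2 log likelihood
of the contaminant-mixture model) is recorded for DIC model comparison.

The starting-point-on-PSE regression replaces the group mean of logit z with a
linear predictor ``b0 + b1 * PSE_std`` (inverse-logit link, standardized
predictor), mirroring regression-style estimation of trial-history covariate
effects on the starting point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .ddm import SERIES_EPS, _wfpt_pdf
from .models import Design, ModelSpec, build_design

__all__ = [
    "GroupPrior",
    "PosteriorSamples",
    "DicResult",
    "sample_posterior",
    "compute_dic",
    "directional_prob",
    "bayes_factor",
    "format_bf",
    "regress_z_on_pse",
    "condition_mean_drift",
]


@dataclass(frozen=True)
class GroupPrior:
    """Weakly-informative hyperpriors for the group-level parameters.

    Group means: v cells ~ N(0, pv_v); log a ~ N(log 1.5, pv_la);
    logit z ~ N(0, pv_lz); log t0 ~ N(log 0.3, pv_lt).  Group variances get
    inverse-gamma(ig_a, ig_b_*) priors on each scale.  Regression coefficients
    (intercept, slope of logit z on standardized PSE) ~ N(0, pv_beta).
    """

    pv_v: float = 25.0
    m_la: float = math.log(1.5)
    pv_la: float = 1.0
    m_lz: float = 0.0
    pv_lz: float = 1.0
    m_lt: float = math.log(0.3)
    pv_lt: float = 1.0
    ig_a: float = 2.0
    ig_b_v: float = 0.5
    ig_b_la: float = 0.05
    ig_b_lz: float = 0.05
    ig_b_lt: float = 0.05
    pv_beta: float = 25.0


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _ll_cell(rt, up, start, count, v, a, z, t0, p_out, t_max):
    out = 0.0
    unif = 0.0
    if p_out > 0.0:
        unif = p_out / t_max * 0.5
    for i in range(start, start + count):
        dens = (1.0 - p_out) * _wfpt_pdf(rt[i], up[i] != 0, v, a, z, t0, SERIES_EPS) + unif
        if dens <= 0.0:
            return -np.inf
        out += math.log(dens)
    return out


@njit(cache=True)
def _deviance_at(rt, up, cell_start, cell_count, v_s, a_s, z_s, t0_s, p_out, t_max):
    n_subj, n_morph = cell_start.shape
    total = 0.0
    for s in range(n_subj):
        for m in range(n_morph):
            total += _ll_cell(
                rt, up, cell_start[s, m], cell_count[s, m],
                v_s[s, m], a_s[s], z_s[s], t0_s[s], p_out, t_max,
            )
    return -2.0 * total


@njit(cache=True)
def _mcmc(
    rt, up, cell_start, cell_count,
    cond_of_subj, zcell_of_subj, acell_of_subj,
    n_cond, n_zcells, n_acells,
    z_free, z_reg, x_reg,
    n_iter, n_burn, seed, p_out, t_max, v_init,
    pv_v, m_la, pv_la, m_lz, pv_lz, m_lt, pv_lt,
    ig_a, ig_b_v, ig_b_la, ig_b_lz, ig_b_lt, pv_beta,
):
    np.random.seed(seed)
    n_subj, n_morph = cell_start.shape

    # --- state
    v_s = np.empty((n_subj, n_morph))
    for s in range(n_subj):
        for m in range(n_morph):
            v_s[s, m] = v_init[cond_of_subj[s], m]
    la_s = np.full(n_subj, math.log(1.5))
    lz_s = np.zeros(n_subj)
    lt_s = np.empty(n_subj)
    for s in range(n_subj):
        lo = 1e30
        for m in range(n_morph):
            for i in range(cell_start[s, m], cell_start[s, m] + cell_count[s, m]):
                if rt[i] < lo:
                    lo = rt[i]
        t0g = 0.85 * lo
        if t0g > 0.5:
            t0g = 0.5
        if t0g < 0.05:
            t0g = 0.05
        lt_s[s] = math.log(t0g)

    mu_v = v_init.copy()
    sig_v = 0.3
    mu_la = np.full(max(n_acells, 1), m_la)
    sig_la = 0.15
    mu_lz = np.full(max(n_zcells, 1), 0.0)
    sig_lz = 0.15
    b0 = 0.0
    b1 = 0.0
    mu_lt = m_lt
    sig_lt = 0.15

    # --- likelihood cache
    ll = np.empty((n_subj, n_morph))
    for s in range(n_subj):
        a = math.exp(la_s[s])
        z = 1.0 / (1.0 + math.exp(-lz_s[s])) if z_free else 0.5
        t0 = math.exp(lt_s[s])
        for m in range(n_morph):
            ll[s, m] = _ll_cell(rt, up, cell_start[s, m], cell_count[s, m],
                                v_s[s, m], a, z, t0, p_out, t_max)

    # --- adaptive proposal scales
    step_v = np.full((n_subj, n_morph), 0.3)
    step_la = np.full(n_subj, 0.08)
    step_lz = np.full(n_subj, 0.1)
    step_lt = np.full(n_subj, 0.08)
    acc_v = np.zeros((n_subj, n_morph))
    acc_la = np.zeros(n_subj)
    acc_lz = np.zeros(n_subj)
    acc_lt = np.zeros(n_subj)
    n_win = 0

    # --- storage
    mu_v_dr = np.empty((n_iter, n_cond, n_morph))
    sig_v_dr = np.empty(n_iter)
    mu_la_dr = np.empty((n_iter, max(n_acells, 1)))
    sig_la_dr = np.empty(n_iter)
    mu_lz_dr = np.empty((n_iter, max(n_zcells, 1)))
    sig_lz_dr = np.empty(n_iter)
    b_dr = np.empty((n_iter, 2))
    mu_lt_dr = np.empty(n_iter)
    sig_lt_dr = np.empty(n_iter)
    v_s_dr = np.empty((n_iter, n_subj, n_morph))
    la_s_dr = np.empty((n_iter, n_subj))
    lz_s_dr = np.empty((n_iter, n_subj))
    lt_s_dr = np.empty((n_iter, n_subj))
    dev_dr = np.empty(n_iter)

    tmp = np.empty(n_morph)

    for it in range(n_iter):
        # ---------------- subject-level Metropolis updates
        for s in range(n_subj):
            c = cond_of_subj[s]
            a = math.exp(la_s[s])
            z = 1.0 / (1.0 + math.exp(-lz_s[s])) if z_free else 0.5
            t0 = math.exp(lt_s[s])

            for m in range(n_morph):
                if cell_count[s, m] == 0:
                    continue
                prop = v_s[s, m] + step_v[s, m] * np.random.normal()
                llp = _ll_cell(rt, up, cell_start[s, m], cell_count[s, m],
                               prop, a, z, t0, p_out, t_max)
                dpr = (-(prop - mu_v[c, m]) ** 2 + (v_s[s, m] - mu_v[c, m]) ** 2) / (
                    2.0 * sig_v * sig_v
                )
                if llp - ll[s, m] + dpr > math.log(np.random.random() + 1e-300):
                    v_s[s, m] = prop
                    ll[s, m] = llp
                    acc_v[s, m] += 1.0

            # boundary separation (log scale)
            prop = la_s[s] + step_la[s] * np.random.normal()
            ap = math.exp(prop)
            tot_new = 0.0
            tot_old = 0.0
            for m in range(n_morph):
                tmp[m] = _ll_cell(rt, up, cell_start[s, m], cell_count[s, m],
                                  v_s[s, m], ap, z, t0, p_out, t_max)
                tot_new += tmp[m]
                tot_old += ll[s, m]
            mm = mu_la[acell_of_subj[s]]
            dpr = (-(prop - mm) ** 2 + (la_s[s] - mm) ** 2) / (2.0 * sig_la * sig_la)
            if tot_new - tot_old + dpr > math.log(np.random.random() + 1e-300):
                la_s[s] = prop
                a = ap
                for m in range(n_morph):
                    ll[s, m] = tmp[m]
                acc_la[s] += 1.0

            # starting point (logit scale)
            if z_free:
                prop = lz_s[s] + step_lz[s] * np.random.normal()
                zp = 1.0 / (1.0 + math.exp(-prop))
                tot_new = 0.0
                tot_old = 0.0
                for m in range(n_morph):
                    tmp[m] = _ll_cell(rt, up, cell_start[s, m], cell_count[s, m],
                                      v_s[s, m], a, zp, t0, p_out, t_max)
                    tot_new += tmp[m]
                    tot_old += ll[s, m]
                if z_reg:
                    mm = b0 + b1 * x_reg[s]
                else:
                    mm = mu_lz[zcell_of_subj[s]]
                dpr = (-(prop - mm) ** 2 + (lz_s[s] - mm) ** 2) / (2.0 * sig_lz * sig_lz)
                if tot_new - tot_old + dpr > math.log(np.random.random() + 1e-300):
                    lz_s[s] = prop
                    z = zp
                    for m in range(n_morph):
                        ll[s, m] = tmp[m]
                    acc_lz[s] += 1.0

            # nondecision time (log scale)
            prop = lt_s[s] + step_lt[s] * np.random.normal()
            tp = math.exp(prop)
            tot_new = 0.0
            tot_old = 0.0
            for m in range(n_morph):
                tmp[m] = _ll_cell(rt, up, cell_start[s, m], cell_count[s, m],
                                  v_s[s, m], a, z, tp, p_out, t_max)
                tot_new += tmp[m]
                tot_old += ll[s, m]
            dpr = (-(prop - mu_lt) ** 2 + (lt_s[s] - mu_lt) ** 2) / (2.0 * sig_lt * sig_lt)
            if tot_new - tot_old + dpr > math.log(np.random.random() + 1e-300):
                lt_s[s] = prop
                for m in range(n_morph):
                    ll[s, m] = tmp[m]
                acc_lt[s] += 1.0

        # ---------------- Gibbs updates for group-level parameters
        # drift cell means and shared spread
        ssq = 0.0
        n_tot = 0
        for c in range(n_cond):
            for m in range(n_morph):
                sx = 0.0
                nc = 0
                for s in range(n_subj):
                    if cond_of_subj[s] == c:
                        sx += v_s[s, m]
                        nc += 1
                if nc > 0:
                    prec = nc / (sig_v * sig_v) + 1.0 / pv_v
                    mean = (sx / (sig_v * sig_v)) / prec
                    mu_v[c, m] = mean + np.random.normal() / math.sqrt(prec)
                for s in range(n_subj):
                    if cond_of_subj[s] == c:
                        ssq += (v_s[s, m] - mu_v[c, m]) ** 2
                        n_tot += 1
        var = (ig_b_v + 0.5 * ssq) / np.random.gamma(ig_a + 0.5 * n_tot, 1.0)
        sig_v = max(math.sqrt(var), 1e-3)

        # boundary separation
        ssq = 0.0
        for cidx in range(max(n_acells, 1)):
            sx = 0.0
            nc = 0
            for s in range(n_subj):
                if acell_of_subj[s] == cidx:
                    sx += la_s[s]
                    nc += 1
            if nc > 0:
                prec = nc / (sig_la * sig_la) + 1.0 / pv_la
                mean = (sx / (sig_la * sig_la) + m_la / pv_la) / prec
                mu_la[cidx] = mean + np.random.normal() / math.sqrt(prec)
            for s in range(n_subj):
                if acell_of_subj[s] == cidx:
                    ssq += (la_s[s] - mu_la[cidx]) ** 2
        var = (ig_b_la + 0.5 * ssq) / np.random.gamma(ig_a + 0.5 * n_subj, 1.0)
        sig_la = max(math.sqrt(var), 1e-3)

        # starting point
        if z_free:
            if z_reg:
                # conjugate bivariate-normal update of (b0, b1)
                s2 = sig_lz * sig_lz
                xx00 = n_subj / s2 + 1.0 / pv_beta
                xx01 = 0.0
                xx11 = 1.0 / pv_beta
                xy0 = 0.0
                xy1 = 0.0
                for s in range(n_subj):
                    xx01 += x_reg[s] / s2
                    xx11 += x_reg[s] * x_reg[s] / s2
                    xy0 += lz_s[s] / s2
                    xy1 += x_reg[s] * lz_s[s] / s2
                det = xx00 * xx11 - xx01 * xx01
                c00 = xx11 / det
                c01 = -xx01 / det
                c11 = xx00 / det
                mb0 = c00 * xy0 + c01 * xy1
                mb1 = c01 * xy0 + c11 * xy1
                l00 = math.sqrt(c00)
                l10 = c01 / l00
                l11 = math.sqrt(max(c11 - l10 * l10, 1e-12))
                e0 = np.random.normal()
                e1 = np.random.normal()
                b0 = mb0 + l00 * e0
                b1 = mb1 + l10 * e0 + l11 * e1
                ssq = 0.0
                for s in range(n_subj):
                    ssq += (lz_s[s] - b0 - b1 * x_reg[s]) ** 2
            else:
                ssq = 0.0
                for cidx in range(max(n_zcells, 1)):
                    sx = 0.0
                    nc = 0
                    for s in range(n_subj):
                        if zcell_of_subj[s] == cidx:
                            sx += lz_s[s]
                            nc += 1
                    if nc > 0:
                        prec = nc / (sig_lz * sig_lz) + 1.0 / pv_lz
                        mean = (sx / (sig_lz * sig_lz) + m_lz / pv_lz) / prec
                        mu_lz[cidx] = mean + np.random.normal() / math.sqrt(prec)
                    for s in range(n_subj):
                        if zcell_of_subj[s] == cidx:
                            ssq += (lz_s[s] - mu_lz[cidx]) ** 2
            var = (ig_b_lz + 0.5 * ssq) / np.random.gamma(ig_a + 0.5 * n_subj, 1.0)
            sig_lz = max(math.sqrt(var), 1e-3)

        # nondecision time
        sx = 0.0
        for s in range(n_subj):
            sx += lt_s[s]
        prec = n_subj / (sig_lt * sig_lt) + 1.0 / pv_lt
        mean = (sx / (sig_lt * sig_lt) + m_lt / pv_lt) / prec
        mu_lt = mean + np.random.normal() / math.sqrt(prec)
        ssq = 0.0
        for s in range(n_subj):
            ssq += (lt_s[s] - mu_lt) ** 2
        var = (ig_b_lt + 0.5 * ssq) / np.random.gamma(ig_a + 0.5 * n_subj, 1.0)
        sig_lt = max(math.sqrt(var), 1e-3)

        # ---------------- adaptation (burn-in only)
        n_win += 1
        if it < n_burn and n_win == 25:
            for s in range(n_subj):
                for m in range(n_morph):
                    rate = acc_v[s, m] / 25.0
                    step_v[s, m] = min(max(step_v[s, m] * math.exp(1.5 * (rate - 0.44)), 1e-3), 3.0)
                    acc_v[s, m] = 0.0
                for arr, st in ((acc_la, step_la), (acc_lz, step_lz), (acc_lt, step_lt)):
                    rate = arr[s] / 25.0
                    st[s] = min(max(st[s] * math.exp(1.5 * (rate - 0.44)), 1e-3), 3.0)
                    arr[s] = 0.0
            n_win = 0

        # ---------------- record
        mu_v_dr[it] = mu_v
        sig_v_dr[it] = sig_v
        mu_la_dr[it] = mu_la
        sig_la_dr[it] = sig_la
        mu_lz_dr[it] = mu_lz
        sig_lz_dr[it] = sig_lz
        b_dr[it, 0] = b0
        b_dr[it, 1] = b1
        mu_lt_dr[it] = mu_lt
        sig_lt_dr[it] = sig_lt
        v_s_dr[it] = v_s
        la_s_dr[it] = la_s
        lz_s_dr[it] = lz_s
        lt_s_dr[it] = lt_s
        dev = 0.0
        for s in range(n_subj):
            for m in range(n_morph):
                dev += ll[s, m]
        dev_dr[it] = -2.0 * dev

    return (mu_v_dr, sig_v_dr, mu_la_dr, sig_la_dr, mu_lz_dr, sig_lz_dr, b_dr,
            mu_lt_dr, sig_lt_dr, v_s_dr, la_s_dr, lz_s_dr, lt_s_dr, dev_dr)


# ---------------------------------------------------------------------------
# python-facing containers and operations


def _ilogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


@dataclass
class PosteriorSamples:
    """MCMC draws for group- and subject-level parameters plus deviance.

    ``group`` maps names like ``v[ownership,45]``, ``z[ownership]``, ``a``,
    ``t0``, ``z_slope`` to arrays of shape (n_chains, n_samples).  Access via
    :meth:`get` returns the flattened post-burn draws.
    """

    group: dict
    subject: dict  # name -> (n_chains, n_samples, n_subj[, n_morph])
    deviance: np.ndarray  # (n_chains, n_samples)
    n_samples: int
    n_burn: int
    seed: int
    design: Design

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def names(self):
        return list(self.group)

    def get(self, name: str) -> np.ndarray:
        """Post-burn draws of a group-level parameter, flattened over chains."""
        if name not in self.group:
            raise KeyError(f"unknown parameter {name!r}; available: {self.names}")
        return self.group[name][:, self.n_burn:].reshape(-1)

    def subject_post(self, name: str) -> np.ndarray:
        arr = self.subject[name]
        return arr[:, self.n_burn:].reshape((-1,) + arr.shape[2:])

    def deviance_post(self) -> np.ndarray:
        return self.deviance[:, self.n_burn:].reshape(-1)

    def summary(self):
        import pandas as pd

        rows = []
        for name in self.names:
            x = self.get(name)
            rows.append(
                dict(parameter=name, mean=x.mean(), sd=x.std(ddof=1),
                     q2_5=np.quantile(x, 0.025), q97_5=np.quantile(x, 0.975),
                     rhat=self.rhat(name))
            )
        return pd.DataFrame(rows)

    def rhat(self, name: str) -> float:
        """Split-R-hat of a group parameter (halved chains via arviz)."""
        import arviz as az

        arr = self.group[name][:, self.n_burn:]
        n = arr.shape[1] // 2
        split = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(az.rhat(az.convert_to_dataset(split))["x"].values)

    def check_convergence(self, threshold: float = 1.05) -> dict:
        """Split-R-hat per group parameter; warns (never raises) on excess."""
        rhats = {name: self.rhat(name) for name in self.names}
        bad = {k: v for k, v in rhats.items() if np.isfinite(v) and v > threshold}
        if bad:
            warnings.warn(f"split-R-hat above {threshold} for: {bad}")
        return rhats


def _v_init_from_data(design: Design) -> np.ndarray:
    """Crude per-cell drift start values from pooled choice fractions."""
    n_cond = len(design.conditions)
    v0 = np.zeros((n_cond, design.n_morph))
    for c in range(n_cond):
        subj = np.where(design.cond_of_subj == c)[0]
        for m in range(design.n_morph):
            k = n = 0
            for s in subj:
                st, ct = design.cell_start[s, m], design.cell_count[s, m]
                k += design.upper[st : st + ct].sum()
                n += ct
            if n > 0:
                p = min(max(k / n, 0.02), 0.98)
                v0[c, m] = np.clip(math.log(p / (1 - p)) / 1.6, -4, 4)
    return v0


def sample_posterior(
    design: Design,
    n_samples: int = 10_000,
    n_burn: int = 1_000,
    seed: int = 0,
    priors: GroupPrior | None = None,
    n_chains: int = 1,
    x_reg: np.ndarray | None = None,
) -> PosteriorSamples:
    """Run the Metropolis-within-Gibbs sampler on a packed design.

    ``x_reg`` (one standardized covariate value per subject) switches the
    starting-point hierarchy to the regression parameterization.  Reproducible
    given ``seed``; chain k uses seed + 1000*k.
    """
    if n_burn >= n_samples:
        raise ValueError("n_burn must be < n_samples")
    pr = priors or GroupPrior()
    spec = design.spec
    z_reg = x_reg is not None
    if z_reg and not spec.z_free:
        raise ValueError("regression on the starting point requires a z-free model")
    xr = np.asarray(x_reg, dtype=float) if z_reg else np.zeros(design.n_subjects)
    v0 = _v_init_from_data(design)

    chains = []
    for k in range(n_chains):
        out = _mcmc(
            design.rt, design.upper, design.cell_start, design.cell_count,
            design.cond_of_subj, design.zcell_of_subj, design.acell_of_subj,
            len(design.conditions), design.n_zcells, design.n_acells,
            spec.z_free, z_reg, xr,
            n_samples, n_burn, int(seed + 1000 * k) % (2**31 - 1), design.p_out,
            design.t_max, v0,
            pr.pv_v, pr.m_la, pr.pv_la, pr.m_lz, pr.pv_lz, pr.m_lt, pr.pv_lt,
            pr.ig_a, pr.ig_b_v, pr.ig_b_la, pr.ig_b_lz, pr.ig_b_lt, pr.pv_beta,
        )
        chains.append(out)

    def stack(i):
        return np.stack([ch[i] for ch in chains])

    mu_v, sig_v, mu_la, sig_la, mu_lz, sig_lz, b = (stack(i) for i in range(7))
    mu_lt, sig_lt, v_s, la_s, lz_s, lt_s, dev = (stack(i) for i in range(7, 14))

    group: dict[str, np.ndarray] = {}
    for c, cond in enumerate(design.conditions):
        for m, morph in enumerate(design.morph_levels):
            group[f"v[{cond},{morph:g}]"] = mu_v[:, :, c, m]
    group["sigma_v"] = sig_v
    if design.n_acells > 1:
        for c, cond in enumerate(design.conditions):
            group[f"a[{cond}]"] = np.exp(mu_la[:, :, c])
    else:
        group["a"] = np.exp(mu_la[:, :, 0])
    if z_reg:
        group["z_intercept"] = b[:, :, 0]
        group["z_slope"] = b[:, :, 1]
    elif spec.z_free:
        if design.n_zcells > 1:
            for c, cond in enumerate(design.conditions):
                group[f"z[{cond}]"] = _ilogit(mu_lz[:, :, c])
        else:
            group["z"] = _ilogit(mu_lz[:, :, 0])
    group["t0"] = np.exp(mu_lt)

    subject = {"v": v_s, "log_a": la_s, "logit_z": lz_s, "log_t0": lt_s}
    post = PosteriorSamples(
        group=group, subject=subject, deviance=dev,
        n_samples=n_samples, n_burn=n_burn, seed=seed, design=design,
    )
    post.check_convergence()
    return post


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    d_bar: float
    d_hat: float


def compute_dic(posterior: PosteriorSamples, design: Design | None = None) -> DicResult:
    """Deviance information criterion: DIC = D(theta-bar) + 2 p_D.

    ``p_D = mean deviance - deviance at the posterior mean`` of the
    subject-level parameters, taken on their unconstrained scales.
    """
    design = design or posterior.design
    dev = posterior.deviance_post()
    if dev.size == 0:
        raise RuntimeError("posterior has no post-burn deviance draws")
    v_s = posterior.subject_post("v").mean(axis=0)
    a_s = np.exp(posterior.subject_post("log_a").mean(axis=0))
    t0_s = np.exp(posterior.subject_post("log_t0").mean(axis=0))
    if design.spec.z_free:
        z_s = _ilogit(posterior.subject_post("logit_z").mean(axis=0))
    else:
        z_s = np.full(design.n_subjects, 0.5)
    d_hat = float(
        _deviance_at(design.rt, design.upper, design.cell_start, design.cell_count,
                     v_s, a_s, z_s, t0_s, design.p_out, design.t_max)
    )
    d_bar = float(dev.mean())
    p_d = d_bar - d_hat
    return DicResult(dic=d_hat + 2.0 * p_d, p_d=p_d, d_bar=d_bar, d_hat=d_hat)


def directional_prob(posterior: PosteriorSamples, greater: str, lesser) -> float:
    """Posterior probability AGAINST the direction ``greater > lesser``.

    ``lesser`` may be a parameter name or a constant.  Small values indicate
    strong directional evidence, matching the convention in which p_Bayes is
    the fraction of posterior draws violating the stated inequality.
    """
    g = posterior.get(greater)
    l = posterior.get(lesser) if isinstance(lesser, str) else float(lesser)
    return float(np.mean(g <= l))


def bayes_factor(p_bayes: float) -> float:
    """Directional Bayes factor BF10 = (1 - p) / p for a posterior probability.

    At the bounds (p = 0 or 1) the evidence saturates and the BF is reported
    as an infinite bound; use :func:`format_bf` for the printed form.
    """
    if p_bayes < 0.0 or p_bayes > 1.0:
        raise ValueError(f"p_bayes must be in [0,1], got {p_bayes}")
    if p_bayes == 0.0:
        return math.inf
    if p_bayes == 1.0:
        return 0.0
    return (1.0 - p_bayes) / p_bayes


def format_bf(bf: float) -> str:
    """Printed form: rounded to the nearest integer, '>999' beyond that."""
    if not math.isfinite(bf) or bf > 999:
        return ">999"
    return str(round(bf))


def regress_z_on_pse(
    trials,
    pse_per_participant: dict,
    n_samples: int = 2000,
    n_burn: int = 500,
    seed: int = 0,
    priors: GroupPrior | None = None,
    p_out: float = 0.05,
) -> PosteriorSamples:
    """Hierarchical fit with subject logit-z linked to the standardized PSE.

    ``z_s = inv-logit(b0 + b1 * PSE_std_s)`` plus subject noise.  A negative
    slope means reductions in the PSE go with increases in the starting point.
    Returns the posterior including ``z_intercept`` and ``z_slope``.
    """
    spec = ModelSpec.from_variant("M2")
    design = build_design(trials, spec, p_out=p_out)
    x = np.array([pse_per_participant[s] for s in design.subjects], dtype=float)
    sd = x.std(ddof=0)
    if sd < 1e-12:
        raise ValueError("PSE predictor is constant; regression is degenerate")
    x_std = (x - x.mean()) / sd
    return sample_posterior(
        design, n_samples=n_samples, n_burn=n_burn, seed=seed,
        priors=priors, x_reg=x_std,
    )


def condition_mean_drift(posterior: PosteriorSamples, condition: str) -> float:
    """Posterior mean of the sign-folded drift, averaged over morph cells.

    Folding (|v|) summarizes how fast evidence accumulates regardless of which
    boundary it favors, giving one information-uptake number per condition.
    """
    design = posterior.design
    cells = [f"v[{condition},{m:g}]" for m in design.morph_levels]
    draws = np.stack([posterior.get(c) for c in cells])
    return float(np.abs(draws).mean())
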
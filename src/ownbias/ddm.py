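"""Wiener diffusion primitives for two-choice decisions.

The drift-diffusion model (DDM) describes a binary decision as noisy evidence
accumulating between two absorbing boundaries separated by ``a``, starting at
relative position ``z`` (fraction of ``a``), with mean rate ``v`` (drift) and
unit diffusion coefficient.  A response is emitted when a boundary is reached;
the observed response time adds a nondecision constant ``t0``.  The upper
boundary is conventionally the *self-related* response in this package.

This module provides the first-passage-time density at each boundary
(a truncated-series evaluation with small-time / large-time regime switching),
closed-form absorption probabilities, a reproducible trial simulator based on
numerical inversion of the defective CDFs, and a contaminant-mixture
log-likelihood in which a fixed fraction ``p_out`` of trials is attributed to
a uniform outlier process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "wfpt_density",
    "choice_probability",
    "simulate_trials",
    "log_likelihood",
]

#: absolute truncation error guaranteed per density evaluation
SERIES_EPS = 1e-7


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a single diffusion process.

    v
        Drift rate (evidence units / s, signed; positive drives toward the
        upper = self boundary).
    a
        Boundary separation (> 0).
    z
        Relative starting point, fraction of ``a``, in (0, 1); 0.5 is unbiased.
    t0
        Nondecision time in seconds (>= 0).
    p_out
        Contaminant fraction in [0, 1): probability that a trial comes from a
        uniform outlier process rather than the diffusion.
    """

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.3
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative starting point z must be in (0,1), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"nondecision time t0 must be >= 0, got {self.t0}")
        if not (0.0 <= self.p_out < 1.0):
            raise ValueError(f"contaminant fraction p_out must be in [0,1), got {self.p_out}")


@njit(cache=True)
def _f_standard(tt: float, w: float, eps: float) -> float:
    """First-passage density at the lower boundary for v=0, a=1, start w,
    at normalized time tt, using whichever series expansion is cheaper."""
    if tt <= 0.0:
        return 0.0
    # number of terms for the large-time expansion
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    # number of terms for the small-time expansion
    if 2.0 * eps * math.sqrt(2.0 * math.pi * tt) < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            u = w + 2.0 * k
            p += u * math.exp(-u * u / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def _wfpt_lower(t: float, v: float, a: float, w: float, eps: float) -> float:
    """Density of absorption at the LOWER boundary at decision time t."""
    if t <= 0.0:
        return 0.0
    tt = t / (a * a)
    return math.exp(-v * a * w - v * v * t / 2.0) / (a * a) * _f_standard(tt, w, eps)


@njit(cache=True)
def _wfpt_pdf(rt: float, upper: bool, v: float, a: float, z: float, t0: float, eps: float) -> float:
    """Defective first-passage density at ``rt`` for the given boundary.

    The upper-boundary density is obtained from the lower-boundary formula by
    the reflection v -> -v, z -> 1 - z.
    """
    t = rt - t0
    if t <= 0.0:
        return 0.0
    if upper:
        return _wfpt_lower(t, -v, a, 1.0 - z, eps)
    return _wfpt_lower(t, v, a, z, eps)


@njit(cache=True)
def _loglik_mixture(
    rts: np.ndarray,
    uppers: np.ndarray,
    v: float,
    a: float,
    z: float,
    t0: float,
    p_out: float,
    t_max: float,
) -> float:
    """Sum of per-trial log densities under the contaminant mixture."""
    out = 0.0
    unif = 0.0
    if p_out > 0.0:
        unif = p_out / t_max * 0.5  # uniform over (0, t_max], mass split over boundaries
    for i in range(rts.shape[0]):
        dens = (1.0 - p_out) * _wfpt_pdf(rts[i], uppers[i] != 0, v, a, z, t0, SERIES_EPS)
        dens += unif
        if dens <= 0.0:
            return -np.inf
        out += math.log(dens)
    return out


def wfpt_density(rt, choice, params: DDMParams):
    """First-passage density (1/s) of the diffusion at ``rt`` for ``choice``.

    ``choice`` is ``"upper"``/``"lower"`` (or 1/0).  The density is defective:
    integrated over rt and summed over both boundaries it equals 1.  The
    contaminant component is *not* included here (see :func:`log_likelihood`).
    """
    upper = _as_upper(choice)
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    out = np.empty_like(rt_arr)
    for i, t in enumerate(rt_arr):
        out[i] = _wfpt_pdf(t, upper, params.v, params.a, params.z, params.t0, SERIES_EPS)
    return out[0] if np.isscalar(rt) or np.ndim(rt) == 0 else out


def _as_upper(choice) -> bool:
    if isinstance(choice, str):
        c = choice.lower()
        if c in ("upper", "self", "1"):
            return True
        if c in ("lower", "friend", "0"):
            return False
        raise ValueError(f"unknown boundary label {choice!r}")
    return bool(choice)


def choice_probability(params: DDMParams, boundary="upper") -> float:
    """Closed-form absorption probability at the given boundary.

    For drift v, separation a, relative start z the probability of reaching
    the upper boundary first is ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))``,
    which reduces to ``z`` as v -> 0.
    """
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-10:
        p_up = z
    else:
        # expm1 keeps this stable for small |v a|
        p_up = math.expm1(-2.0 * v * a * z) / math.expm1(-2.0 * v * a)
    p_up = min(max(p_up, 0.0), 1.0)
    return p_up if _as_upper(boundary) else 1.0 - p_up


# ---------------------------------------------------------------------------
# simulation by numerical inversion of the defective CDFs


@njit(cache=True)
def _density_grid(ts: np.ndarray, v: float, a: float, z: float) -> tuple:
    """Defective densities at decision times ``ts`` for both boundaries."""
    n = ts.shape[0]
    f_up = np.empty(n)
    f_lo = np.empty(n)
    for i in range(n):
        f_up[i] = _wfpt_lower(ts[i], -v, a, 1.0 - z, SERIES_EPS)
        f_lo[i] = _wfpt_lower(ts[i], v, a, z, SERIES_EPS)
    return f_up, f_lo


def _decision_time_cdfs(v: float, a: float, z: float, n_grid: int = 2048):
    """Grids of decision time and conditional CDFs per boundary.

    The time horizon is extended until at least 1 - 1e-5 of the total mass is
    captured, so inverse sampling loses only negligible tail mass.
    """
    t_hi = max(4.0 * a * a, 2.0)
    for _ in range(30):
        # sqrt spacing resolves the sharp early peak of the density
        ts = np.linspace(0.0, math.sqrt(t_hi), n_grid) ** 2
        f_up, f_lo = _density_grid(ts, v, a, z)
        from scipy.integrate import cumulative_trapezoid

        c_up = np.concatenate([[0.0], cumulative_trapezoid(f_up, ts)])
        c_lo = np.concatenate([[0.0], cumulative_trapezoid(f_lo, ts)])
        if c_up[-1] + c_lo[-1] >= 1.0 - 1e-5:
            return ts, c_up, c_lo
        t_hi *= 2.0
    return ts, c_up, c_lo


def simulate_trials(params: DDMParams, n: int, seed=None, rng=None):
    """Draw ``n`` (choice, rt) pairs from the diffusion (plus contaminants).

    Choices are sampled from the closed-form absorption probabilities and
    decision times by inverting the boundary-conditional first-passage CDFs on
    an adaptive grid.  With probability ``p_out`` a trial is replaced by a
    contaminant: uniform RT on (0, t0 + q99] with a coin-flip choice.

    Returns ``(choices, rts)`` as int (1=upper) and float arrays.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    ts, c_up, c_lo = _decision_time_cdfs(params.v, params.a, params.z)
    total = c_up[-1] + c_lo[-1]
    p_up = c_up[-1] / total

    choices = (rng.random(n) < p_up).astype(np.int64)
    u = rng.random(n)
    rts = np.empty(n)
    for b, cdf in ((1, c_up), (0, c_lo)):
        m = choices == b
        if not m.any():
            continue
        rts[m] = np.interp(u[m] * cdf[-1], cdf, ts)
    rts += params.t0

    if params.p_out > 0:
        is_out = rng.random(n) < params.p_out
        n_out = int(is_out.sum())
        if n_out:
            q99 = params.t0 + float(np.interp(0.99 * total, c_up + c_lo, ts))
            rts[is_out] = rng.uniform(0.0, q99, n_out)
            choices[is_out] = rng.integers(0, 2, n_out)
    return choices, rts


def log_likelihood(trials, params: DDMParams, t_max: float | None = None) -> float:
    """Joint log-likelihood of trials under the contaminant-mixture model.

    Per trial the density is ``(1-p_out)*wfpt + p_out * uniform(0, t_max]/2``,
    the outlier mass split equally over the two boundaries.  ``t_max`` defaults
    to the 99th percentile of the observed RTs, matching the convention used
    when fitting.  ``trials`` is ``(choices, rts)`` arrays or a DataFrame with
    ``response``/``rt_s`` columns.

    Returns -inf (rather than raising) when ``p_out == 0`` and some rt <= t0.
    """
    choices, rts = _coerce_trials(trials)
    if rts.size == 0:
        raise ValueError("empty trial list")
    if t_max is None:
        t_max = float(np.quantile(rts, 0.99))
    return float(
        _loglik_mixture(
            rts,
            choices.astype(np.int64),
            params.v,
            params.a,
            params.z,
            params.t0,
            params.p_out,
            t_max,
        )
    )


def _coerce_trials(trials):
    if isinstance(trials, tuple):
        choices, rts = trials
        return np.asarray(choices), np.asarray(rts, dtype=float)
    # assume DataFrame-like
    from .io import RESPONSE_UPPER

    choices = np.asarray([1 if r in RESPONSE_UPPER else 0 for r in trials["response"]])
    return choices, np.asarray(trials["rt_s"], dtype=float)
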
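"""Psychometric analysis of morph-continuum classification.

Per participant and condition a cumulative logistic

    P(self | morph) = 1 / (1 + exp(-beta * (morph - alpha)))

is fitted by maximum likelihood to the binary self/friend responses.  The
location ``alpha`` is the point of subjective equality (PSE): the morph level
(in % self-owned-object information) at which both classifications are equally
likely.  Deviations of the group-mean PSE from the objective midpoint of the
continuum (50%) index a classification bias; a *leftward* shift (PSE < 50)
means less self-related information is needed to trigger a self response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "PsychCurve",
    "GroupPseResult",
    "filter_trials",
    "fit_logistic",
    "fit_participants",
    "exclude_random_responders",
    "pse",
    "group_tests",
]

#: responses faster than this (seconds) are treated as anticipations and dropped
FAST_RT_CUTOFF = 0.200

#: objective midpoint of the morph continuum, % self
MIDPOINT = 50.0


@dataclass
class PsychCurve:
    """Fitted cumulative logistic for one participant x condition."""

    alpha: float  # location = PSE, % self
    beta: float  # slope per % unit, > 0 after orientation normalization
    n_trials: int
    participant: object = None
    condition: str | None = None
    converged: bool = True

    @property
    def pse(self) -> float:
        return self.alpha

    def predict(self, morph):
        """P(self response) at the given morph level(s)."""
        return special.expit(self.beta * (np.asarray(morph, float) - self.alpha))


@dataclass
class GroupPseResult:
    """One- or two-sample inference on PSE values."""

    kind: str  # "one-sample" | "two-sample"
    mean: float
    sd: float
    t: float
    df: int
    p: float
    d: float
    delta: float
    ci_low: float
    ci_high: float
    n: tuple


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop anticipatory responses (rt < 200 ms).

    Returns the kept trials and a per-participant exclusion report with the
    fraction of trials removed.
    """
    fast = trials["rt_s"] < FAST_RT_CUTOFF
    report = (
        trials.assign(excluded=fast)
        .groupby("participant", sort=False)["excluded"]
        .agg(n_total="size", n_excluded="sum")
        .reset_index()
    )
    report["frac_excluded"] = report["n_excluded"] / report["n_total"]
    kept = trials.loc[~fast].reset_index(drop=True)
    if kept.empty:
        warnings.warn("all trials removed by the fast-response filter")
    return kept, report


def _aggregate(morph, self_resp):
    morph = np.asarray(morph, float)
    self_resp = np.asarray(self_resp, float)
    levels = np.unique(morph)
    k = np.array([self_resp[morph == m].sum() for m in levels])
    n = np.array([(morph == m).sum() for m in levels])
    return levels, k, n


def _nll(params, levels, k, n):
    alpha, beta = params
    p = special.expit(beta * (levels - alpha))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))


_BOUNDS = [(-100.0, 200.0), (1e-4, 10.0)]


def fit_logistic(morph, self_resp, participant=None, condition=None) -> PsychCurve:
    """Maximum-likelihood cumulative-logistic fit of P(self) against morph.

    ``morph`` is % self-object information; ``self_resp`` is 0/1 per trial.
    Deterministic (fixed optimizer settings, multi-start over coarse alpha
    grid).  If the responses are inverted (probability decreasing in morph)
    the fitted beta is negative before normalization; the curve is re-oriented
    so beta > 0 and the reported alpha is unchanged.  Complete separation is
    handled by the bounded slope (fit pinned at the bound, with a warning).
    """
    levels, k, n = _aggregate(morph, self_resp)
    if len(levels) < 2:
        raise ValueError("need responses at >= 2 distinct morph levels")

    best = None
    for a0 in (35.0, 50.0, 65.0):
        for b0 in (0.05, 0.15, 0.5):
            res = optimize.minimize(
                _nll, x0=[a0, b0], args=(levels, k, n), method="L-BFGS-B", bounds=_BOUNDS
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    alpha, beta = best.x
    # orientation: allow a decreasing fit by also trying negative slope
    res_neg = optimize.minimize(
        _nll, x0=[alpha, -0.15], args=(levels, k, n), method="L-BFGS-B",
        bounds=[_BOUNDS[0], (-10.0, -1e-4)],
    )
    if res_neg.fun < best.fun - 1e-9:
        alpha, beta = res_neg.x
        beta = abs(beta)  # normalize orientation; alpha (the 50% point) is unchanged
    if beta >= _BOUNDS[1][1] - 1e-6:
        warnings.warn("slope at bound: responses may be completely separated")
    return PsychCurve(
        alpha=float(alpha),
        beta=float(beta),
        n_trials=int(n.sum()),
        participant=participant,
        condition=condition,
        converged=bool(best.success),
    )


def fit_participants(trials: pd.DataFrame) -> list[PsychCurve]:
    """One cumulative-logistic fit per participant (condition carried along)."""
    curves = []
    for (pid, cond), grp in trials.groupby(["participant", "condition"], sort=False):
        self01 = _self_indicator(grp["response"])
        curves.append(fit_logistic(grp["morph_pct_self"], self01, participant=pid, condition=cond))
    return curves


def _self_indicator(resp) -> np.ndarray:
    from .io import RESPONSE_UPPER

    return np.asarray([1 if r in RESPONSE_UPPER else 0 for r in resp])


def exclude_random_responders(
    trials: pd.DataFrame,
    curves: list[PsychCurve],
    alpha_level: float = 0.01,
    anchor_min_accuracy: float = 0.60,
) -> tuple[list[PsychCurve], list]:
    """Drop participants whose responding is flat across morph levels.

    A participant is excluded when EITHER (a) a likelihood-ratio test of their
    fitted logistic against a constant-probability model fails to reject
    flatness at ``alpha_level``, OR (b) accuracy on the unambiguous anchor
    stimuli (morph 0 and 100) falls below ``anchor_min_accuracy``.
    """
    kept, excluded = [], []
    by_pid = {(c.participant, c.condition): c for c in curves}
    for (pid, cond), grp in trials.groupby(["participant", "condition"], sort=False):
        curve = by_pid.get((pid, cond))
        if curve is None:
            continue
        self01 = _self_indicator(grp["response"])
        levels, k, n = _aggregate(grp["morph_pct_self"], self01)
        # LR test: logistic (2 df) vs constant probability (1 df)
        p_hat = np.clip(k.sum() / n.sum(), 1e-12, 1 - 1e-12)
        nll_const = -np.sum(k * np.log(p_hat) + (n - k) * np.log(1 - p_hat))
        nll_logit = _nll([curve.alpha, curve.beta], levels, k, n)
        lr = max(0.0, 2.0 * (nll_const - nll_logit))
        p_flat = stats.chi2.sf(lr, df=1)

        morph = np.asarray(grp["morph_pct_self"], float)
        anchors = (morph == 0) | (morph == 100)
        if anchors.any():
            correct = np.where(morph[anchors] == 100, self01[anchors], 1 - self01[anchors])
            anchor_acc = correct.mean()
        else:
            anchor_acc = 1.0

        if p_flat > alpha_level or anchor_acc < anchor_min_accuracy:
            excluded.append(pid)
        else:
            kept.append(curve)
    return kept, excluded


def pse(curve: PsychCurve) -> float:
    """The point of subjective equality in % self: P(self | PSE) = 0.5."""
    return curve.alpha


def group_tests(pse_by_condition: dict, reference: float = MIDPOINT) -> dict:
    """One-sample t-tests of each condition's PSEs against the midpoint, plus
    the pooled-variance two-sample comparison between conditions.

    Cohen's d is (mean - reference)/SD for one-sample tests and the
    pooled-SD standardized mean difference for the two-sample test.
    Returns ``{condition: GroupPseResult, ..., "<c1> vs <c2>": GroupPseResult}``.
    """
    out = {}
    conds = list(pse_by_condition)
    for cond in conds:
        x = np.asarray(pse_by_condition[cond], float)
        if x.size < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 participants")
        t, p = stats.ttest_1samp(x, reference)
        sd = x.std(ddof=1)
        n = x.size
        se = sd / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        out[cond] = GroupPseResult(
            kind="one-sample",
            mean=float(x.mean()),
            sd=float(sd),
            t=float(t),
            df=n - 1,
            p=float(p),
            d=float((x.mean() - reference) / sd),
            delta=float(x.mean() - reference),
            ci_low=float(x.mean() - tcrit * se),
            ci_high=float(x.mean() + tcrit * se),
            n=(n,),
        )
    if len(conds) == 2:
        x = np.asarray(pse_by_condition[conds[0]], float)
        y = np.asarray(pse_by_condition[conds[1]], float)
        n1, n2 = x.size, y.size
        t, p = stats.ttest_ind(x, y)  # pooled variance
        sp = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
        delta = x.mean() - y.mean()
        se = sp * np.sqrt(1 / n1 + 1 / n2)
        tcrit = stats.t.ppf(0.975, n1 + n2 - 2)
        out[f"{conds[0]} vs {conds[1]}"] = GroupPseResult(
            kind="two-sample",
            mean=float(delta),
            sd=float(sp),
            t=float(t),
            df=n1 + n2 - 2,
            p=float(p),
            d=float(delta / sp) if sp > 0 else 0.0,
            delta=float(delta),
            ci_low=float(delta - tcrit * se),
            ci_high=float(delta + tcrit * se),
            n=(n1, n2),
        )
    return out
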
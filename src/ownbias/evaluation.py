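"""Posterior predictive checking and drift-based psychometric functions.

A fitted model is probed by simulating complete datasets from joint posterior
draws (one draw per dataset, so the bands reflect parameter uncertainty),
refitting the psychometric pipeline to each, and asking whether the empirical
per-morph response probabilities and group PSEs fall inside the simulated 95%
bands.  Drift-based psychometric functions summarize the posterior of the
per-morph drift cells — a process-level analogue of the choice curves that
stays informative when accuracy saturates at the unambiguous anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_trials
from .inference import PosteriorSamples, _ilogit
from .models import Design
from .psychometrics import fit_participants

__all__ = ["PpcResult", "posterior_predict", "drift_psychometric", "compare_curves"]


@dataclass
class PpcResult:
    """Quantitative posterior-predictive comparison per condition."""

    n_datasets: int
    pse_emp: dict  # condition -> empirical group-mean PSE
    pse_sim: dict  # condition -> array of simulated group-mean PSEs
    pse_inside: dict  # condition -> empirical PSE inside simulated 95% band?
    prob_table: pd.DataFrame  # per condition x morph response-probability bands

    @property
    def misfit(self) -> bool:
        return not all(self.pse_inside.values())

    def summary(self) -> pd.DataFrame:
        rows = []
        for cond, emp in self.pse_emp.items():
            sim = self.pse_sim[cond]
            rows.append(
                dict(condition=cond, pse_emp=emp, pse_sim_mean=sim.mean(),
                     pse_sim_lo=np.quantile(sim, 0.025),
                     pse_sim_hi=np.quantile(sim, 0.975),
                     abs_discrepancy=abs(emp - sim.mean()),
                     inside_band=self.pse_inside[cond])
            )
        return pd.DataFrame(rows)


def posterior_predict(
    posterior: PosteriorSamples,
    design: Design | None = None,
    n_datasets: int = 10,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Simulate datasets with the input's exact trial structure.

    Each dataset uses the subject-level parameters of one randomly chosen
    post-burn joint draw; choices/RTs are then sampled from the diffusion for
    every subject x morph cell at the cell's observed trial count.
    """
    design = design or posterior.design
    rng = np.random.default_rng(seed)
    v_s = posterior.subject_post("v")
    a_s = np.exp(posterior.subject_post("log_a"))
    t0_s = np.exp(posterior.subject_post("log_t0"))
    if design.spec.z_free:
        z_s = _ilogit(posterior.subject_post("logit_z"))
    else:
        z_s = np.full((v_s.shape[0], design.n_subjects), 0.5)
    if v_s.shape[1] != design.n_subjects or v_s.shape[2] != design.n_morph:
        raise ValueError("posterior and design have mismatched subjects/morph cells")

    datasets = []
    draw_idx = rng.integers(0, v_s.shape[0], n_datasets)
    for d in draw_idx:
        rows = []
        for s, pid in enumerate(design.subjects):
            cond = design.conditions[design.cond_of_subj[s]]
            for m, morph in enumerate(design.morph_levels):
                n_m = int(design.cell_count[s, m])
                if n_m == 0:
                    continue
                params = DDMParams(
                    v=float(v_s[d, s, m]), a=float(a_s[d, s]),
                    z=float(z_s[d, s]), t0=float(t0_s[d, s]),
                )
                ch, rt = simulate_trials(params, n_m, rng=rng)
                rows.append(
                    pd.DataFrame(
                        dict(participant=pid, condition=cond, morph_pct_self=morph,
                             response=np.where(ch == 1, "self", "friend"), rt_s=rt)
                    )
                )
        datasets.append(pd.concat(rows, ignore_index=True))
    return datasets


def drift_psychometric(posterior: PosteriorSamples, hdi_prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central interval of drift per condition x morph.

    Includes a monotonicity diagnostic: the number of adjacent inversions in
    the posterior-mean drift sequence along the morph axis (0 = perfectly
    monotone, as expected when uptake speeds up away from maximal ambiguity).
    """
    design = posterior.design
    lo_q, hi_q = (1 - hdi_prob) / 2, 1 - (1 - hdi_prob) / 2
    rows = []
    for cond in design.conditions:
        means = []
        for morph in design.morph_levels:
            draws = posterior.get(f"v[{cond},{morph:g}]")
            means.append(draws.mean())
            rows.append(
                dict(condition=cond, morph=float(morph), v_mean=draws.mean(),
                     v_lo=np.quantile(draws, lo_q), v_hi=np.quantile(draws, hi_q))
            )
        inversions = int(np.sum(np.diff(means) < 0))
        for r in rows[-len(design.morph_levels):]:
            r["inversions"] = inversions
    return pd.DataFrame(rows)


def _group_pse_and_probs(trials: pd.DataFrame):
    curves = fit_participants(trials)
    pse = {}
    for cond in sorted(set(c.condition for c in curves)):
        pse[cond] = float(np.mean([c.alpha for c in curves if c.condition == cond]))
    self01 = trials["response"].eq("self").astype(float)
    probs = (
        trials.assign(self01=self01)
        .groupby(["condition", "morph_pct_self"])["self01"]
        .mean()
    )
    return pse, probs


def compare_curves(empirical: pd.DataFrame, simulated: list[pd.DataFrame]) -> PpcResult:
    """Empirical vs posterior-simulated psychometric behavior, per condition.

    Reports the absolute difference between the empirical group-mean PSE and
    the mean simulated PSE, whether the empirical PSE falls inside the
    simulated 95% band, and per-morph response-probability bands.
    """
    pse_emp, probs_emp = _group_pse_and_probs(empirical)
    sims = [_group_pse_and_probs(s) for s in simulated]
    conds = list(pse_emp)
    for p, _ in sims:
        if list(p) != conds:
            raise ValueError("simulated datasets have different conditions than empirical")

    pse_sim = {c: np.array([p[c] for p, _ in sims]) for c in conds}
    pse_inside = {
        c: bool(
            np.quantile(pse_sim[c], 0.025) <= pse_emp[c] <= np.quantile(pse_sim[c], 0.975)
        )
        for c in conds
    }
    rows = []
    for (cond, morph), p_emp in probs_emp.items():
        sim_vals = np.array([pr.get((cond, morph), np.nan) for _, pr in sims])
        lo, hi = np.nanquantile(sim_vals, [0.025, 0.975])
        rows.append(
            dict(condition=cond, morph=float(morph), p_emp=float(p_emp),
                 p_sim_mean=float(np.nanmean(sim_vals)), p_sim_lo=float(lo),
                 p_sim_hi=float(hi), inside=bool(lo <= p_emp <= hi))
        )
    return PpcResult(
        n_datasets=len(simulated), pse_emp=pse_emp, pse_sim=pse_sim,
        pse_inside=pse_inside, prob_table=pd.DataFrame(rows),
    )
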
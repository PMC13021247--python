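"""Synthetic replicates of the two morph-classification experiments.

Experiment 1 crosses Judgment (ownership vs identity, between subjects) with
Owner (self vs friend, within); Experiment 2 crosses Presentation Duration
(short vs long, between) with Owner.  Each participant completes 7 blocks of
80 trials over an 8-level morph continuum (each level 10 times per block, so
70 per level overall).  Choices and RTs are drawn from the diffusion model:
each subject gets group-sampled (a, t0, z, v_max) and the drift at morph m is
the antisymmetric linear map ``v = v_max * (2 m / 100 - 1)``, so drift is zero
at maximal ambiguity and largest at the unmorphed anchors.

Default group means encode the fitted signatures of the two experiments: a
small self-ward starting-point bias where a self-centric strategy applies
(z = 0.52 ownership vs 0.50 identity; 0.53 short vs 0.52 long) and drift
scales whose folded per-condition means reproduce the reported information-
uptake rates (0.95/0.87 and 1.05/0.99) under the linear map, for which the
folded mean over the grid is 0.5 * v_max.  Boundary separation 1.6 and
nondecision time 0.35 s are unreported in the source analyses and are
realistic conventions for speeded binary classification.  Between-subject SDs
default to 10% of each mean.  Contaminants (fast guesses and uniform slow
outliers) are injected to exercise the exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_trials
from .io import MORPH_GRID

__all__ = [
    "ExperimentConfig",
    "generate_experiment",
    "morph_to_drift",
    "inject_contaminants",
    "recovery_config",
    "logistic_cohort",
]

_DEFAULTS = {
    1: dict(
        conditions=("ownership", "identity"),
        z_mean={"ownership": 0.52, "identity": 0.50},
        v_max_mean={"ownership": 1.74, "identity": 1.90},
    ),
    2: dict(
        conditions=("short", "long"),
        z_mean={"short": 0.53, "long": 0.52},
        v_max_mean={"short": 2.10, "long": 1.98},
    ),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Generative configuration for one synthetic experiment."""

    experiment: int
    conditions: tuple
    z_mean: dict
    v_max_mean: dict
    n_per_cell: int = 40
    morph_grid: tuple = MORPH_GRID
    blocks: int = 7
    trials_per_block: int = 80
    a_mean: float = 1.6
    t0_mean: float = 0.35
    rel_sd: float = 0.10  # between-subject SD as a fraction of each mean
    z_sd: float | None = None  # overrides rel_sd * z_mean when set
    fast_frac: float = 0.01
    outlier_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        per_block, rem = divmod(self.trials_per_block, len(self.morph_grid))
        if rem or per_block < 1:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} is not a multiple of "
                f"the {len(self.morph_grid)}-level morph grid"
            )
        for cond in self.conditions:
            if cond not in self.z_mean or cond not in self.v_max_mean:
                raise ValueError(f"missing generative values for condition {cond!r}")

    @classmethod
    def for_experiment(cls, experiment: int, **overrides) -> "ExperimentConfig":
        if experiment not in _DEFAULTS:
            raise ValueError(f"experiment must be 1 or 2, got {experiment}")
        kw = dict(_DEFAULTS[experiment])
        kw.update(overrides)
        return cls(experiment=experiment, **kw)

    @property
    def trials_per_participant(self) -> int:
        return self.blocks * self.trials_per_block


def morph_to_drift(morph, v_max: float):
    """Antisymmetric linear morph-to-drift map: v = v_max * (2*morph/100 - 1).

    Positive drift pushes toward the self (upper) boundary; magnitude grows
    with distance from the ambiguous midpoint of the continuum.
    """
    return v_max * (2.0 * np.asarray(morph, dtype=float) / 100.0 - 1.0)


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    return float(np.clip(mean, lo, hi))


def generate_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full experiment; returns (trial table, ground-truth table).

    Fully reproducible from ``config.seed``.  Condition assignment, object
    ownership (pencil vs pen = self) and key mapping are counterbalanced by
    interleaving across the participant sequence.  Morph levels are balanced
    within every block.  Contaminant trials are injected last.
    """
    rng = np.random.default_rng(config.seed)
    n_cond = len(config.conditions)
    grid = np.asarray(config.morph_grid, dtype=float)
    reps = config.trials_per_block // len(grid)

    trial_rows = []
    truth_rows = []
    n_total = config.n_per_cell * n_cond
    for i in range(n_total):
        pid = f"p{i + 1:03d}"
        cond = config.conditions[i % n_cond]
        self_object = ("pencil", "pen")[(i // n_cond) % 2]
        key_map = ("CM", "MC")[(i // (2 * n_cond)) % 2]

        a = _trunc_normal(rng, config.a_mean, config.rel_sd * config.a_mean, 0.3, 5.0)
        t0 = _trunc_normal(rng, config.t0_mean, config.rel_sd * config.t0_mean, 0.12, 1.0)
        zm = config.z_mean[cond]
        z_sd = config.z_sd if config.z_sd is not None else config.rel_sd * zm
        z = _trunc_normal(rng, zm, z_sd, 0.05, 0.95)
        vm = config.v_max_mean[cond]
        v_max = _trunc_normal(rng, vm, config.rel_sd * vm, 0.05, 10.0)
        truth_rows.append(
            dict(participant=pid, condition=cond, a=a, t0=t0, z=z, v_max=v_max)
        )

        # balanced morph sequence per block
        morph_seq = np.concatenate(
            [rng.permutation(np.repeat(grid, reps)) for _ in range(config.blocks)]
        )
        # one diffusion pool per morph level, dealt out in sequence order
        pools = {}
        for m in grid:
            n_m = int((morph_seq == m).sum())
            params = DDMParams(v=float(morph_to_drift(m, v_max)), a=a, z=z, t0=t0)
            ch, rt = simulate_trials(params, n_m, rng=rng)
            pools[m] = [ch, rt, 0]
        for t_idx, m in enumerate(morph_seq):
            ch, rt, k = pools[m]
            pools[m][2] += 1
            trial_rows.append(
                dict(
                    participant=pid,
                    condition=cond,
                    block=t_idx // config.trials_per_block + 1,
                    morph_pct_self=float(m),
                    response="self" if ch[k] == 1 else "friend",
                    rt_s=float(rt[k]),
                    self_object=self_object,
                    key_map=key_map,
                )
            )

    trials = pd.DataFrame(trial_rows)
    truth = pd.DataFrame(truth_rows)
    trials = inject_contaminants(
        trials, config.fast_frac, config.outlier_frac,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return trials, truth


def inject_contaminants(
    trials: pd.DataFrame, fast_frac: float, outlier_frac: float, seed: int
) -> pd.DataFrame:
    """Replace random trials with fast guesses and slow uniform outliers.

    Fast guesses get rt ~ U(0.05, 0.2) s (targets of the 200 ms exclusion
    rule); outliers get rt ~ U(0.2, 5.0) s; both get coin-flip responses.  The
    fractions must lie in [0, 0.1].  A ``contaminant`` column records the type.
    """
    for frac in (fast_frac, outlier_frac):
        if not (0.0 <= frac <= 0.1):
            raise ValueError(f"contaminant fractions must be in [0, 0.1], got {frac}")
    rng = np.random.default_rng(seed)
    n = len(trials)
    out = trials.copy()
    if "contaminant" not in out.columns:
        out["contaminant"] = "none"
    u = rng.random(n)
    fast = u < fast_frac
    slow = (u >= fast_frac) & (u < fast_frac + outlier_frac)
    for mask, label, lo, hi in ((fast, "fast", 0.05, 0.2), (slow, "outlier", 0.2, 5.0)):
        k = int(mask.sum())
        if k:
            out.loc[mask, "rt_s"] = rng.uniform(lo, hi, k)
            out.loc[mask, "response"] = np.where(rng.random(k) < 0.5, "self", "friend")
            out.loc[mask, "contaminant"] = label
    return out


def recovery_config(
    n_subjects: int = 12,
    z: float = 0.52,
    z_sd: float = 0.03,
    v_max: float = 1.74,
    condition: str = "ownership",
    seed: int = 0,
    **overrides,
) -> ExperimentConfig:
    """Single-condition cohort for parameter-recovery harnesses.

    Generates ``n_subjects`` participants of one condition at the given group
    starting point.  The between-subject z SD defaults to 0.03 — small enough
    that the cohort mean is a stable estimand at recovery-harness sample
    sizes — rather than the full experiment emulator's 10%-of-mean default.
    Contaminants are off unless overridden, so the harness tests the sampler,
    not the exclusion rules.
    """
    kw = dict(
        conditions=(condition,),
        z_mean={condition: z},
        v_max_mean={condition: v_max},
        n_per_cell=n_subjects,
        z_sd=z_sd,
        fast_frac=0.0,
        outlier_frac=0.0,
        seed=seed,
    )
    kw.update(overrides)
    return ExperimentConfig(experiment=1, **kw)


def logistic_cohort(
    n_participants: int,
    pse_mean: float,
    pse_sd: float,
    slope: float = 0.15,
    trials_per_level: int = 70,
    grid=MORPH_GRID,
    condition: str = "ownership",
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bernoulli responses from per-participant logistic curves.

    Participant-level true PSEs are drawn N(pse_mean, pse_sd); each trial's
    self response is Bernoulli(1/(1+exp(-slope*(morph - PSE)))).  Used to test
    whether the psychometric estimator recovers group means generated at
    reported condition summaries.  RTs are a constant placeholder (the curves
    use only choices).  Returns (trial table, true PSE vector).
    """
    rng = np.random.default_rng(seed)
    true_pse = rng.normal(pse_mean, pse_sd, n_participants)
    grid = np.asarray(grid, dtype=float)
    rows = []
    for i, alpha in enumerate(true_pse):
        pid = f"q{i + 1:03d}"
        morph = np.repeat(grid, trials_per_level)
        p = 1.0 / (1.0 + np.exp(-slope * (morph - alpha)))
        resp = rng.random(morph.size) < p
        rows.append(
            pd.DataFrame(
                dict(
                    participant=pid,
                    condition=condition,
                    morph_pct_self=morph,
                    response=np.where(resp, "self", "friend"),
                    rt_s=0.5,
                )
            )
        )
    return pd.concat(rows, ignore_index=True), true_pse
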
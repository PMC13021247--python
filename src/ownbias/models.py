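"""Parameter-mapping model variants and the trial -> parameter-cell design.

Three nested hierarchical diffusion models are compared:

* **M1** — drift rate varies with condition x morph level; starting point fixed
  at z = 0.5 (no response bias); one boundary separation.
* **M2** — as M1, but the starting point is free and varies with the
  between-subject condition (response-selection bias).
* **M3** — as M2, with boundary separation also varying by condition
  (response caution).

Models are response coded: the upper boundary is the self-related response,
the lower boundary the friend-related response, for every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RESPONSE_UPPER

__all__ = ["ModelSpec", "Design", "build_design"]

VARIANTS = ("M1", "M2", "M3")


@dataclass(frozen=True)
class ModelSpec:
    """Which diffusion parameters vary with which experimental factors."""

    variant: str
    z_by_condition: bool
    a_by_condition: bool
    z_fixed: float | None = None  # 0.5 for M1, None when z is free

    @classmethod
    def from_variant(cls, variant: str) -> "ModelSpec":
        if variant not in VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
        if variant == "M1":
            return cls("M1", z_by_condition=False, a_by_condition=False, z_fixed=0.5)
        if variant == "M2":
            return cls("M2", z_by_condition=True, a_by_condition=False)
        return cls("M3", z_by_condition=True, a_by_condition=True)

    @property
    def z_free(self) -> bool:
        return self.z_fixed is None


@dataclass
class Design:
    """Packed trial data plus the cell -> parameter-index maps for one model.

    Trials are sorted by (subject, morph cell); ``cell_start``/``cell_count``
    give each subject x morph slice into the flat ``rt``/``upper`` arrays.
    """

    spec: ModelSpec
    subjects: list
    conditions: list
    morph_levels: np.ndarray
    cond_of_subj: np.ndarray  # (n_subj,) int
    zcell_of_subj: np.ndarray  # (n_subj,) int; all zeros when z collapsed/fixed
    acell_of_subj: np.ndarray
    n_zcells: int
    n_acells: int
    rt: np.ndarray
    upper: np.ndarray  # int 1 = self/upper
    cell_start: np.ndarray  # (n_subj, n_morph)
    cell_count: np.ndarray
    t_max: float  # contaminant horizon: 99th pct of observed RTs
    p_out: float = 0.05

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_morph(self) -> int:
        return len(self.morph_levels)

    @property
    def n_vcells(self) -> int:
        return len(self.conditions) * self.n_morph

    def vcell_label(self, cond_idx: int, morph_idx: int) -> str:
        return f"v[{self.conditions[cond_idx]},{self.morph_levels[morph_idx]:g}]"


def build_design(trials: pd.DataFrame, spec: ModelSpec, p_out: float = 0.05) -> Design:
    """Map every trial to its (v, z, a, t0) parameter cells and pack arrays.

    Drift cells are condition x morph level; z cells follow the spec (per
    condition for M2/M3, collapsing to one when the data hold a single
    condition; absent for M1); a cells likewise; t0 is one per subject.
    """
    required = {"participant", "condition", "morph_pct_self", "response", "rt_s"}
    missing = required - set(trials.columns)
    if missing:
        raise KeyError(f"trial table missing columns {sorted(missing)}")

    subjects = list(pd.unique(trials["participant"]))
    conditions = sorted(pd.unique(trials["condition"].astype(str)))
    morph_levels = np.sort(pd.unique(trials["morph_pct_self"].astype(float)))
    cond_idx = {c: i for i, c in enumerate(conditions)}
    morph_idx = {m: i for i, m in enumerate(morph_levels)}
    subj_idx = {s: i for i, s in enumerate(subjects)}

    cond_of_subj = np.full(len(subjects), -1, dtype=np.int64)
    for s, grp in trials.groupby("participant", sort=False):
        cs = set(grp["condition"].astype(str))
        if len(cs) != 1:
            raise ValueError(f"participant {s!r} appears in multiple conditions {cs}")
        cond_of_subj[subj_idx[s]] = cond_idx[cs.pop()]

    n_morph = len(morph_levels)
    si = trials["participant"].map(subj_idx).to_numpy()
    mi = trials["morph_pct_self"].astype(float).map(morph_idx).to_numpy()
    order = np.lexsort((mi, si))
    rt = trials["rt_s"].to_numpy(dtype=float)[order]
    upper = np.asarray(
        [1 if r in RESPONSE_UPPER else 0 for r in trials["response"]], dtype=np.int64
    )[order]
    si, mi = si[order], mi[order]

    n_subj = len(subjects)
    cell_start = np.zeros((n_subj, n_morph), dtype=np.int64)
    cell_count = np.zeros((n_subj, n_morph), dtype=np.int64)
    flat = si * n_morph + mi
    starts = np.searchsorted(flat, np.arange(n_subj * n_morph))
    counts = np.diff(np.append(starts, len(flat)))
    cell_start[:] = starts.reshape(n_subj, n_morph)
    cell_count[:] = counts.reshape(n_subj, n_morph)

    if spec.z_free and spec.z_by_condition:
        zcell_of_subj = cond_of_subj.copy()
        n_zcells = len(conditions)
    else:
        zcell_of_subj = np.zeros(n_subj, dtype=np.int64)
        n_zcells = 0 if not spec.z_free else 1
    if spec.a_by_condition:
        acell_of_subj = cond_of_subj.copy()
        n_acells = len(conditions)
    else:
        acell_of_subj = np.zeros(n_subj, dtype=np.int64)
        n_acells = 1

    return Design(
        spec=spec,
        subjects=subjects,
        conditions=conditions,
        morph_levels=morph_levels,
        cond_of_subj=cond_of_subj,
        zcell_of_subj=zcell_of_subj,
        acell_of_subj=acell_of_subj,
        n_zcells=n_zcells,
        n_acells=n_acells,
        rt=rt,
        upper=upper,
        cell_start=cell_start,
        cell_count=cell_count,
        t_max=float(np.quantile(rt, 0.99)),
        p_out=p_out,
    )
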
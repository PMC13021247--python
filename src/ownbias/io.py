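"""Readers and writers for the pipeline's delimited-text artifacts.

The canonical trial table has one row per trial with columns

    participant, condition, morph_pct_self, response, rt_s

``response`` is coded ``self``/``friend`` (or 1/0, mapped at ingest with
self = 1 = upper boundary); ``morph_pct_self`` is the % of self-owned-object
information in the image on the 8-level grid; ``rt_s`` is in seconds.  Files
whose morph axis is expressed as %pen carry a ``self_object`` counterbalance
column (``pencil``/``pen``) and are converted to % self at ingest
(morph_pct_self = 100 - %pen for participants whose self-owned object is the
pencil).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_trials", "write_table", "MORPH_GRID", "RESPONSE_UPPER", "TrialValidationError"]

#: morph continuum grid, % self-owned-object information
MORPH_GRID = (0.0, 20.0, 35.0, 45.0, 55.0, 65.0, 80.0, 100.0)

#: response codes mapped to the upper (self) boundary
RESPONSE_UPPER = frozenset({"self", 1, "1", 1.0, True})

REQUIRED_COLUMNS = ("participant", "condition", "morph_pct_self", "response", "rt_s")


class TrialValidationError(ValueError):
    """Raised when a trial table contains invalid rows; carries row errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid trial rows:\n" + "\n".join(errors[:20]))


def _normalize_response(r):
    if isinstance(r, str):
        rl = r.strip().lower()
        if rl in ("self", "1"):
            return "self"
        if rl in ("friend", "0"):
            return "friend"
        return None
    if r in (1, 1.0, True):
        return "self"
    if r in (0, 0.0, False):
        return "friend"
    return None


def read_trials(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a trial table; returns the canonical frame.

    Performs the %pen -> %self conversion when the file carries a
    ``morph_pct_pen`` axis plus a ``self_object`` counterbalance column.
    Invalid rows (unknown response codes, non-positive RTs, off-grid morphs)
    are collected and reported together in a :class:`TrialValidationError`.
    """
    df = pd.read_csv(path, sep=sep)
    if "morph_pct_pen" in df.columns and "morph_pct_self" not in df.columns:
        if "self_object" not in df.columns:
            raise TrialValidationError(
                ["morph_pct_pen axis requires a self_object counterbalance column"]
            )
        pen = df["morph_pct_pen"].astype(float)
        is_pencil_self = df["self_object"].astype(str).str.lower().eq("pencil")
        df["morph_pct_self"] = np.where(is_pencil_self, 100.0 - pen, pen)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing columns: {missing}"])

    errors = []
    resp = df["response"].map(_normalize_response)
    for i in df.index[resp.isna()]:
        errors.append(f"row {i}: unknown response code {df.loc[i, 'response']!r}")
    rt = pd.to_numeric(df["rt_s"], errors="coerce")
    for i in df.index[~(rt > 0)]:
        errors.append(f"row {i}: rt_s must be > 0, got {df.loc[i, 'rt_s']!r}")
    morph = pd.to_numeric(df["morph_pct_self"], errors="coerce")
    on_grid = morph.isin(MORPH_GRID)
    for i in df.index[~on_grid]:
        errors.append(f"row {i}: morph_pct_self {df.loc[i, 'morph_pct_self']!r} not on grid")
    if errors:
        raise TrialValidationError(errors)

    out = df.copy()
    out["response"] = resp
    out["rt_s"] = rt
    out["morph_pct_self"] = morph
    return out


def write_table(df: pd.DataFrame, path, sep: str = ",") -> Path:
    """Write a table as delimited text, creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    return path
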
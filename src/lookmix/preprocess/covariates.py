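"""Participant-level covariates: vocabulary counts and processing speed."""

from __future__ import annotations

import numpy as np
import pandas as pd


def standardize_covariate(values) -> np.ndarray:
    """Center/scale to sample mean 0, SD 1 (ddof=1); NaNs propagate."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("need at least two non-missing values")
    sd = np.std(x[ok], ddof=1)
    if sd == 0:
        raise ValueError("zero variance covariate")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - np.mean(x[ok])) / sd
    return out


def build_covariates(
    table: pd.DataFrame,
    rt_col: str = "rt_ms",
    verbs_col: str = "n_verbs",
    vocab_col: str = "total_vocab",
) -> pd.DataFrame:
    """ParticipantCovariates table with standardized RT and verb columns.

    ``table`` must have one row per participant.  Standardization is over the
    participants present (post-exclusion), so downstream model coefficients
    are on the per-SD scale.
    """
    if table["participant_id"].duplicated().any():
        raise ValueError("one row per participant expected")
    out = table[["participant_id"]].copy()
    out["rt_mean_ms"] = table[rt_col].to_numpy(dtype=float)
    out["n_verbs"] = table[verbs_col].to_numpy()
    if vocab_col in table:
        out["total_vocab"] = table[vocab_col].to_numpy()
    out["rt_std"] = standardize_covariate(out["rt_mean_ms"])
    out["verbs_std"] = standardize_covariate(out["n_verbs"])
    if vocab_col in table:
        # proportion of verbs known is exposed as an alternative predictor
        out["prop_verbs"] = out["n_verbs"] / out["total_vocab"].replace(0, np.nan)
    return out
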
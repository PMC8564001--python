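"""Fixed-effect design matrices and grouping indices for the chance-test models."""

from __future__ import annotations

import numpy as np
import pandas as pd

N_ITEMS = 16  # 8 sequences x 2 trials


def _sum_code(levels: pd.Series, name: str) -> np.ndarray:
    """Two-level sum coding: level 1 -> +0.5, level 2 -> -0.5."""
    vals = levels.to_numpy()
    if not np.isin(vals, (1, 2)).all():
        raise ValueError(f"{name} must take levels 1/2")
    return np.where(vals == 1, 0.5, -0.5)


def _bin_code(levels: pd.Series) -> np.ndarray:
    """Deviation coding for the four 2000-ms bins (bin 4 is the reference:
    its row is -1 in all three columns, so effects sum to zero)."""
    vals = levels.to_numpy()
    if not np.isin(vals, (1, 2, 3, 4)).all():
        raise ValueError("bin must take levels 1..4")
    cols = np.zeros((len(vals), 3))
    for k in (1, 2, 3):
        cols[vals == k, k - 1] = 1.0
    cols[vals == 4, :] = -1.0
    return cols


def item_index(observations: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Item (unique trial type) index derived from (sequence_id, trial)."""
    seq = observations["sequence_id"].to_numpy()
    trial = observations["trial"].to_numpy()
    if not ((seq >= 1) & (seq <= 8)).all():
        raise ValueError("sequence_id must be 1..8")
    idx = (seq - 1) * 2 + (trial - 1)
    return idx.astype(int), N_ITEMS


def build_design_matrix(observations: pd.DataFrame, spec) -> tuple[pd.DataFrame, dict]:
    """Model matrix plus grouping indices for a ChanceTestSpec.

    Returns ``(X, groups)`` where X always contains an ``Intercept`` column
    and groups maps ``participant``/``item`` to integer index arrays.
    """
    n = len(observations)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    if spec.salience:
        cols["salience_logit"] = observations["salience_logit"].to_numpy(dtype=float)
    main: dict[str, np.ndarray] = {}
    if spec.window_factor:
        main["window"] = _sum_code(observations["window"], "window")
    if spec.trial_factor:
        main["trial"] = _sum_code(observations["trial"], "trial")
    bin_cols = None
    if spec.bin_factor:
        bin_cols = _bin_code(observations["bin"])
    cols.update(main)
    if bin_cols is not None:
        for k in range(3):
            cols[f"bin{k + 1}"] = bin_cols[:, k]
    if spec.interactions:
        if "window" in main and "trial" in main:
            cols["window:trial"] = main["window"] * main["trial"]
        if bin_cols is not None:
            for fac in ("window", "trial"):
                if fac in main:
                    for k in range(3):
                        cols[f"{fac}:bin{k + 1}"] = main[fac] * bin_cols[:, k]
            if "window" in main and "trial" in main:
                for k in range(3):
                    cols[f"window:trial:bin{k + 1}"] = (
                        main["window"] * main["trial"] * bin_cols[:, k]
                    )
    X = pd.DataFrame(cols)

    pids = observations["participant_id"].to_numpy()
    uniq, part_idx = np.unique(pids, return_inverse=True)
    it_idx, _ = item_index(observations)
    groups = {
        "participant": {"index": part_idx, "n_levels": len(uniq), "ids": uniq},
        "item": {"index": it_idx, "n_levels": N_ITEMS},
    }
    return X, groups
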
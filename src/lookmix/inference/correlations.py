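"""Pairwise Pearson correlations with t-based p-values."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pairwise_correlations(wide: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every column pair, pairwise-complete.

    Raises on columns with zero variance (r is undefined) or fewer than three
    complete pairs.
    """
    cols = list(wide.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            sub = wide[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                raise ValueError(f"zero-variance column in pair ({a}, {b})")
            res = stats.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p
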
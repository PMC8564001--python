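"""Action-salience control covariate.

Each action's intrinsic pull on gaze is estimated from the windows in which
it was the distracter video: the pooled proportion of (valid) looks it
attracted there, logit-transformed.  The logit is then attached to every
observation whose *target* is that action, so the model intercept reads as
looks-to-target over and above the action's baseline attractiveness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit

from lookmix.simulate.design import ACTIONS


def _with_actions(windows: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    key = design[["sequence_id", "trial", "target_action", "distracter_action"]]
    merged = windows.merge(key, on=["sequence_id", "trial"], how="left", validate="m:1")
    if merged["target_action"].isna().any():
        bad = merged[merged["target_action"].isna()]
        raise ValueError(
            "windows with no design row: "
            f"{bad[['sequence_id', 'trial']].drop_duplicates().to_dict('records')}"
        )
    return merged


def action_salience(
    windows: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """SalienceTable: per action, pooled distracter-attraction proportion.

    ``windows`` must carry prop_target, n_valid and sequence_id so each row
    can be joined to its counterbalancing design row.
    """
    merged = _with_actions(windows, design)
    rows = []
    for action in ACTIONS:
        sub = merged[merged["distracter_action"] == action]
        n_valid = sub["n_valid"].sum()
        if len(sub) == 0 or n_valid == 0:
            raise ValueError(f"action {action!r} never observed as distracter")
        looks_dist = ((1.0 - sub["prop_target"]) * sub["n_valid"]).sum()
        p = looks_dist / n_valid
        p = min(max(p, 1e-12), 1 - 1e-12)
        rows.append(
            {
                "action": action,
                "prop_as_distracter": p,
                "salience_logit": float(logit(p)),
            }
        )
    return pd.DataFrame(rows)


def attach_salience(
    windows: pd.DataFrame, design: pd.DataFrame, salience: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Windows with a ``salience_logit`` column for each row's target action."""
    if salience is None:
        salience = action_salience(windows, design)
    merged = _with_actions(windows, design)
    out = merged.merge(
        salience[["action", "salience_logit"]].rename(
            columns={"action": "target_action"}
        ),
        on="target_action",
        how="left",
    )
    return out
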
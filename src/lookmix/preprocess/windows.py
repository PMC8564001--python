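"""Window/bin proportions, the exclusion cascade, and the boundary transform."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lookmix.simulate.gaze import AOI_DISTRACTER, AOI_MISSING, AOI_TARGET

MISSING_THRESHOLD = 0.66
MAX_MISSING_WINDOWS = 2
EXPECTED_WINDOWS = 4


@dataclass(frozen=True)
class WindowSummary:
    """Per (participant, trial, window) proportion of looks to target.

    ``prop_target`` uses target/(target+distracter): away/missing samples do
    not enter the denominator. ``frac_missing`` is relative to the full
    sample count of the window.
    """

    participant_id: int
    trial: int
    window: int
    prop_target: float
    frac_missing: float
    n_valid: int
    excluded: bool
    sequence_id: int = 0


def _counts(aoi: pd.Series) -> tuple[int, int, int]:
    c = aoi.value_counts()
    return (
        int(c.get(AOI_TARGET, 0)),
        int(c.get(AOI_DISTRACTER, 0)),
        int(c.get(AOI_MISSING, 0)),
    )


def window_proportion(
    stream: pd.DataFrame,
    trial: int,
    window: int,
    missing_threshold: float = MISSING_THRESHOLD,
) -> WindowSummary:
    """Summarize one window of one participant's stream."""
    sub = stream[(stream["trial"] == trial) & (stream["window"] == window)]
    pid = int(stream["participant_id"].iloc[0]) if len(stream) else -1
    seq = int(sub["sequence_id"].iloc[0]) if len(sub) else 0
    n_t, n_d, n_m = _counts(sub["aoi"]) if len(sub) else (0, 0, 0)
    total = n_t + n_d + n_m
    n_valid = n_t + n_d
    if total == 0:
        return WindowSummary(pid, trial, window, float("nan"), 1.0, 0, True, seq)
    frac_missing = n_m / total
    prop = n_t / n_valid if n_valid else float("nan")
    excluded = n_valid == 0 or frac_missing >= missing_threshold
    return WindowSummary(pid, trial, window, prop, frac_missing, n_valid, excluded, seq)


def summarize_windows(
    stream: pd.DataFrame, missing_threshold: float = MISSING_THRESHOLD
) -> pd.DataFrame:
    """Window summaries for every (participant, trial, window) in a gaze table."""
    rows = []
    for (pid, seq, trial, window), sub in stream.groupby(
        ["participant_id", "sequence_id", "trial", "window"], sort=True
    ):
        n_t, n_d, n_m = _counts(sub["aoi"])
        total = n_t + n_d + n_m
        n_valid = n_t + n_d
        frac_missing = n_m / total if total else 1.0
        prop = n_t / n_valid if n_valid else np.nan
        rows.append(
            {
                "participant_id": pid,
                "sequence_id": seq,
                "trial": trial,
                "window": window,
                "prop_target": prop,
                "frac_missing": frac_missing,
                "n_valid": n_valid,
                "excluded": n_valid == 0 or frac_missing >= missing_threshold,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    windows: pd.DataFrame,
    missing_threshold: float = MISSING_THRESHOLD,
    expected_windows: int = EXPECTED_WINDOWS,
    max_missing_windows: int = MAX_MISSING_WINDOWS,
) -> tuple[pd.DataFrame, list, list[str]]:
    """Apply the window/participant exclusion cascade.

    A window is dropped when its missing fraction is at or above
    ``missing_threshold``; a participant is dropped when the number of
    dropped-or-absent windows (out of ``expected_windows``) reaches
    ``max_missing_windows``.  Returns (included windows, excluded participant
    ids, audit log).  The cascade is idempotent.
    """
    keys = windows[["participant_id", "trial", "window"]]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].to_dict("records")
        raise ValueError(f"duplicate (participant, trial, window) keys: {dupes}")

    audit: list[str] = []
    win = windows.copy()
    win["excluded"] = (win["frac_missing"] >= missing_threshold) | (win["n_valid"] == 0)
    for rec in win[win["excluded"]].itertuples():
        audit.append(
            f"window participant={rec.participant_id} trial={rec.trial} "
            f"window={rec.window}: EXCLUDED frac_missing={rec.frac_missing:.3f}"
        )

    excluded_participants = []
    for pid, sub in win.groupby("participant_id", sort=True):
        n_bad = int(sub["excluded"].sum()) + (expected_windows - len(sub))
        if n_bad >= max_missing_windows:
            excluded_participants.append(pid)
            audit.append(
                f"participant {pid}: EXCLUDED ({n_bad} of {expected_windows} "
                "windows missing or dropped)"
            )
        else:
            audit.append(
                f"participant {pid}: retained ({n_bad} of {expected_windows} "
                "windows missing or dropped)"
            )
    included = win[
        ~win["excluded"] & ~win["participant_id"].isin(excluded_participants)
    ].reset_index(drop=True)
    return included, excluded_participants, audit


def sv_transform(y, n):
    """Shrink proportions off the boundary: (y*(n-1) + 0.5) / n.

    ``n`` is the number of proportions being transformed.  Strictly inside
    (0, 1) for any y in [0, 1] and n >= 1, and monotone in y.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    out = (y * (n - 1.0) + 0.5) / n
    return out if out.ndim else float(out)


def bin_proportions(
    stream: pd.DataFrame,
    bin_ms: float = 2000.0,
    window_ms: float = 8000.0,
    sample_rate_hz: float = 60.0,
) -> pd.DataFrame:
    """Per 2000-ms-bin proportions, boundary-transformed across the dataset.

    The window length must divide evenly into bins.  Bins with zero valid
    samples are flagged (``excluded``) and receive no transformed value; the
    transform's ``n`` is the number of non-flagged bins in the dataset.
    """
    if abs(window_ms / bin_ms - round(window_ms / bin_ms)) > 1e-9:
        raise ValueError("window length must be divisible by bin length")
    df = stream.copy()
    df["bin"] = (df["time_ms"] // bin_ms).astype(int) + 1
    rows = []
    for (pid, seq, trial, window, b), sub in df.groupby(
        ["participant_id", "sequence_id", "trial", "window", "bin"], sort=True
    ):
        n_t, n_d, n_m = _counts(sub["aoi"])
        n_valid = n_t + n_d
        total = n_t + n_d + n_m
        rows.append(
            {
                "participant_id": pid,
                "sequence_id": seq,
                "trial": trial,
                "window": window,
                "bin": b,
                "prop_target": n_t / n_valid if n_valid else np.nan,
                "frac_missing": n_m / total if total else 1.0,
                "n_valid": n_valid,
                "excluded": n_valid == 0,
            }
        )
    bins = pd.DataFrame(rows)
    ok = ~bins["excluded"]
    n = int(ok.sum())
    bins["prop_target_transformed"] = np.nan
    if n >= 1:
        bins.loc[ok, "prop_target_transformed"] = sv_transform(
            bins.loc[ok, "prop_target"].to_numpy(), n
        )
    return bins
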
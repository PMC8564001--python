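"""Reaction-time extraction for the looking-while-listening task.

A trial contributes an RT only when (a) the child was on-screen for at least
half of the 3000-ms window after target-word onset, (b) gaze was on the
distracter image at onset, and (c) the first >=100-ms fixation on the target
image started between 300 and 1800 ms after onset.  The RT is the start time
of that fixation, relative to onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lookmix.simulate.gaze import AOI_DISTRACTER, AOI_TARGET

SCREEN_WINDOW_MS = 3000.0
MIN_SCREEN_FRACTION = 0.5
RT_LOW_MS = 300.0
RT_HIGH_MS = 1800.0
MIN_FIXATION_MS = 100.0


@dataclass(frozen=True)
class RtRecord:
    participant_id: int
    trial: int
    eligible: bool
    rt_ms: float | None
    exclusion_reason: str  # low_screen_time | target_initial | no_shift_in_window | none

    def __post_init__(self) -> None:
        if self.eligible != (self.rt_ms is not None):
            raise ValueError("rt_ms must be present iff eligible")
        if self.rt_ms is not None and not (RT_LOW_MS <= self.rt_ms <= RT_HIGH_MS):
            raise ValueError("eligible RT outside the 300-1800 ms window")


def _target_runs(aoi: np.ndarray, times: np.ndarray, dt_ms: float):
    """(start_time, duration_ms) of each maximal run of target samples."""
    on = aoi == AOI_TARGET
    runs = []
    i = 0
    n = len(on)
    while i < n:
        if on[i]:
            j = i
            while j < n and on[j]:
                j += 1
            runs.append((float(times[i]), (j - i) * dt_ms))
            i = j
        else:
            i += 1
    return runs


def lwl_trial_rt(
    stream: pd.DataFrame,
    target_onset_ms: float,
    sample_rate_hz: float = 60.0,
) -> RtRecord:
    """Extract the RT record for a single trial's gaze stream."""
    pid = int(stream["participant_id"].iloc[0])
    trial = int(stream["trial"].iloc[0])
    times = stream["time_ms"].to_numpy()
    aoi = stream["aoi"].to_numpy()
    dt = 1000.0 / sample_rate_hz
    if target_onset_ms < times[0] or target_onset_ms > times[-1]:
        raise ValueError("target onset outside the trial stream")

    post = (times >= target_onset_ms) & (times < target_onset_ms + SCREEN_WINDOW_MS)
    post_aoi = aoi[post]
    on_screen = np.isin(post_aoi, (AOI_TARGET, AOI_DISTRACTER))
    if len(post_aoi) == 0 or on_screen.mean() < MIN_SCREEN_FRACTION:
        return RtRecord(pid, trial, False, None, "low_screen_time")

    onset_idx = int(np.searchsorted(times, target_onset_ms))
    if aoi[onset_idx] != AOI_DISTRACTER:
        return RtRecord(pid, trial, False, None, "target_initial")

    after = times > target_onset_ms
    runs = _target_runs(aoi[after], times[after], dt)
    for start, dur in runs:
        if dur + 1e-9 >= MIN_FIXATION_MS:
            rt = start - target_onset_ms
            if RT_LOW_MS <= rt <= RT_HIGH_MS:
                return RtRecord(pid, trial, True, float(rt), "none")
            return RtRecord(pid, trial, False, None, "no_shift_in_window")
    return RtRecord(pid, trial, False, None, "no_shift_in_window")


def session_rts(
    stream: pd.DataFrame, target_onset_ms: float, sample_rate_hz: float = 60.0
) -> list[RtRecord]:
    return [
        lwl_trial_rt(sub, target_onset_ms, sample_rate_hz)
        for _, sub in stream.groupby("trial", sort=True)
    ]


def participant_rt(records: list[RtRecord]) -> float:
    """Mean RT across eligible trials; NaN when no trial is eligible."""
    rts = [r.rt_ms for r in records if r.eligible]
    if not rts:
        return float("nan")
    return float(np.mean(rts))
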
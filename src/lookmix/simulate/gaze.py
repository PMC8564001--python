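"""Raw 60-Hz gaze stream simulation.

Looks are arranged in contiguous fixation runs by a two-state dwell process
(geometric run lengths) whose stationary target share equals the
participant's latent mean ``mu_i``; data loss is inserted as missing runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lookmix.simulate.config import GazeSimConfig, ParticipantTruth
from lookmix.simulate.design import DesignRow

AOI_TARGET = "target"
AOI_DISTRACTER = "distracter"
AOI_MISSING = "missing"

GAZE_COLUMNS = [
    "participant_id",
    "task",
    "sequence_id",
    "trial",
    "window",
    "time_ms",
    "aoi",
]


def _dwell_sequence(
    rng: np.random.Generator, n: int, share: float, mean_dwell_samples: float
) -> np.ndarray:
    """Binary look sequence (1=target) from a two-state geometric dwell chain.

    State dwell means are split proportionally to the stationary share so that
    one full target+distracter cycle averages ``2 * mean_dwell_samples`` and
    the long-run target share is exactly ``share``.
    """
    if share >= 1.0 - 1e-9:
        return np.ones(n, dtype=bool)
    if share <= 1e-9:
        return np.zeros(n, dtype=bool)
    cycle = 2.0 * mean_dwell_samples
    d_t = max(share * cycle, 1.0)
    d_d = max((1.0 - share) * cycle, 1.0)
    state = rng.random() < share  # start at stationarity
    out = np.empty(n, dtype=bool)
    i = 0
    while i < n:
        mean = d_t if state else d_d
        run = rng.geometric(min(1.0, 1.0 / mean))
        out[i : i + run] = state
        i += run
        state = not state
    return out


def _missing_mask(rng: np.random.Generator, n: int, sim: GazeSimConfig) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if sim.blackout_prob > 0 and rng.random() < sim.blackout_prob:
        return np.ones(n, dtype=bool)
    if sim.missing_run_prob <= 0:
        return mask
    mean_run = max(sim.missing_mean_run_ms * sim.sample_rate_hz / 1000.0, 1.0)
    starts = np.flatnonzero(rng.random(n) < sim.missing_run_prob)
    for s in starts:
        run = rng.geometric(1.0 / mean_run)
        mask[s : s + run] = True
    return mask


def generate_gaze_stream(
    truth: ParticipantTruth,
    design: list[DesignRow] | DesignRow,
    sim: GazeSimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the full test-phase gaze stream for one participant.

    One row per 60-Hz sample, long format, with ``aoi`` in
    {target, distracter, missing}.  ``design`` is the participant's assigned
    counterbalancing rows (one per trial); a single row may be passed for a
    one-trial stream.
    """
    if rng is None:
        rng = np.random.default_rng(truth.participant_id)
    if isinstance(design, DesignRow):
        design = [design]
    n = sim.samples_per_window
    times = sim.sample_times_ms(n)
    mean_dwell_samples = sim.mean_dwell_ms * sim.sample_rate_hz / 1000.0

    frames = []
    for row in design:
        for window in range(1, sim.windows_per_trial + 1):
            on_target = _dwell_sequence(rng, n, truth.mu_i, mean_dwell_samples)
            aoi = np.where(on_target, AOI_TARGET, AOI_DISTRACTER).astype(object)
            aoi[_missing_mask(rng, n, sim)] = AOI_MISSING
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": truth.participant_id,
                        "task": "impl",
                        "sequence_id": row.sequence_id,
                        "trial": row.trial,
                        "window": window,
                        "time_ms": times,
                        "aoi": aoi,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[GAZE_COLUMNS]


def generate_lwl_session(
    truth: ParticipantTruth,
    sim: GazeSimConfig,
    planted_rts: list,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a looking-while-listening session with known reaction times.

    ``planted_rts`` holds one entry per trial: a number (ms after target-word
    onset; the trial is distracter-initial and the first >=100-ms target
    fixation starts exactly there, snapped to the sample grid), or one of the
    markers ``"target_initial"`` (gaze on target at onset) and ``"missing"``
    (over half the post-onset window lost) used to exercise the downstream
    eligibility filters.
    """
    if rng is None:
        rng = np.random.default_rng(truth.participant_id + 10_000)
    n = sim.samples_per_lwl_trial
    times = sim.sample_times_ms(n)
    dt = 1000.0 / sim.sample_rate_hz
    onset_idx = int(round(sim.lwl_target_onset_ms / dt))
    max_rt = sim.lwl_trial_ms - sim.lwl_target_onset_ms

    frames = []
    for trial, planted in enumerate(planted_rts, start=1):
        aoi = np.full(n, AOI_DISTRACTER, dtype=object)
        # pre-onset: look around casually, then settle per the plant
        pre = _dwell_sequence(rng, onset_idx, 0.5,
                              sim.mean_dwell_ms * sim.sample_rate_hz / 1000.0)
        aoi[:onset_idx] = np.where(pre, AOI_TARGET, AOI_DISTRACTER)
        if isinstance(planted, str):
            if planted == "target_initial":
                aoi[onset_idx:] = AOI_TARGET
            elif planted == "missing":
                post = slice(onset_idx, n)
                aoi[post] = AOI_DISTRACTER
                n_post = n - onset_idx
                lost = rng.choice(n_post, size=int(0.6 * n_post), replace=False)
                aoi[onset_idx + lost] = AOI_MISSING
            else:
                raise ValueError(f"unknown planted marker {planted!r}")
        else:
            rt = float(planted)
            if not 0.0 < rt < max_rt:
                raise ValueError(f"planted RT {rt} outside (0, {max_rt}) ms")
            shift_idx = onset_idx + int(round(rt / dt))
            aoi[onset_idx:shift_idx] = AOI_DISTRACTER
            # a fixation comfortably above the 100-ms criterion
            fix_len = max(int(round(500.0 / dt)), int(np.ceil(100.0 / dt)))
            aoi[shift_idx : min(shift_idx + fix_len, n)] = AOI_TARGET
            tail = shift_idx + fix_len
            if tail < n:
                post = _dwell_sequence(rng, n - tail, 0.7,
                                       sim.mean_dwell_ms * sim.sample_rate_hz / 1000.0)
                aoi[tail:] = np.where(post, AOI_TARGET, AOI_DISTRACTER)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": truth.participant_id,
                    "task": "lwl",
                    "sequence_id": 0,
                    "trial": trial,
                    "window": 1,
                    "time_ms": times,
                    "aoi": aoi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[GAZE_COLUMNS]
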
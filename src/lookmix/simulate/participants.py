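"""Participant-level ground truth and direct proportion simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from lookmix.simulate.config import (
    DISCRETE,
    GRADED,
    RT_BOUNDS_MS,
    VERB_BOUNDS,
    VOCAB_BOUNDS,
    GenerativeConfig,
    ParticipantTruth,
)

_EPS = 1e-9


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal; bounds are far enough out that
    acceptance is high for every configuration we generate."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_participants(
    config: GenerativeConfig, rng: np.random.Generator | None = None
) -> list[ParticipantTruth]:
    """Draw one ground-truth record per participant under the configured regime.

    Covariates are drawn first so that, under the discrete regime with
    ``beta_verbs != 0``, group membership can depend on the standardized verb
    count, and under either regime ``beta_rt`` can shift the relevant mean
    logit.  Standardization for the linear predictors uses the configured
    population mean/SD (not the realized sample moments) so each
    participant's truth is well defined in isolation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    cov = config.covariates

    rt = _truncated_normal(rng, cov.rt_mean_ms, cov.rt_sd_ms, *RT_BOUNDS_MS, size=n)
    verbs = np.rint(
        _truncated_normal(rng, cov.verbs_mean, cov.verbs_sd, *VERB_BOUNDS, size=n)
    ).astype(int)
    vocab = np.rint(
        _truncated_normal(rng, cov.vocab_mean, cov.vocab_sd, *VOCAB_BOUNDS, size=n)
    ).astype(int)
    vocab = np.maximum(vocab, verbs)

    rt_std = (rt - cov.rt_mean_ms) / cov.rt_sd_ms
    verbs_std = (verbs - cov.verbs_mean) / cov.verbs_sd

    truths: list[ParticipantTruth] = []
    if config.regime == GRADED:
        t = rng.normal(0.0, config.sigma, size=n) if config.sigma > 0 else np.zeros(n)
        eta = (
            config.B0
            + config.beta_rt * rt_std
            + config.beta_verbs * verbs_std
            + t
        )
        mu = np.clip(expit(eta), _EPS, 1 - _EPS)
        for i in range(n):
            truths.append(
                ParticipantTruth(
                    participant_id=i + 1,
                    regime=GRADED,
                    mu_i=float(mu[i]),
                    t_i=float(t[i]),
                    rt_ms=float(rt[i]),
                    n_verbs=int(verbs[i]),
                    total_vocab=int(vocab[i]),
                )
            )
    else:
        if config.beta_verbs != 0.0:
            # membership probability moves with the verb count
            from scipy.special import logit

            pi_i = expit(logit(np.clip(config.pi, 1e-12, 1 - 1e-12))
                         + config.beta_verbs * verbs_std)
        else:
            pi_i = np.full(n, config.pi)
        T = (rng.random(n) < pi_i).astype(int)
        eta2 = config.mu2_logit + config.beta_rt * rt_std
        mu = np.where(T == 1, expit(eta2), expit(config.mu1_logit))
        mu = np.clip(mu, _EPS, 1 - _EPS)
        for i in range(n):
            truths.append(
                ParticipantTruth(
                    participant_id=i + 1,
                    regime=DISCRETE,
                    mu_i=float(mu[i]),
                    T_i=int(T[i]),
                    rt_ms=float(rt[i]),
                    n_verbs=int(verbs[i]),
                    total_vocab=int(vocab[i]),
                )
            )
    return truths


def truths_frame(truths: list[ParticipantTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truths])


def simulate_proportions(
    truths: list[ParticipantTruth],
    config: GenerativeConfig,
    n_obs: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw ``n_obs`` beta-distributed looking proportions per participant.

    This is the distribution-level route (no gaze microstructure): the
    response is ``Beta(mu_i, phi)`` in mean-precision form, with the
    participant's component precision under the discrete regime.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows = []
    for t in truths:
        if config.regime == GRADED:
            phi = config.phi
        else:
            phi = config.phi2 if t.T_i == 1 else config.phi1
        a, b = t.mu_i * phi, (1.0 - t.mu_i) * phi
        y = np.clip(rng.beta(a, b, size=n_obs), 1e-12, 1 - 1e-12)
        for k in range(n_obs):
            rows.append(
                {"participant_id": t.participant_id, "obs": k + 1, "prop": float(y[k])}
            )
    return pd.DataFrame(rows)
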
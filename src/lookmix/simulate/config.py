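"""Configuration and ground-truth types for the synthetic-data generator."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

GRADED = "graded"
DISCRETE = "discrete"

#: Task-feasible covariate bounds: the vocabulary checklist has 678 items and
#: the reaction-time window closes at 1800 ms.
RT_BOUNDS_MS = (200.0, 1800.0)
VERB_BOUNDS = (0, 678)
VOCAB_BOUNDS = (0, 678)


@dataclass(frozen=True)
class CovariateScales:
    """Population location/scale used to draw participant covariates."""

    rt_mean_ms: float = 563.0
    rt_sd_ms: float = 111.7
    verbs_mean: float = 54.6
    verbs_sd: float = 30.2
    vocab_mean: float = 350.9
    vocab_sd: float = 151.8


@dataclass(frozen=True)
class GenerativeConfig:
    """Ground-truth regime for participant-level looking propensities.

    Under the ``graded`` regime each participant's mean looking proportion is
    ``inverse_logit(B0 + t_i)`` with ``t_i ~ Normal(0, sigma)``; observed
    proportions are ``Beta(mu_i, phi)`` in the mean-precision
    parameterization.  Under the ``discrete`` regime participants belong to
    one of two latent groups (``T_i ~ Bernoulli(pi_i)``) with component means
    ``inverse_logit(mu1_logit)`` / ``inverse_logit(mu2_logit)`` and
    precisions ``phi1`` / ``phi2``.  ``beta_verbs`` moves the membership
    logit with the standardized verb count; ``beta_rt`` moves the second
    component's mean logit with the standardized reaction time.
    """

    regime: str = GRADED
    n_participants: int = 92
    B0: float = 0.04
    sigma: float = 0.25
    phi: float = 22.7
    pi: float = 0.19
    mu1_logit: float = 0.01
    mu2_logit: float = 0.33
    phi1: float = 23.31
    phi2: float = 11.41
    beta_rt: float = 0.0
    beta_verbs: float = 0.0
    covariates: CovariateScales = field(default_factory=CovariateScales)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in (GRADED, DISCRETE):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for name in ("phi", "phi1", "phi2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"non-finite parameter {f.name}")

    def replace(self, **kw) -> "GenerativeConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GazeSimConfig:
    """Timing structure of the simulated eye-tracking session."""

    sample_rate_hz: float = 60.0
    impl_trials: int = 2
    windows_per_trial: int = 2
    window_ms: float = 8000.0
    lwl_trials: int = 24
    lwl_trial_ms: float = 7000.0
    lwl_target_onset_ms: float = 2500.0
    mean_dwell_ms: float = 500.0
    missing_run_prob: float = 0.004
    missing_mean_run_ms: float = 400.0
    blackout_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "sample_rate_hz",
            "window_ms",
            "lwl_trial_ms",
            "lwl_target_onset_ms",
            "mean_dwell_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.missing_run_prob <= 1:
            raise ValueError("missing_run_prob must be in [0, 1]")
        if not 0 <= self.blackout_prob <= 1:
            raise ValueError("blackout_prob must be in [0, 1]")

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_ms * self.sample_rate_hz / 1000.0))

    @property
    def samples_per_lwl_trial(self) -> int:
        return int(round(self.lwl_trial_ms * self.sample_rate_hz / 1000.0))

    def sample_times_ms(self, n: int) -> np.ndarray:
        """Integer timestamps (ms) of the first ``n`` samples, 0-based."""
        return np.round(np.arange(n) * 1000.0 / self.sample_rate_hz).astype(int)

    def replace(self, **kw) -> "GazeSimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ParticipantTruth:
    """Latent state of one simulated participant."""

    participant_id: int
    regime: str
    mu_i: float
    t_i: float = float("nan")  # graded deviation on logit scale
    T_i: int = -1  # discrete group label; -1 when not applicable
    rt_ms: float = float("nan")
    n_verbs: int = 0
    total_vocab: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mu_i < 1.0:
            raise ValueError("mu_i must lie strictly inside (0, 1)")
        if self.T_i not in (-1, 0, 1):
            raise ValueError("T_i must be 0, 1, or -1 (unused)")
        if self.n_verbs > self.total_vocab:
            raise ValueError("n_verbs cannot exceed total_vocab")
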
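"""Shared fixtures and independent oracle models for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betaln, expit, gammaln

from lookmix.simulate import (
    GazeSimConfig,
    GenerativeConfig,
    ParticipantTruth,
    generate_participants,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    return GazeSimConfig()


@pytest.fixture
def graded_config():
    return GenerativeConfig(regime="graded", n_participants=20, seed=7)


@pytest.fixture
def truth():
    return ParticipantTruth(
        participant_id=1,
        regime="graded",
        mu_i=0.55,
        t_i=0.2,
        rt_ms=560.0,
        n_verbs=50,
        total_vocab=300,
    )


def make_window_frame(records):
    """WindowSummary rows from (pid, trial, window, prop, frac_missing, n_valid)."""
    rows = []
    for pid, trial, window, prop, fm, nv in records:
        rows.append(
            {
                "participant_id": pid,
                "sequence_id": (pid - 1) % 8 + 1,
                "trial": trial,
                "window": window,
                "prop_target": prop,
                "frac_missing": fm,
                "n_valid": nv,
                "excluded": False,
            }
        )
    return pd.DataFrame(rows)


class NormalNormalToy:
    """Conjugate toy: y_i ~ N(theta, s2) with theta ~ N(m0, t2).

    The marginal likelihood is multivariate normal with covariance
    s2*I + t2*J -- the independent closed-form oracle for bridge sampling.
    """

    def __init__(self, y, s2=1.0, m0=0.0, t2=4.0):
        self.y = np.asarray(y, dtype=float)
        self.s2, self.m0, self.t2 = s2, m0, t2
        self.dim = 1

    def logp_grad(self, th):
        t = th[0]
        n = len(self.y)
        lp = (
            -0.5 * np.sum((self.y - t) ** 2) / self.s2
            - n / 2 * np.log(2 * np.pi * self.s2)
            - 0.5 * (t - self.m0) ** 2 / self.t2
            - 0.5 * np.log(2 * np.pi * self.t2)
        )
        g = np.sum(self.y - t) / self.s2 - (t - self.m0) / self.t2
        return lp, np.array([g])

    def logp(self, th):
        return self.logp_grad(th)[0]

    def exact_log_evidence(self):
        n = len(self.y)
        cov = self.s2 * np.eye(n) + self.t2 * np.ones((n, n))
        return float(
            stats.multivariate_normal(np.full(n, self.m0), cov).logpdf(self.y)
        )


class BetaBinomialToy:
    """Conjugate toy: k | p ~ Binomial(n, p), p ~ Beta(a, b), sampled on logit(p)."""

    def __init__(self, k=7, n=20, a=2.0, b=3.0):
        self.k, self.n, self.a, self.b = k, n, a, b
        self.dim = 1

    def _const(self):
        return (
            gammaln(self.n + 1)
            - gammaln(self.k + 1)
            - gammaln(self.n - self.k + 1)
            - betaln(self.a, self.b)
        )

    def logp_grad(self, th):
        u = th[0]
        p = expit(u)
        # likelihood + prior + logit jacobian collapse to a beta density in u
        lp = (
            self._const()
            + (self.k + self.a) * np.log(p)
            + (self.n - self.k + self.b) * np.log1p(-p)
        )
        g = (self.k + self.a) - (self.n + self.a + self.b) * p
        return lp, np.array([g])

    def logp(self, th):
        return self.logp_grad(th)[0]

    def exact_log_evidence(self):
        return float(
            gammaln(self.n + 1)
            - gammaln(self.k + 1)
            - gammaln(self.n - self.k + 1)
            + betaln(self.k + self.a, self.n - self.k + self.b)
            - betaln(self.a, self.b)
        )


@pytest.fixture
def normal_normal_toy():
    return NormalNormalToy(np.array([0.3, -0.4, 0.9]))


@pytest.fixture
def beta_binomial_toy():
    return BetaBinomialToy()
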
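"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

Models expose ``logp_grad(theta) -> (float, ndarray)`` for the unnormalized
log posterior (constraint Jacobians included).  Warmup adapts the step size
by dual averaging and a diagonal mass matrix from windowed draw variances;
trajectory lengths are jittered to avoid resonance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIVERGENCE_ENERGY = 1000.0


@dataclass
class HmcResult:
    draws: np.ndarray  # (chains, draws, dim), unconstrained
    divergences: int
    accept_rate: float
    step_sizes: list[float] = field(default_factory=list)


class _DualAveraging:
    """Nesterov dual averaging of log step size (standard NUTS constants)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _find_initial_step(logp_grad, theta, inv_mass, rng) -> float:
    """Crude bracketing: double/halve until the one-step accept prob crosses 1/2."""
    eps = 0.1
    lp0, g0 = logp_grad(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = -lp0 + 0.5 * np.sum(p * p * inv_mass)

    def one_step(eps):
        p1 = p + 0.5 * eps * g0
        q1 = theta + eps * inv_mass * p1
        lp1, g1 = logp_grad(q1)
        p1 = p1 + 0.5 * eps * g1
        if not np.isfinite(lp1):
            return -np.inf
        return -(-lp1 + 0.5 * np.sum(p1 * p1 * inv_mass)) + h0

    direction = 1.0 if one_step(eps) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        if direction * one_step(eps) < direction * np.log(0.5):
            break
    return float(min(max(eps, 1e-8), 10.0))


def _leapfrog(logp_grad, q, p, eps, n_steps, inv_mass):
    lp, g = logp_grad(q)
    p = p + 0.5 * eps * g
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        lp, g = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * g
    return q, p, lp


def hmc_sample(
    logp_grad,
    dim: int,
    *,
    seed: int,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    target_accept: float = 0.9,
    max_leapfrog: int = 128,
    traj_len: float = 1.2,
    init: np.ndarray | None = None,
    init_jitter: float = 0.5,
) -> HmcResult:
    """Run ``chains`` independent adaptive HMC chains.

    Returns post-warmup draws in unconstrained space.  Divergences (energy
    error above 1000 or non-finite density mid-trajectory) are counted on
    post-warmup iterations only.
    """
    root = np.random.default_rng(seed)
    all_draws = np.empty((chains, draws, dim))
    divergences = 0
    accepts = 0
    step_sizes = []

    for chain in range(chains):
        rng = np.random.default_rng(root.integers(2**63))
        if init is not None:
            q = np.array(init, dtype=float) + init_jitter * rng.standard_normal(dim) * 0.1
        else:
            q = init_jitter * rng.standard_normal(dim)
        inv_mass = np.ones(dim)
        eps = _find_initial_step(logp_grad, q, inv_mass, rng)
        da = _DualAveraging(eps, target_accept)

        # mass-matrix re-estimation checkpoints within warmup
        checkpoints = {int(warmup * f) for f in (0.4, 0.7, 0.9) if warmup > 20}
        window: list[np.ndarray] = []

        lp, _ = logp_grad(q)
        for it in range(warmup + draws):
            in_warmup = it < warmup
            if it == warmup:
                eps = da.adapted
                step_sizes.append(eps)
            p = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = -lp + 0.5 * np.sum(p * p * inv_mass)
            n_base = max(1, min(max_leapfrog, int(round(traj_len / max(eps, 1e-8)))))
            n_steps = int(rng.integers(max(1, n_base // 2), n_base + 1))
            q_new, p_new, lp_new = _leapfrog(logp_grad, q, p, eps, n_steps, inv_mass)
            if np.isfinite(lp_new):
                h1 = -lp_new + 0.5 * np.sum(p_new * p_new * inv_mass)
                delta = h0 - h1
            else:
                delta = -np.inf
            accept_prob = min(1.0, np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
            divergent = (not np.isfinite(delta)) or (-delta > DIVERGENCE_ENERGY)
            if rng.random() < accept_prob and not divergent:
                q, lp = q_new, lp_new
            if in_warmup:
                eps = da.update(accept_prob)
                window.append(q.copy())
                if it in checkpoints and len(window) > 10:
                    var = np.var(np.asarray(window), axis=0)
                    var = np.where(var > 1e-12, var, 1e-12)
                    # regularize toward unity like Stan's windowed adaptation
                    w = len(window)
                    inv_mass = (w / (w + 5.0)) * var + (5.0 / (w + 5.0)) * 1e-3
                    window.clear()
                    eps = da.adapted
                    da = _DualAveraging(eps, target_accept)
            else:
                if divergent:
                    divergences += 1
                accepts += accept_prob
                all_draws[chain, it - warmup] = q
    return HmcResult(
        draws=all_draws,
        divergences=divergences,
        accept_rate=accepts / (chains * draws),
        step_sizes=step_sizes,
    )
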
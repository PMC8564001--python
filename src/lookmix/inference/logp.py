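"""Unconstrained log posteriors with analytic gradients.

Two model families cover every specification in the registry:

* :class:`HierBetaModel` -- beta mean-precision regression with a logit link,
  arbitrary fixed-effect columns and non-centered Gaussian random effects by
  any number of grouping factors (random intercepts or full uncorrelated
  random effects).  The graded (random-intercept-only) structure model is the
  one-group special case.
* :class:`MixtureBetaModel` -- two-component beta mixture with the latent
  group membership marginalized out (log-sum-exp over components), optionally
  with a covariate on the second component's mean logit or on the membership
  logit.

Positive parameters are log-transformed and probabilities logit-transformed;
all log densities include the transformation Jacobians, so ``logp(theta)``
is the unnormalized posterior on R^d and its integral is the marginal
likelihood (as required by bridge sampling).
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

from lookmix.models.priors import PriorSpec

_MU_EPS = 1e-12
_LOG_CAP = 45.0  # caps exp() of log-transformed positives; keeps logp finite


def _exp_clip(u):
    return np.exp(np.clip(u, -_LOG_CAP, _LOG_CAP))


def _beta_ll_terms(y, logit_y_terms, mu, phi):
    """Pointwise beta log likelihood and its partials wrt eta (logit mu) and phi.

    ``logit_y_terms`` caches (log y, log1p(-y), logit y).
    """
    ly, l1my, logit_y = logit_y_terms
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * ly + (b - 1.0) * l1my
    da, db = digamma(a), digamma(b)
    dll_dmu = phi * (logit_y - da + db)
    dll_deta = dll_dmu * mu * (1.0 - mu)
    dll_dphi = mu * ly + (1.0 - mu) * l1my + digamma(phi) - mu * da - (1.0 - mu) * db
    return ll, dll_deta, dll_dphi


def _prior_logpdf_grad(prior: PriorSpec, value: float):
    """Log prior density and d/dvalue on the *natural* (untransformed) axis."""
    p = prior.params
    d = prior.distribution
    if d == "normal":
        z = (value - p["mean"]) / p["sd"]
        return -0.5 * z * z - np.log(p["sd"]), -z / p["sd"]
    if d == "student_t":
        nu, m, s = p["df"], p.get("mean", 0.0), p["sd"]
        u = (value - m) / s
        lp = -0.5 * (nu + 1.0) * np.log1p(u * u / nu)
        g = -(nu + 1.0) * (value - m) / (nu * s * s + (value - m) ** 2)
        return lp, g
    if d == "exponential":
        r = p["rate"]
        return -r * value, -r
    if d == "half_normal":
        s = p["sd"]
        return -0.5 * (value / s) ** 2, -value / s**2
    if d == "gamma":
        a, r = p["shape"], p["rate"]
        return (a - 1.0) * np.log(value) - r * value, (a - 1.0) / value - r
    raise ValueError(f"no gradient rule for prior {d!r}")


def _log_prior(prior: PriorSpec, u: float, transform: str):
    """Log prior + Jacobian and gradient wrt the unconstrained coordinate u."""
    if transform == "identity":
        return _prior_logpdf_grad(prior, u)
    if transform == "log":
        v = _exp_clip(u)
        lp, g = _prior_logpdf_grad(prior, v)
        return lp + u, g * v + 1.0
    if transform == "logit":
        # only used with a flat Beta(1,1) prior on the probability
        pr = np.clip(expit(u), 1e-15, 1.0 - 1e-15)
        a, b = prior.params.get("a", 1.0), prior.params.get("b", 1.0)
        lp = a * np.log(pr) + b * np.log1p(-pr)  # includes Jacobian pr(1-pr)
        g = a - (a + b) * pr
        return lp, g
    raise ValueError(transform)


class HierBetaModel:
    """Beta regression with fixed effects X and non-centered random effects.

    Parameters (unconstrained vector, in order):
      beta (k; a coordinate is log-transformed when its prior is
      exponential), log phi, log sd for each (group, column) random-effect
      block, then the standard-normal effects z for each block.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        beta_priors: list[PriorSpec],
        phi_prior: PriorSpec,
        groups: list[dict] | None = None,
        column_names: list[str] | None = None,
    ):
        y = np.asarray(y, dtype=float)
        if len(y) == 0:
            raise ValueError("empty response")
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("responses must lie strictly inside (0, 1)")
        self.y = y
        self.X = np.asarray(X, dtype=float)
        self.n, self.k = self.X.shape
        if len(beta_priors) != self.k:
            raise ValueError("one prior per fixed-effect column required")
        self.beta_priors = beta_priors
        self.beta_transforms = [
            "log" if p.distribution == "exponential" else "identity"
            for p in beta_priors
        ]
        self.phi_prior = phi_prior
        self.column_names = column_names or [f"x{i}" for i in range(self.k)]
        self._logit_terms = (np.log(y), np.log1p(-y), np.log(y) - np.log1p(-y))

        # groups: name, index (n,), n_levels, z_cols (column indices of X),
        # sd_prior
        self.groups = groups or []
        self._blocks = []  # (group_pos, col, sd_slot, z_slot, size)
        pos = self.k + 1
        self._sd_slots = []
        for g in self.groups:
            for c in g["z_cols"]:
                self._sd_slots.append((g, c, pos))
                pos += 1
        self._z_slots = []
        for g, c, _ in self._sd_slots:
            self._z_slots.append((g, c, pos, g["n_levels"]))
            pos += g["n_levels"]
        self.dim = pos

        names = [f"b_{nm}" for nm in self.column_names] + ["phi"]
        for g, c, _ in self._sd_slots:
            names.append(f"sd_{g['name']}_{self.column_names[c]}")
        self.scalar_names = names

    # -- core density ---------------------------------------------------
    def _eta_mu(self, theta):
        beta = theta[: self.k].copy()
        for i, tr in enumerate(self.beta_transforms):
            if tr == "log":
                beta[i] = _exp_clip(beta[i])
        eta = self.X @ beta
        for (g, c, sd_slot), (_, _, z_slot, L) in zip(self._sd_slots, self._z_slots):
            sd = _exp_clip(theta[sd_slot])
            z = theta[z_slot : z_slot + L]
            eta = eta + self.X[:, c] * (sd * z[g["index"]])
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        return beta, eta, mu

    def logp_grad(self, theta: np.ndarray):
        beta, eta, mu = self._eta_mu(theta)
        phi = _exp_clip(theta[self.k])
        ll, dll_deta, dll_dphi = _beta_ll_terms(self.y, self._logit_terms, mu, phi)
        logp = float(ll.sum())
        grad = np.zeros_like(theta)

        # fixed effects
        gb = self.X.T @ dll_deta
        for i, (prior, tr) in enumerate(zip(self.beta_priors, self.beta_transforms)):
            lp, gp = _log_prior(prior, theta[i], tr)
            logp += lp
            grad[i] = gp + (gb[i] * beta[i] if tr == "log" else gb[i])

        # precision
        lp, gp = _log_prior(self.phi_prior, theta[self.k], "log")
        logp += lp
        grad[self.k] = gp + dll_dphi.sum() * phi

        # random effects
        for (g, c, sd_slot), (_, _, z_slot, L) in zip(self._sd_slots, self._z_slots):
            sd = _exp_clip(theta[sd_slot])
            z = theta[z_slot : z_slot + L]
            w = self.X[:, c] * dll_deta
            per_level = np.bincount(g["index"], weights=w, minlength=L)
            lp, gp = _log_prior(g["sd_prior"], theta[sd_slot], "log")
            logp += lp + float(-0.5 * z @ z)
            grad[sd_slot] = gp + sd * float(z @ per_level)
            grad[z_slot : z_slot + L] = sd * per_level - z
        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        _, _, mu = self._eta_mu(theta)
        phi = _exp_clip(theta[self.k])
        ll, _, _ = _beta_ll_terms(self.y, self._logit_terms, mu, phi)
        return ll

    # -- draws -> named parameters ---------------------------------------
    def constrain(self, draws: np.ndarray) -> dict[str, np.ndarray]:
        """Map (chains, draws, dim) unconstrained draws to named parameters."""
        out: dict[str, np.ndarray] = {}
        for i, nm in enumerate(self.column_names):
            v = draws[..., i]
            out[f"b_{nm}"] = np.exp(v) if self.beta_transforms[i] == "log" else v
        out["phi"] = np.exp(draws[..., self.k])
        for (g, c, sd_slot), (_, _, z_slot, L) in zip(self._sd_slots, self._z_slots):
            sd = np.exp(draws[..., sd_slot])
            out[f"sd_{g['name']}_{self.column_names[c]}"] = sd
            out[f"z_{g['name']}_{self.column_names[c]}"] = draws[
                ..., z_slot : z_slot + L
            ]
        return out

    def init_point(self) -> np.ndarray:
        theta = np.zeros(self.dim)
        from scipy.special import logit

        ybar = float(np.clip(np.mean(self.y), 0.05, 0.95))
        if self.beta_transforms[0] == "identity":
            theta[0] = logit(ybar)
        theta[self.k] = np.log(10.0)
        for _, _, sd_slot in self._sd_slots:
            theta[sd_slot] = np.log(0.1)
        return theta


class MixtureBetaModel:
    """Marginalized two-component beta mixture.

    Parameter order: mu1_logit, mu2 intercept [, mu2 slope], log phi1,
    log phi2, then either pi_logit or (pi intercept, pi slope).
    """

    def __init__(
        self,
        y: np.ndarray,
        mu1_prior: PriorSpec,
        mu2_prior: PriorSpec,
        phi1_prior: PriorSpec,
        phi2_prior: PriorSpec,
        pi_prior: PriorSpec,
        placement: str = "none",
        x: np.ndarray | None = None,
        pi_intercept_prior: PriorSpec | None = None,
        slope_prior: PriorSpec | None = None,
    ):
        y = np.asarray(y, dtype=float)
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("responses must lie strictly inside (0, 1)")
        if placement not in ("none", "mu2:rt_std", "pi:verbs_std"):
            raise ValueError(f"unknown placement {placement!r}")
        if placement != "none" and x is None:
            raise ValueError("covariate values required for this placement")
        self.y = y
        self.n = len(y)
        self.placement = placement
        self.x = np.asarray(x, dtype=float) if x is not None else None
        self.mu1_prior = mu1_prior
        self.mu2_prior = mu2_prior
        self.phi1_prior = phi1_prior
        self.phi2_prior = phi2_prior
        self.pi_prior = pi_prior
        self.pi_intercept_prior = pi_intercept_prior
        self.slope_prior = slope_prior
        self._logit_terms = (np.log(y), np.log1p(-y), np.log(y) - np.log1p(-y))

        names = ["mu1_logit", "mu2_logit"]
        if placement == "mu2:rt_std":
            names.append("b_rt")
        names += ["phi1", "phi2"]
        if placement == "pi:verbs_std":
            names += ["pi_b0", "b_verbs"]
        else:
            names.append("pi")
        self.scalar_names = names
        self.dim = len(names)

    def _unpack(self, theta):
        i = 0
        mu1_l = theta[i]; i += 1
        mu2_b0 = theta[i]; i += 1
        mu2_b1 = 0.0
        if self.placement == "mu2:rt_std":
            mu2_b1 = theta[i]; i += 1
        lphi1 = theta[i]; i += 1
        lphi2 = theta[i]; i += 1
        if self.placement == "pi:verbs_std":
            pi_b0, pi_b1 = theta[i], theta[i + 1]
            pl = pi_b0 + pi_b1 * self.x
        else:
            pi_b0, pi_b1 = theta[i], 0.0
            pl = np.full(self.n, pi_b0)
        return mu1_l, mu2_b0, mu2_b1, lphi1, lphi2, pi_b0, pi_b1, pl

    def _components(self, theta):
        mu1_l, mu2_b0, mu2_b1, lphi1, lphi2, _, _, pl = self._unpack(theta)
        mu1 = float(np.clip(expit(mu1_l), _MU_EPS, 1 - _MU_EPS))
        eta2 = mu2_b0 + (mu2_b1 * self.x if self.placement == "mu2:rt_std" else 0.0)
        mu2 = np.clip(expit(eta2), _MU_EPS, 1 - _MU_EPS)
        phi1, phi2 = _exp_clip(lphi1), _exp_clip(lphi2)
        pi = np.clip(expit(pl), _MU_EPS, 1 - _MU_EPS)
        return mu1, mu2, phi1, phi2, pi

    def _mixture_terms(self, theta):
        mu1, mu2, phi1, phi2, pi = self._components(theta)
        ll1, d1_eta, d1_phi = _beta_ll_terms(self.y, self._logit_terms, mu1, phi1)
        ll2, d2_eta, d2_phi = _beta_ll_terms(self.y, self._logit_terms, mu2, phi2)
        la = np.log1p(-pi) + ll1
        lb = np.log(pi) + ll2
        lmix = np.logaddexp(la, lb)
        r2 = np.exp(lb - lmix)  # responsibility of component 2
        r1 = 1.0 - r2
        return lmix, r1, r2, d1_eta, d1_phi, d2_eta, d2_phi, pi, phi1, phi2

    def logp_grad(self, theta: np.ndarray):
        (lmix, r1, r2, d1_eta, d1_phi, d2_eta, d2_phi, pi, phi1, phi2) = (
            self._mixture_terms(theta)
        )
        logp = float(lmix.sum())
        grad = np.zeros_like(theta)

        i = 0
        lp, gp = _log_prior(self.mu1_prior, theta[i], "identity")
        logp += lp
        grad[i] = gp + float((r1 * d1_eta).sum())
        i += 1

        lp, gp = _log_prior(self.mu2_prior, theta[i], "identity")
        logp += lp
        grad[i] = gp + float((r2 * d2_eta).sum())
        i += 1
        if self.placement == "mu2:rt_std":
            lp, gp = _log_prior(self.slope_prior, theta[i], "identity")
            logp += lp
            grad[i] = gp + float((r2 * d2_eta * self.x).sum())
            i += 1

        lp, gp = _log_prior(self.phi1_prior, theta[i], "log")
        logp += lp
        grad[i] = gp + float((r1 * d1_phi).sum()) * phi1
        i += 1
        lp, gp = _log_prior(self.phi2_prior, theta[i], "log")
        logp += lp
        grad[i] = gp + float((r2 * d2_phi).sum()) * phi2
        i += 1

        dl_dpl = r2 - pi  # d log mix / d logit(pi), per observation
        if self.placement == "pi:verbs_std":
            lp, gp = _log_prior(self.pi_intercept_prior, theta[i], "identity")
            logp += lp
            grad[i] = gp + float(dl_dpl.sum())
            lp, gp = _log_prior(self.slope_prior, theta[i + 1], "identity")
            logp += lp
            grad[i + 1] = gp + float((dl_dpl * self.x).sum())
        else:
            lp, gp = _log_prior(self.pi_prior, theta[i], "logit")
            logp += lp
            grad[i] = gp + float(dl_dpl.sum())
        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        return self._mixture_terms(theta)[0]

    def membership_probs(self, theta: np.ndarray) -> np.ndarray:
        """Posterior P(T_i = 1 | y_i, theta) per observation."""
        return self._mixture_terms(theta)[2]

    def constrain(self, draws: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, nm in enumerate(self.scalar_names):
            v = draws[..., i]
            if nm in ("phi1", "phi2"):
                out[nm] = np.exp(v)
            elif nm == "pi":
                out[nm] = expit(v)
            else:
                out[nm] = v
        if self.placement == "pi:verbs_std":
            out["pi_at_mean"] = expit(out["pi_b0"])
        return out

    def init_point(self) -> np.ndarray:
        theta = np.zeros(self.dim)
        theta[self.scalar_names.index("mu2_logit")] = 0.4
        theta[self.scalar_names.index("phi1")] = np.log(15.0)
        theta[self.scalar_names.index("phi2")] = np.log(10.0)
        return theta
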
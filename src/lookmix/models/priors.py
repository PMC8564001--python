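"""Named prior specifications and their probability-scale implications."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

SUPPORTED = ("normal", "gamma", "exponential", "half_normal", "student_t", "beta")


@dataclass(frozen=True)
class PriorSpec:
    """A prior distribution attached to a named parameter.

    ``scale`` records whether the parameter lives on the logit or natural
    scale.  ``gamma`` uses the shape-rate convention.
    """

    distribution: str
    params: dict = field(default_factory=dict)
    applies_to: str = ""
    scale: str = "logit"

    def __post_init__(self) -> None:
        if self.distribution not in SUPPORTED:
            raise ValueError(f"unsupported distribution {self.distribution!r}")
        p = self.params
        for key in ("s", "sd", "rate", "shape"):
            if key in p and p[key] <= 0:
                raise ValueError(f"{key} must be > 0")

    def frozen(self):
        """The corresponding scipy frozen distribution."""
        p = self.params
        if self.distribution == "normal":
            return stats.norm(p["mean"], p["sd"])
        if self.distribution == "gamma":
            return stats.gamma(p["shape"], scale=1.0 / p["rate"])
        if self.distribution == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.distribution == "half_normal":
            return stats.halfnorm(scale=p["sd"])
        if self.distribution == "student_t":
            return stats.t(p["df"], loc=p.get("mean", 0.0), scale=p["sd"])
        if self.distribution == "beta":
            return stats.beta(p["a"], p["b"])
        raise AssertionError

    def describe(self) -> str:
        args = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"{self.distribution}({args}) on {self.applies_to} [{self.scale} scale]"


def prior_interval(prior: PriorSpec, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed prior interval pushed through inverse-logit.

    The prior must live on the logit scale; because inverse-logit is
    monotone, quantiles commute with the transformation, so the endpoints
    are exact.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if prior.scale != "logit":
        raise ValueError("prior_interval expects a logit-scale prior")
    alpha = (1.0 - level) / 2.0
    dist = prior.frozen()
    lo, hi = dist.ppf(alpha), dist.ppf(1.0 - alpha)
    return float(expit(lo)), float(expit(hi))


def prior_quantile_prob(prior: PriorSpec, q: float) -> float:
    """A single prior quantile on the probability scale."""
    return float(expit(prior.frozen().ppf(q)))


# The paper-stated priors, by role.
def null_intercept_prior() -> PriorSpec:
    return PriorSpec("normal", {"mean": 0.0, "sd": 0.05}, "intercept", "logit")


def alt1_intercept_prior() -> PriorSpec:
    return PriorSpec("normal", {"mean": 0.4, "sd": 0.15}, "intercept", "logit")


def alt2_intercept_prior() -> PriorSpec:
    return PriorSpec("exponential", {"rate": 1.0}, "intercept", "logit")


def sigma_prior() -> PriorSpec:
    # stated Normal(0, 1) on an SD; implemented as its positive truncation
    return PriorSpec("half_normal", {"sd": 1.0}, "sigma", "natural")


def phi_prior() -> PriorSpec:
    return PriorSpec("gamma", {"shape": 3.5, "rate": 0.5}, "phi", "natural")


def default_intercept_prior() -> PriorSpec:
    # documented weakly-informative default for the plain chance-test model
    return PriorSpec("student_t", {"df": 3, "mean": 0.0, "sd": 2.5}, "intercept", "logit")


def default_slope_prior(name: str = "slope") -> PriorSpec:
    return PriorSpec("normal", {"mean": 0.0, "sd": 1.0}, name, "logit")


def membership_intercept_prior() -> PriorSpec:
    return PriorSpec("normal", {"mean": 0.0, "sd": 1.5}, "pi_intercept", "logit")


def uniform_pi_prior() -> PriorSpec:
    return PriorSpec("beta", {"a": 1.0, "b": 1.0}, "pi", "natural")
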
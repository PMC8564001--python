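"""Mean-precision beta likelihood and the two-component mixture density."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass(frozen=True)
class BetaMeanPrecision:
    """Beta distribution parameterized by mean ``mu`` and precision ``phi``.

    Shape parameters are ``a = mu * phi`` and ``b = (1 - mu) * phi``; the
    variance is ``mu * (1 - mu) / (1 + phi)``.
    """

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must be in (0, 1)")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")

    @property
    def shapes(self) -> tuple[float, float]:
        return self.mu * self.phi, (1.0 - self.mu) * self.phi

    @property
    def variance(self) -> float:
        return self.mu * (1.0 - self.mu) / (1.0 + self.phi)


def beta_logpdf(y, mu, phi):
    """Log density of Beta(mu*phi, (1-mu)*phi) at y, elementwise.

    Requires y strictly inside (0, 1) -- boundary values have no density
    under a beta likelihood and raise.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any(phi <= 0.0):
        raise ValueError("phi must be > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return out if out.ndim else float(out)


def mixture_loglik(y, pi, mu1, phi1, mu2, phi2):
    """Log of (1-pi)*Beta(y; mu1, phi1) + pi*Beta(y; mu2, phi2), elementwise.

    Computed with log-sum-exp; exact at pi = 0 and pi = 1.
    """
    if np.any((np.asarray(pi) < 0) | (np.asarray(pi) > 1)):
        raise ValueError("pi must be in [0, 1]")
    lf1 = beta_logpdf(y, mu1, phi1)
    lf2 = beta_logpdf(y, mu2, phi2)
    pi = np.asarray(pi, dtype=float)
    with np.errstate(divide="ignore"):
        la = np.log1p(-pi) + lf1
        lb = np.log(pi) + lf2
    out = np.logaddexp(la, lb)
    return out if np.ndim(out) else float(out)
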
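"""PSIS leave-one-out model comparison (arviz-backed)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np


@dataclass(frozen=True)
class LooResult:
    elpd: float
    se: float
    p_loo: float
    pareto_k: np.ndarray
    pointwise: np.ndarray  # per-observation elpd

    @property
    def n_high_k(self) -> int:
        return int((self.pareto_k > 0.7).sum())


@dataclass(frozen=True)
class LooComparison:
    """Pairwise LOO comparison. ``elpd_diff`` is elpd(second) - elpd(first):
    negative values favor the first-listed model."""

    names: tuple[str, str]
    elpd: dict
    elpd_diff: float
    se_diff: float
    results: dict


def _loo_one(fit) -> LooResult:
    # az.loo needs a posterior group for draw counts; any scalar will do
    scalar = next(k for k, v in fit.params.items() if v.ndim == 2)
    idata = az.from_dict(
        posterior={scalar: fit.params[scalar]},
        log_likelihood={"obs": fit.log_lik},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        p_loo=float(res.p_loo),
        pareto_k=np.asarray(res.pareto_k),
        pointwise=np.asarray(res.loo_i),
    )


def loo_elpd(fit) -> LooResult:
    """PSIS-LOO expected log pointwise predictive density for one fit."""
    return _loo_one(fit)


def loo_compare(fits: dict) -> LooComparison:
    """Compare exactly two fits on the same observations.

    ``fits``: ordered mapping name -> PosteriorDraws.  The SE of the elpd
    difference is computed from the pointwise elpd differences.
    """
    if len(fits) != 2:
        raise ValueError("loo_compare expects exactly two fits")
    (name_a, fit_a), (name_b, fit_b) = fits.items()
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("fits have different observation counts")
    res_a, res_b = _loo_one(fit_a), _loo_one(fit_b)
    diff_i = res_b.pointwise - res_a.pointwise
    n = len(diff_i)
    elpd_diff = float(diff_i.sum())
    se_diff = float(np.sqrt(n * np.var(diff_i, ddof=1))) if n > 1 else float("nan")
    return LooComparison(
        names=(name_a, name_b),
        elpd={name_a: res_a.elpd, name_b: res_b.elpd},
        elpd_diff=elpd_diff,
        se_diff=se_diff,
        results={name_a: res_a, name_b: res_b},
    )
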
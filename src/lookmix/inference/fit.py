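"""Model fitting: spec + data -> posterior draws with diagnostics."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from lookmix.inference.logp import HierBetaModel, MixtureBetaModel
from lookmix.inference.sampler import hmc_sample
from lookmix.models.design_matrix import build_design_matrix
from lookmix.models.registry import ChanceTestSpec, DiscreteSpec, GradedSpec


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    seed: int = 0
    max_retries: int = 1
    rhat_threshold: float = 1.01
    max_divergence_rate: float = 0.01


@dataclass
class FitDiagnostics:
    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    divergences: int
    n_draws: int
    converged: bool
    retries: int = 0

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


@dataclass
class PosteriorDraws:
    """Fitted-model artifact: named draws + pointwise log likelihood."""

    params: dict[str, np.ndarray]  # name -> (chains, draws) or (chains, draws, L)
    log_lik: np.ndarray  # (chains, draws, n_obs)
    unconstrained: np.ndarray  # (chains, draws, dim)
    model: object
    meta: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.log_lik.shape[-1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled: (chains*draws, ...)."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Scalar parameters as a flat draws table."""
        cols = {
            k: self.stacked(k)
            for k, v in self.params.items()
            if v.ndim == 2
        }
        return pd.DataFrame(cols)


def _data_hash(y: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(y).tobytes()).hexdigest()[:16]


def _build_model(spec, data: pd.DataFrame):
    if isinstance(spec, GradedSpec):
        y = data["prop"].to_numpy(dtype=float)
        pids = data["participant_id"].to_numpy()
        uniq, idx = np.unique(pids, return_inverse=True)
        cols = ["Intercept"] + list(spec.covariates)
        X = np.column_stack(
            [np.ones(len(y))]
            + [data[c].to_numpy(dtype=float) for c in spec.covariates]
        )
        priors = [spec.intercept_prior] + [spec.slope_prior] * len(spec.covariates)
        groups = [
            {
                "name": "participant",
                "index": idx,
                "n_levels": len(uniq),
                "z_cols": [0],
                "sd_prior": spec.sigma_prior,
            }
        ]
        return HierBetaModel(y, X, priors, spec.phi_prior, groups, cols)
    if isinstance(spec, DiscreteSpec):
        y = data["prop"].to_numpy(dtype=float)
        x = None
        if spec.covariate_placement == "mu2:rt_std":
            x = data["rt_std"].to_numpy(dtype=float)
        elif spec.covariate_placement == "pi:verbs_std":
            x = data["verbs_std"].to_numpy(dtype=float)
        return MixtureBetaModel(
            y,
            spec.mu1_prior,
            spec.mu2_prior,
            spec.phi1_prior,
            spec.phi2_prior,
            spec.pi_prior,
            placement=spec.covariate_placement,
            x=x,
            pi_intercept_prior=spec.pi_intercept_prior,
            slope_prior=spec.slope_prior,
        )
    if isinstance(spec, ChanceTestSpec):
        y = data["prop"].to_numpy(dtype=float)
        Xdf, groups_info = build_design_matrix(data, spec)
        X = Xdf.to_numpy(dtype=float)
        cols = list(Xdf.columns)
        priors = []
        for c in cols:
            priors.append(spec.intercept_prior if c == "Intercept" else spec.slope_prior)
        z_cols = list(range(len(cols))) if spec.full_random_effects else [0]
        # salience is a control covariate, never given a random slope
        if spec.full_random_effects and "salience_logit" in cols:
            z_cols = [i for i in z_cols if cols[i] != "salience_logit"]
        groups = [
            {
                "name": "participant",
                "index": groups_info["participant"]["index"],
                "n_levels": groups_info["participant"]["n_levels"],
                "z_cols": z_cols,
                "sd_prior": spec.sd_prior,
            },
            {
                "name": "item",
                "index": groups_info["item"]["index"],
                "n_levels": groups_info["item"]["n_levels"],
                "z_cols": z_cols,
                "sd_prior": spec.sd_prior,
            },
        ]
        return HierBetaModel(y, X, priors, spec.phi_prior, groups, cols)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def _diagnostics(params: dict[str, np.ndarray], divergences: int, n_draws: int,
                 cfg: McmcConfig, retries: int) -> FitDiagnostics:
    scalars = {k: v for k, v in params.items() if v.ndim == 2}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=scalars)
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in scalars}
    ess = {k: float(ess_ds[k].values) for k in scalars}
    max_rhat = max(rhat.values()) if rhat else np.nan
    div_rate = divergences / max(n_draws, 1)
    converged = bool(
        np.isfinite(max_rhat)
        and max_rhat <= cfg.rhat_threshold
        and div_rate <= cfg.max_divergence_rate
    )
    return FitDiagnostics(rhat, ess, divergences, n_draws, converged, retries)


def fit_model(
    spec,
    data: pd.DataFrame,
    mcmc: McmcConfig | None = None,
) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Fit a registry spec to a data table by adaptive HMC.

    Retries once at a stricter acceptance target when diagnostics fail; the
    returned diagnostics carry the final convergence verdict (``converged``)
    rather than raising, so recovery experiments can record failures
    per replicate.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    model = _build_model(spec, data)

    target = mcmc.target_accept
    warmup = mcmc.warmup
    for attempt in range(mcmc.max_retries + 1):
        res = hmc_sample(
            model.logp_grad,
            model.dim,
            seed=mcmc.seed + 1000 * attempt,
            chains=mcmc.chains,
            warmup=warmup,
            draws=mcmc.draws,
            target_accept=target,
            init=model.init_point(),
        )
        params = model.constrain(res.draws)
        diag = _diagnostics(
            params, res.divergences, mcmc.chains * mcmc.draws, mcmc, attempt
        )
        if diag.converged or attempt == mcmc.max_retries:
            break
        target = min(0.99, target + 0.09)
        warmup = int(warmup * 1.5)

    chains, draws, dim = res.draws.shape
    log_lik = np.empty((chains, draws, model.n))
    for c in range(chains):
        for d in range(draws):
            log_lik[c, d] = model.pointwise_loglik(res.draws[c, d])

    fit = PosteriorDraws(
        params=params,
        log_lik=log_lik,
        unconstrained=res.draws,
        model=model,
        meta={
            "model_name": getattr(spec, "name", type(spec).__name__),
            "seed": mcmc.seed,
            "chains": chains,
            "warmup": warmup,
            "draws": draws,
            "target_accept": target,
            "accept_rate": res.accept_rate,
            "data_hash": _data_hash(model.y),
            "n_obs": model.n,
        },
    )
    return fit, diag
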
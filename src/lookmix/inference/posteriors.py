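"""Posterior summaries on logit and probability scales, and condition means."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit


@dataclass(frozen=True)
class PosteriorSummary:
    parameter: str
    mean: float
    ci_low: float
    ci_high: float
    prob_direction: float
    scale: str  # "logit" or "probability"


def _summary(draws: np.ndarray, name: str, scale: str) -> PosteriorSummary:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return PosteriorSummary(
        parameter=name,
        mean=float(np.mean(draws)),
        ci_low=float(lo),
        ci_high=float(hi),
        prob_direction=float(np.mean(draws > 0)),
        scale=scale,
    )


def summarize(fit, parameter: str, scale: str = "logit") -> PosteriorSummary:
    """Posterior mean, 95% equal-tailed CI and directional mass.

    ``scale="probability"`` applies inverse-logit to each draw *before*
    summarizing (the transform and the summary do not commute for the mean).
    """
    if parameter not in fit.params:
        raise KeyError(f"unknown parameter {parameter!r}")
    draws = fit.stacked(parameter)
    if draws.ndim != 1:
        raise ValueError("summarize expects a scalar parameter")
    if scale == "probability":
        return _summary(expit(draws), parameter, "probability")
    if scale == "logit":
        return _summary(draws, parameter, "logit")
    raise ValueError(f"unknown scale {scale!r}")


def summary_table(fit, parameters: list[str]) -> pd.DataFrame:
    rows = []
    for p in parameters:
        s = summarize(fit, p)
        rows.append(vars(s))
    return pd.DataFrame(rows)


def condition_means(fit, conditions: pd.DataFrame) -> pd.DataFrame:
    """Probability-scale posterior means/CIs per design cell.

    ``conditions`` holds one row per cell with the factor levels used at fit
    time (window/trial[/bin]); the salience covariate is set to 0 and random
    effects to their population level (0).
    """
    model = fit.model
    from lookmix.models.design_matrix import _bin_code, _sum_code

    cols = model.column_names
    rows = []
    for _, cell in conditions.iterrows():
        x = np.zeros(len(cols))
        vals: dict[str, float] = {"Intercept": 1.0}
        if "window" in conditions.columns:
            vals["window"] = 0.5 if cell["window"] == 1 else -0.5
        if "trial" in conditions.columns:
            vals["trial"] = 0.5 if cell["trial"] == 1 else -0.5
        if "bin" in conditions.columns:
            b = _bin_code(pd.Series([cell["bin"]]))[0]
            for k in range(3):
                vals[f"bin{k + 1}"] = b[k]
        if "window" in vals and "trial" in vals:
            vals["window:trial"] = vals["window"] * vals["trial"]
        for fac in ("window", "trial"):
            if fac in vals and "bin" in conditions.columns:
                for k in range(3):
                    vals[f"{fac}:bin{k + 1}"] = vals[fac] * vals[f"bin{k + 1}"]
        if "window" in vals and "trial" in vals and "bin" in conditions.columns:
            for k in range(3):
                vals[f"window:trial:bin{k + 1}"] = (
                    vals["window"] * vals["trial"] * vals[f"bin{k + 1}"]
                )
        missing_factors = [
            c for c in conditions.columns if c in ("window", "trial", "bin")
            and c not in cols and f"{c}1" not in cols
        ]
        if missing_factors:
            raise ValueError(f"fit lacks factors {missing_factors}")
        for name, v in vals.items():
            if name in cols:
                x[cols.index(name)] = v
        eta_draws = np.zeros(fit.stacked("phi").shape[0])
        for i, name in enumerate(cols):
            if x[i] != 0.0:
                eta_draws = eta_draws + x[i] * fit.stacked(f"b_{name}")
        p_draws = expit(eta_draws)
        lo, hi = np.quantile(p_draws, [0.025, 0.975])
        row = {c: cell[c] for c in conditions.columns}
        row.update(
            mean=float(np.mean(p_draws)), ci_low=float(lo), ci_high=float(hi)
        )
        rows.append(row)
    return pd.DataFrame(rows)
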
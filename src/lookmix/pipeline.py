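"""End-to-end orchestration: simulate -> preprocess -> fit -> compare -> report.

Stages are cached by a content hash of their configuration (plus upstream
hashes), so re-running a pipeline recomputes only what changed.  Every report
echoes the seeds, priors, exclusion thresholds and sampler settings needed to
reproduce it bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lookmix.inference import (
    McmcConfig,
    bayes_factor,
    fit_model,
    loo_compare,
    pairwise_correlations,
    summarize,
)
from lookmix.models import make_paper_models, serialize_registry
from lookmix.models.registry import ChanceTestSpec, DiscreteSpec, GradedSpec
from lookmix.preprocess import (
    apply_exclusions,
    attach_salience,
    build_covariates,
    participant_rt,
    session_rts,
    summarize_windows,
    sv_transform,
)
from lookmix.simulate import (
    GazeSimConfig,
    GenerativeConfig,
    design_frame,
    generate_gaze_stream,
    generate_lwl_session,
    generate_participants,
    simulate_proportions,
    truths_frame,
)

log = logging.getLogger("lookmix")


@dataclass(frozen=True)
class PreprocessConfig:
    missing_threshold: float = 0.66
    expected_windows: int = 4
    max_missing_windows: int = 2


@dataclass(frozen=True)
class ExperimentConfig:
    n_replicates: int = 20
    regimes: tuple[str, ...] = ("graded", "discrete")
    n_participants: int = 200
    n_obs: int = 1
    seed: int = 0
    graded_sigma: float = 0.5
    graded_phi: float = 22.0
    graded_B0: float = 0.04
    discrete_pi: float = 0.5
    discrete_mu1_logit: float = 0.0
    discrete_mu2_logit: float = 1.4
    discrete_phi: float = 60.0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "out"
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    gaze_sim: GazeSimConfig = field(default_factory=GazeSimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    models: tuple[str, ...] = (
        "chance",
        "chance_salience",
        "bf_null",
        "bf_alt1",
        "bf_alt2",
        "window_trial",
        "graded",
        "discrete",
    )
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(chains=2, warmup=400, draws=400))
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def __post_init__(self) -> None:
        known = set(make_paper_models())
        unknown = set(self.models) - known
        if unknown:
            raise ValueError(f"unknown model names: {sorted(unknown)}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "generative" in raw:
        kwargs["generative"] = GenerativeConfig(**raw["generative"])
    if "gaze_sim" in raw:
        kwargs["gaze_sim"] = GazeSimConfig(**raw["gaze_sim"])
    if "preprocess" in raw:
        kwargs["preprocess"] = PreprocessConfig(**raw["preprocess"])
    if "mcmc" in raw:
        kwargs["mcmc"] = McmcConfig(**raw["mcmc"])
    if "experiment" in raw:
        exp = dict(raw["experiment"])
        if "regimes" in exp:
            exp["regimes"] = tuple(exp["regimes"])
        kwargs["experiment"] = ExperimentConfig(**exp)
    if "models" in raw:
        kwargs["models"] = tuple(raw["models"])
    if "out_dir" in raw:
        kwargs["out_dir"] = raw["out_dir"]
    return PipelineConfig(**kwargs)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_cached(stage_dir: Path, key: str) -> bool:
    mark = stage_dir / ".stage_hash"
    return mark.exists() and mark.read_text().strip() == key


def _mark_stage(stage_dir: Path, key: str) -> None:
    (stage_dir / ".stage_hash").write_text(key + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> dict[str, Path]:
    sdir = out / "sim"
    sdir.mkdir(parents=True, exist_ok=True)
    key = _hash_obj(
        [dataclasses.asdict(config.generative), dataclasses.asdict(config.gaze_sim)]
    )
    paths = {
        "gaze": sdir / "gaze.csv",
        "lwl": sdir / "lwl.csv",
        "truths": sdir / "truths.csv",
    }
    if _stage_cached(sdir, key) and all(p.exists() for p in paths.values()):
        log.info("simulate: cached")
        return paths
    gen, sim = config.generative, config.gaze_sim
    rng = np.random.default_rng(gen.seed)
    truths = generate_participants(gen, rng)
    from lookmix.simulate.design import design_lookup

    lookup = design_lookup()
    gaze_frames, lwl_frames = [], []
    for t in truths:
        seq = (t.participant_id - 1) % 8 + 1
        d_rows = [lookup[(seq, 1)], lookup[(seq, 2)]]
        gaze_frames.append(generate_gaze_stream(t, d_rows, sim, rng))
        planted = list(
            np.round(rng.uniform(350, 1200, size=max(sim.lwl_trials - 2, 1)) / 50) * 50
        )
        planted += ["target_initial", "missing"]
        lwl_frames.append(generate_lwl_session(t, sim, planted, rng))
    pd.concat(gaze_frames, ignore_index=True).to_csv(paths["gaze"], index=False)
    pd.concat(lwl_frames, ignore_index=True).to_csv(paths["lwl"], index=False)
    truths_frame(truths).to_csv(paths["truths"], index=False)
    _mark_stage(sdir, key)
    log.info("simulate: wrote %s participants", len(truths))
    return paths


def stage_preprocess(config: PipelineConfig, out: Path, sim_paths: dict) -> dict:
    pdir = out / "preprocess"
    pdir.mkdir(parents=True, exist_ok=True)
    key = _hash_obj(
        [
            dataclasses.asdict(config.preprocess),
            {k: str(v) for k, v in sim_paths.items()},
            (out / "sim" / ".stage_hash").read_text()
            if (out / "sim" / ".stage_hash").exists()
            else "",
        ]
    )
    paths = {
        "windows": pdir / "windows.csv",
        "salience": pdir / "salience.csv",
        "covariates": pdir / "covariates.csv",
        "audit": pdir / "audit.log",
    }
    if _stage_cached(pdir, key) and all(p.exists() for p in paths.values()):
        log.info("preprocess: cached")
        return paths
    pc = config.preprocess
    gaze = pd.read_csv(sim_paths["gaze"])
    windows = summarize_windows(gaze, pc.missing_threshold)
    included, excluded_pids, audit = apply_exclusions(
        windows,
        pc.missing_threshold,
        pc.expected_windows,
        pc.max_missing_windows,
    )
    design = design_frame()
    from lookmix.preprocess import action_salience

    sal = action_salience(included, design)
    obs = attach_salience(included, design, sal)
    obs.to_csv(paths["windows"], index=False)
    sal.to_csv(paths["salience"], index=False)

    # covariates: RT from the simulated looking-while-listening session
    lwl = pd.read_csv(sim_paths["lwl"])
    truths = pd.read_csv(sim_paths["truths"])
    onset = config.gaze_sim.lwl_target_onset_ms
    rt_rows = []
    for pid, sub in lwl.groupby("participant_id", sort=True):
        recs = session_rts(sub, onset, config.gaze_sim.sample_rate_hz)
        rt_rows.append({"participant_id": pid, "rt_ms": participant_rt(recs)})
        for r in recs:
            audit.append(
                f"lwl participant={r.participant_id} trial={r.trial} "
                f"eligible={r.eligible} reason={r.exclusion_reason}"
            )
    rt_df = pd.DataFrame(rt_rows)
    cov_src = truths[["participant_id", "n_verbs", "total_vocab"]].merge(
        rt_df, on="participant_id"
    )
    cov_src = cov_src[~cov_src["participant_id"].isin(excluded_pids)]
    cov = build_covariates(cov_src)
    cov.to_csv(paths["covariates"], index=False)
    paths["audit"].write_text("\n".join(audit) + "\n")
    _mark_stage(pdir, key)
    log.info(
        "preprocess: %d windows kept, %d participants excluded",
        len(included),
        len(excluded_pids),
    )
    return paths


def participant_means(obs: pd.DataFrame) -> pd.DataFrame:
    """Average proportion per participant across retained windows (the
    structure-model response), with boundary values transformed away."""
    means = (
        obs.groupby("participant_id", as_index=False)["prop_target"]
        .mean()
        .rename(columns={"prop_target": "prop"})
    )
    at_boundary = (means["prop"] <= 0) | (means["prop"] >= 1)
    if at_boundary.any():
        means["prop"] = sv_transform(means["prop"].to_numpy(), len(means))
    return means


def _model_data(name: str, spec, obs: pd.DataFrame, cov: pd.DataFrame) -> pd.DataFrame:
    if isinstance(spec, ChanceTestSpec):
        data = obs.rename(columns={"prop_target": "prop"}).copy()
        bad = (data["prop"] <= 0) | (data["prop"] >= 1)
        if bad.any():
            data["prop"] = sv_transform(data["prop"].to_numpy(), len(data))
            log.info("%s: boundary proportions transformed (n=%d)", name, bad.sum())
        return data
    means = participant_means(obs)
    data = means.merge(
        cov[["participant_id", "rt_std", "verbs_std"]], on="participant_id", how="left"
    )
    needed = list(getattr(spec, "covariates", ()))
    placement = getattr(spec, "covariate_placement", "none")
    if placement == "mu2:rt_std":
        needed.append("rt_std")
    elif placement == "pi:verbs_std":
        needed.append("verbs_std")
    for c in needed:
        data = data[np.isfinite(data[c])]
    return data


def stage_fit(config: PipelineConfig, out: Path, prep_paths: dict) -> dict:
    fdir = out / "fits"
    fdir.mkdir(parents=True, exist_ok=True)
    registry = make_paper_models()
    obs = pd.read_csv(prep_paths["windows"])
    cov = pd.read_csv(prep_paths["covariates"])
    fits, diags = {}, {}
    for name in config.models:
        spec = registry[name]
        data = _model_data(name, spec, obs, cov)
        fit, diag = fit_model(spec, data, config.mcmc)
        fits[name] = fit
        diags[name] = diag
        fit.to_frame().to_csv(fdir / f"{name}_draws.csv", index=False)
        log.info(
            "fit %s: rhat=%.3f div=%d converged=%s",
            name,
            diag.max_rhat,
            diag.divergences,
            diag.converged,
        )
    return {"fits": fits, "diags": diags, "dir": fdir}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_paths = stage_simulate(config, out)
    prep_paths = stage_preprocess(config, out, sim_paths)
    fit_bundle = stage_fit(config, out, prep_paths)
    fits, diags = fit_bundle["fits"], fit_bundle["diags"]

    report: dict = {
        "config": {
            "generative": dataclasses.asdict(config.generative),
            "gaze_sim": dataclasses.asdict(config.gaze_sim),
            "preprocess": dataclasses.asdict(config.preprocess),
            "mcmc": dataclasses.asdict(config.mcmc),
            "models": list(config.models),
        },
        "priors": yaml.safe_load(serialize_registry(make_paper_models())),
        "summaries": {},
        "diagnostics": {},
    }
    for name, fit in fits.items():
        spec = make_paper_models()[name]
        entries = {}
        if isinstance(spec, (ChanceTestSpec, GradedSpec)):
            s_logit = summarize(fit, "b_Intercept", "logit")
            s_prob = summarize(fit, "b_Intercept", "probability")
            entries["intercept_logit"] = vars(s_logit)
            entries["intercept_prob"] = vars(s_prob)
            entries["phi"] = vars(summarize(fit, "phi"))
        if isinstance(spec, DiscreteSpec):
            for p in fit.to_frame().columns:
                entries[p] = vars(summarize(fit, p))
        report["summaries"][name] = entries
        d = diags[name]
        report["diagnostics"][name] = {
            "max_rhat": d.max_rhat,
            "divergences": d.divergences,
            "converged": d.converged,
        }

    if "bf_null" in fits and "bf_alt1" in fits:
        bf1 = bayes_factor(fits["bf_null"], fits["bf_alt1"], seed=config.mcmc.seed)
        report["bayes_factors"] = {"alt1_vs_null": bf1.bf_alt_over_null}
        if "bf_alt2" in fits:
            bf2 = bayes_factor(fits["bf_null"], fits["bf_alt2"], seed=config.mcmc.seed)
            report["bayes_factors"]["alt2_vs_null"] = bf2.bf_alt_over_null
    if "graded" in fits and "discrete" in fits:
        cmp = loo_compare({"graded": fits["graded"], "discrete": fits["discrete"]})
        report["loo"] = {
            "elpd": cmp.elpd,
            "elpd_diff": cmp.elpd_diff,
            "se_diff": cmp.se_diff,
        }

    # within-participant correlation structure, as in the descriptive checks
    obs = pd.read_csv(prep_paths["windows"])
    wide = obs.pivot_table(
        index="participant_id", columns="trial", values="prop_target", aggfunc="mean"
    )
    wide.columns = [f"trial{c}" for c in wide.columns]
    try:
        r, p = pairwise_correlations(wide)
        report["trial_correlation"] = {
            "r": float(r.iloc[0, 1]),
            "p": float(p.iloc[0, 1]),
        }
    except ValueError:
        report["trial_correlation"] = None

    if "bayes_factors" in report:
        (out / "bf.json").write_text(json.dumps(report["bayes_factors"], indent=2))
    if "loo" in report:
        (out / "loo.json").write_text(json.dumps(report["loo"], indent=2, default=float))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "registry.yaml").write_text(serialize_registry(make_paper_models()))
    _write_text_report(report, out / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["lookmix pipeline report", "=" * 30, ""]
    lines.append("sampler: " + json.dumps(report["config"]["mcmc"]))
    lines.append(
        "exclusions: " + json.dumps(report["config"]["preprocess"])
    )
    lines.append("seed: " + str(report["config"]["generative"]["seed"]))
    lines.append("")
    for model, entries in report["summaries"].items():
        lines.append(f"[{model}]")
        for pname, s in entries.items():
            if isinstance(s, dict) and "mean" in s:
                lines.append(
                    f"  {pname:<22s} {s['mean']:+.3f}  ({s['ci_low']:+.3f}, {s['ci_high']:+.3f})"
                )
        lines.append("")
    if "bayes_factors" in report:
        lines.append("Bayes factors (alt/null): " + json.dumps(report["bayes_factors"]))
    if "loo" in report:
        lines.append("LOO: " + json.dumps(report["loo"]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    per_replicate: pd.DataFrame
    selection_rates: dict
    coverage: dict
    bias: dict
    rmse: dict


def _experiment_config(exp: ExperimentConfig, regime: str, seed: int) -> GenerativeConfig:
    if regime == "graded":
        return GenerativeConfig(
            regime="graded",
            n_participants=exp.n_participants,
            B0=exp.graded_B0,
            sigma=exp.graded_sigma,
            phi=exp.graded_phi,
            seed=seed,
        )
    return GenerativeConfig(
        regime="discrete",
        n_participants=exp.n_participants,
        pi=exp.discrete_pi,
        mu1_logit=exp.discrete_mu1_logit,
        mu2_logit=exp.discrete_mu2_logit,
        phi1=exp.discrete_phi,
        phi2=exp.discrete_phi,
        seed=seed,
    )


def run_recovery_experiment(
    exp: ExperimentConfig, mcmc: McmcConfig | None = None
) -> RecoveryReport:
    """Simulate under each regime, fit both structure models, record the LOO
    winner and (for the generating model) parameter recovery."""
    if mcmc is None:
        mcmc = McmcConfig(chains=2, warmup=400, draws=400, max_retries=0)
    registry = make_paper_models()
    rows = []
    for regime in exp.regimes:
        for rep in range(exp.n_replicates):
            seed = exp.seed + 1000 * rep + (0 if regime == "graded" else 500_000)
            gen = _experiment_config(exp, regime, seed)
            truths = generate_participants(gen)
            props = simulate_proportions(truths, gen, n_obs=exp.n_obs)
            row: dict = {"regime": regime, "replicate": rep, "seed": seed}
            try:
                fg, dg = fit_model(
                    registry["graded"], props, dataclasses.replace(mcmc, seed=seed)
                )
                fd, dd = fit_model(
                    registry["discrete"], props, dataclasses.replace(mcmc, seed=seed + 1)
                )
                cmp = loo_compare({"graded": fg, "discrete": fd})
                row["elpd_diff"] = cmp.elpd_diff
                row["se_diff"] = cmp.se_diff
                row["winner"] = "graded" if cmp.elpd_diff < 0 else "discrete"
                row["failed"] = False
                if regime == "graded":
                    for pname, true_val, key in (
                        ("b_Intercept", gen.B0, "B0"),
                        ("sd_participant_Intercept", gen.sigma, "sigma"),
                        ("phi", gen.phi, "phi"),
                    ):
                        s = summarize(fg, pname)
                        row[f"{key}_true"] = true_val
                        row[f"{key}_est"] = s.mean
                        row[f"{key}_covered"] = s.ci_low <= true_val <= s.ci_high
                else:
                    s = summarize(fd, "pi")
                    row["pi_true"] = gen.pi
                    row["pi_est"] = s.mean
                    row["pi_covered"] = s.ci_low <= gen.pi <= s.ci_high
            except Exception as err:  # fit failures recorded, not fatal
                row["failed"] = True
                row["error"] = str(err)
            rows.append(row)
            log.info("recovery %s rep %d: %s", regime, rep, row.get("winner", "failed"))
    per_rep = pd.DataFrame(rows)

    selection, coverage, bias, rmse = {}, {}, {}, {}
    for regime in exp.regimes:
        sub = per_rep[(per_rep["regime"] == regime) & (~per_rep["failed"])]
        if len(sub) == 0:
            continue
        counts = sub["winner"].value_counts(normalize=True)
        selection[regime] = {k: float(v) for k, v in counts.items()}
        params = ("B0", "sigma", "phi") if regime == "graded" else ("pi",)
        coverage[regime] = {
            p: float(sub[f"{p}_covered"].mean()) for p in params if f"{p}_covered" in sub
        }
        bias[regime] = {
            p: float((sub[f"{p}_est"] - sub[f"{p}_true"]).mean()) for p in params
        }
        rmse[regime] = {
            p: float(np.sqrt(((sub[f"{p}_est"] - sub[f"{p}_true"]) ** 2).mean()))
            for p in params
        }
    return RecoveryReport(per_rep, selection, coverage, bias, rmse)
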
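"""End-to-end analysis pipeline with config, logging, and seed fan-out.

Stages — simulate, fit, compare, correlate — are runnable independently
from serialized intermediates (trial CSVs, draw CSVs, JSON reports).
A single master seed deterministically fans out to per-stage seeds, so
a full run with a fixed master seed reproduces every numeric output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cuebias import synthetic
from cuebias.bridge import bayes_factors, warp3_logml
from cuebias.data import StudyData, accuracy_code, filter_rts, read_trials, summarize_behavior, write_trials
from cuebias.hierarchical import (
    MODEL_SPECS,
    build_model,
    load_draws,
    posterior_predict,
    sample_posterior,
)
from cuebias.plausible import plausible_values_analysis

logger = logging.getLogger("cuebias")

_STAGE_INDEX = {"simulate": 1, "fit": 2, "compare": 3, "correlate": 4}


def stage_seed(master_seed: int, stage: str, salt: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_INDEX[stage], int(salt)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    output_dir: str = "results/run"
    master_seed: int = 0
    # data source: synthetic unless a trials file is given
    trials_csv: str | None = None
    covariates_csv: str | None = None
    rt_unit: str = "s"
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    # fitting
    models: list = field(default_factory=lambda: list(MODEL_SPECS))
    n_chains: int = 3
    n_iter: int = 15000
    burn_in: int = 6000
    rhat_threshold: float = 1.05
    n_posterior_predictive: int = 50
    # model comparison
    bridge_repetitions: int = 6
    bridge_max_iter: int = 20000
    bridge_tol: float = 1e-10
    # plausible values
    plausible_parameters: list = field(default_factory=lambda: ["start_effect", "alpha"])
    plausible_n_draws: int = 3000
    plausible_prior_width: float = 1.0
    plausible_model: str = "M1_start"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def outdir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def _log_seed(stage: str, seed: int, outdir: Path) -> None:
    logger.info("stage %s: effective seed %d", stage, seed)
    log = outdir / "seeds.json"
    entries = json.loads(log.read_text()) if log.exists() else {}
    entries[stage] = seed
    log.write_text(json.dumps(entries, indent=2))


def cmd_simulate(config: RunConfig):
    """Generate a synthetic study and write trial/covariate/truth CSVs."""
    outdir = config.outdir()
    seed = stage_seed(config.master_seed, "simulate")
    _log_seed("simulate", seed, outdir)
    cfg = synthetic.SyntheticConfig(**{**config.synthetic, "seed": seed})
    data, participants = synthetic.generate_study(cfg)
    write_trials(data, outdir / "trials.csv", outdir / "covariates.csv")
    participants.to_csv(outdir / "truth.csv")
    (outdir / "synthetic_config.json").write_text(
        json.dumps(synthetic.config_dict(cfg), indent=2)
    )
    logger.info("wrote %d trials for %d participants", len(data), cfg.n_participants)
    return data, participants


def load_study(config: RunConfig) -> StudyData:
    """Load the study (from files if given, else the simulated CSVs)."""
    outdir = config.outdir()
    trials = config.trials_csv or outdir / "trials.csv"
    cov = config.covariates_csv or outdir / "covariates.csv"
    cov = cov if Path(cov).exists() else None
    return read_trials(trials, cov, rt_unit=config.rt_unit)


def prepare_study(config: RunConfig):
    """Read, filter and accuracy-code the study; write retention/behavior reports."""
    outdir = config.outdir()
    data = load_study(config)
    filtered, report = filter_rts(data)
    report["per_participant"].to_csv(outdir / "retention.csv")
    (outdir / "retention.json").write_text(
        json.dumps({k: v for k, v in report.items() if k != "per_participant"}, indent=2)
    )
    coded = accuracy_code(filtered)
    summary = summarize_behavior(coded)
    summary.to_frame().to_csv(outdir / "behavior_summary.csv", index=False)
    summary.to_json(outdir / "behavior_summary.json")
    logger.info(
        "retained %.2f%% of trials on average (range %.1f-%.1f%%)",
        report["mean_retention_pct"],
        report["min_retention_pct"],
        report["max_retention_pct"],
    )
    return coded, report, summary


def cmd_fit(config: RunConfig, data: StudyData | None = None):
    """Fit every configured model; write draws, R-hat report, predictives."""
    outdir = config.outdir()
    if data is None:
        data, _, _ = prepare_study(config)
    fits = {}
    rhat_report = {}
    for i, spec in enumerate(config.models):
        seed = stage_seed(config.master_seed, "fit", i)
        _log_seed(f"fit:{spec}", seed, outdir)
        model = build_model(spec, data)
        draws = sample_posterior(
            model,
            n_chains=config.n_chains,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=seed,
        )
        draws.save(outdir / f"draws_{spec}.csv")
        rh = draws.rhat()
        rhat_report[spec] = rh.to_dict()
        if (rh > config.rhat_threshold).any():
            worst = rh.idxmax()
            warnings.warn(
                f"{spec}: R-hat above {config.rhat_threshold} "
                f"(worst {worst} = {rh.max():.3f}); treat estimates with caution"
            )
        if config.n_posterior_predictive > 0:
            ppc = posterior_predict(
                draws, data, n_rep=config.n_posterior_predictive,
                seed=stage_seed(config.master_seed, "fit", 100 + i),
            )
            _write_ppc(ppc, outdir, spec)
        fits[spec] = draws
    (outdir / "rhat.json").write_text(json.dumps(rhat_report, indent=2))
    (outdir / "fit_config.json").write_text(
        json.dumps(
            {k: v for k, v in asdict(config).items()
             if k in ("models", "n_chains", "n_iter", "burn_in", "master_seed")},
            indent=2,
        )
    )
    return fits


def _write_ppc(ppc: dict, outdir: Path, spec: str) -> None:
    tables = []
    for key in ("observed", "mean", "band_low", "band_high"):
        t = ppc[key].copy()
        t["summary"] = key
        tables.append(t.reset_index())
    pd.concat(tables, ignore_index=True).to_csv(
        outdir / f"posterior_predictive_{spec}.csv", index=False
    )
    try:
        _plot_ppc(ppc, outdir / f"posterior_predictive_{spec}.png")
    except Exception as err:  # plotting must never sink a fit
        logger.warning("posterior predictive plot failed: %s", err)


def _plot_ppc(ppc: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qcols = [c for c in ppc["observed"].columns if c.startswith("q")]
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharey=True)
    labels = {1: "neutral", 2: "valid", 3: "invalid"}
    probs = [int(c[1:]) / 100 for c in qcols]
    for ax, cond in zip(axes, (1, 2, 3)):
        ax.fill_between(
            probs,
            ppc["band_low"].loc[cond, qcols],
            ppc["band_high"].loc[cond, qcols],
            alpha=0.3,
            label="95% predictive band",
        )
        ax.plot(probs, ppc["mean"].loc[cond, qcols], "-", label="predicted")
        ax.plot(probs, ppc["observed"].loc[cond, qcols], "ko", label="observed")
        acc_o = ppc["observed"].loc[cond, "accuracy"]
        acc_m = ppc["mean"].loc[cond, "accuracy"]
        ax.set_title(f"{labels[cond]} (acc {acc_o:.2f} obs / {acc_m:.2f} pred)")
        ax.set_xlabel("RT quantile")
    axes[0].set_ylabel("correct RT (s)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cmd_compare(config: RunConfig, data: StudyData | None = None, fits: dict | None = None):
    """Warp-III log marginal likelihoods and pairwise log Bayes factors."""
    outdir = config.outdir()
    if data is None:
        data, _, _ = prepare_study(config)
    estimates = []
    for i, spec in enumerate(config.models):
        model = build_model(spec, data)
        if fits and spec in fits:
            draws = fits[spec]
        else:
            draws = load_draws(model, outdir / f"draws_{spec}.csv")
        seed = stage_seed(config.master_seed, "compare", i)
        _log_seed(f"compare:{spec}", seed, outdir)
        est = warp3_logml(
            draws.flat(),
            model.log_posterior_batch,
            model_id=spec,
            n_repetitions=config.bridge_repetitions,
            max_iter=config.bridge_max_iter,
            tol=config.bridge_tol,
            seed=seed,
        )
        logger.info(
            "%s: logml %.2f (rep SD %.3f)", spec, est.logml, est.repetition_sd
        )
        estimates.append(est)
    table = bayes_factors(estimates)
    report = table.to_dict()
    report["per_repetition"] = {e.model_id: e.repetitions.tolist() for e in estimates}
    report["converged"] = {e.model_id: e.converged for e in estimates}
    (outdir / "model_comparison.json").write_text(json.dumps(report, indent=2))
    return table, estimates


def cmd_correlate(config: RunConfig, data: StudyData | None = None, fits: dict | None = None):
    """Plausible-values correlation of fitted parameters with the trait score."""
    outdir = config.outdir()
    if data is None:
        data, _, _ = prepare_study(config)
    spec = config.plausible_model
    model = build_model(spec, data)
    if fits and spec in fits:
        draws = fits[spec]
    else:
        draws = load_draws(model, outdir / f"draws_{spec}.csv")
    trait = data.covariates.loc[model.participants, "aq"].to_numpy(float)
    results = {}
    for i, param in enumerate(config.plausible_parameters):
        seed = stage_seed(config.master_seed, "correlate", i)
        _log_seed(f"correlate:{param}", seed, outdir)
        pc, post = plausible_values_analysis(
            draws, param, trait,
            n_draws=config.plausible_n_draws,
            prior_width=config.plausible_prior_width,
            seed=seed,
        )
        results[param] = {
            "mean_plausible_r": float(np.mean(pc.r)),
            "n_draws": int(len(pc.r)),
            "n_dropped": pc.n_dropped,
            "ci_95": [post.ci_low, post.ci_high],
            "bayes_p": post.bayes_p,
            "p_above_zero": post.p_above_zero,
            "p_below_zero": post.p_below_zero,
            "posterior_mean_rho": post.mean(),
        }
        logger.info(
            "%s vs trait: CI [%.3f, %.3f], Bayesian p = %.3f",
            param, post.ci_low, post.ci_high, post.bayes_p,
        )
        try:
            _plot_plausible(
                draws, param, trait, pc, post, outdir / f"plausible_{spec}_{param}.png"
            )
        except Exception as err:
            logger.warning("plausible-values plot failed: %s", err)
    (outdir / "plausible_values.json").write_text(json.dumps(results, indent=2))
    return results


def _plot_plausible(draws, param, trait, pc, post, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    post_means = draws.participant_matrix(param).mean(axis=0)
    axes[0].plot(trait, post_means, "o", ms=3, alpha=0.6)
    axes[0].set_xlabel("AQ score")
    axes[0].set_ylabel(f"posterior mean {param}")
    axes[1].hist(pc.r, bins=40, density=True)
    axes[1].set_xlabel("plausible correlation r")
    axes[2].plot(post.grid, post.density)
    axes[2].axvline(0, color="k", lw=0.5)
    axes[2].fill_between(
        post.grid, post.density, where=(post.grid >= post.ci_low) & (post.grid <= post.ci_high),
        alpha=0.3,
    )
    axes[2].set_xlabel(r"population correlation $\rho$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cmd_report(config: RunConfig) -> dict:
    """Aggregate the run's JSON artifacts into one report (report.json)."""
    outdir = config.outdir()
    report: dict = {}
    for name in ("retention", "behavior_summary", "rhat", "model_comparison",
                 "plausible_values", "seeds"):
        path = outdir / f"{name}.json"
        if path.exists():
            report[name] = json.loads(path.read_text())
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_pipeline(config: RunConfig):
    """simulate (if no input files) -> fit -> compare -> correlate."""
    if config.trials_csv is None:
        cmd_simulate(config)
    data, report, summary = prepare_study(config)
    fits = cmd_fit(config, data)
    out = {"behavior": summary, "retention": report, "fits": fits}
    if len(config.models) >= 2:
        out["comparison"], out["logml"] = cmd_compare(config, data, fits)
    out["plausible"] = cmd_correlate(config, data, fits)
    out["report"] = cmd_report(config)
    return out
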
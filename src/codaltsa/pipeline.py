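"""Orchestration: tie the stages into one reproducible analysis run.

Stages (each reads/writes plain CSV + JSON side-cars in the run directory):
``simulate -> prepare -> events -> fit -> phtest -> substitute -> report``.
Worker counts are conserved across stages; every exclusion carries a
reason code so the cohort flow can be reconstructed from the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accel_prep import ValidityRules, prepare_workers
from .compositions import DomainComposition, compositional_mean
from .register import outcomes_from_register
from .substitution import default_grid, plot_substitution, substitution_curve
from .survival import (
    build_model_matrix,
    cox_fit,
    grambsch_therneau,
    ses_sensitivity,
    wald_table,
)
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "analyze_frames", "stage_simulate",
           "sample_compositional_mean", "recover_reallocation_hrs"]


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    outdir: str = "run"
    days_path: str | None = None        # default: <outdir>/days.csv
    bed_path: str | None = None
    covariates_path: str | None = None
    register_path: str | None = None
    composition_mode: str = "separate"  # or "whole_day"
    work_min_wear: float = 240.0
    leisure_frac_of_avg: float = 0.75
    bed_min: float = 240.0
    delta: float = 0.5                  # zero-replacement minutes
    min_run: int = 6
    horizon: int = 212
    event_timing: str = "start"
    ties: str = "efron"
    ses_handling: str = "none"          # none | adjust | stratify
    grid_lo: int = -30
    grid_hi: int = 30
    grid_step: int = 5
    alpha: float = 0.05
    seed: int = 1

    def path(self, name: str) -> Path:
        override = getattr(self, f"{name}_path", None)
        return Path(override) if override else Path(self.outdir) / f"{name}.csv"

    @property
    def rules(self) -> ValidityRules:
        return ValidityRules(self.work_min_wear, self.leisure_frac_of_avg, self.bed_min)

    @property
    def grid(self) -> list[float]:
        return default_grid(self.grid_lo, self.grid_hi, self.grid_step)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


# ---------------------------------------------------------------------------
# In-memory analysis core (the stages wrap file I/O around this)


def analyze_frames(
    days_df: pd.DataFrame,
    bed_df: pd.DataFrame,
    covariates_df: pd.DataFrame,
    register_df: pd.DataFrame,
    cfg: RunConfig | None = None,
    include_ses: bool = False,
    with_ph_test: bool = True,
    with_curves: bool = True,
) -> dict:
    """Run prepare -> events -> fit (-> phtest -> substitution) in memory."""
    cfg = cfg or RunConfig()
    workers, excl_prep = prepare_workers(
        days_df, bed_df, covariates_df, rules=cfg.rules, delta=cfg.delta
    )
    outcomes = outcomes_from_register(
        register_df, workers, min_run=cfg.min_run, horizon=cfg.horizon,
        event_timing=cfg.event_timing,
    )
    X, excl_cov = build_model_matrix(
        workers, include_ses=include_ses, delta=cfg.delta,
        composition_mode=cfg.composition_mode,
    )
    fit = cox_fit(X, outcomes, ties=cfg.ties)
    out = {
        "workers": workers,
        "exclusions_prepare": excl_prep,
        "exclusions_covariates": excl_cov,
        "outcomes": outcomes,
        "X": X,
        "fit": fit,
    }
    if with_ph_test:
        out["ph_test"] = grambsch_therneau(fit, X, outcomes)
    if with_curves:
        out["means"], out["curves"] = {}, {}
        for domain in ("work", "leisure"):
            out["means"][domain] = _sample_mean(workers, domain)
            out["curves"][domain] = substitution_curve(
                fit, out["means"][domain], "mvpa", cfg.grid, cfg.alpha
            )
    return out


def sample_compositional_mean(workers: pd.DataFrame, domain: str) -> DomainComposition:
    """Sample compositional mean closed to the cohort's mean domain duration."""
    from .compositions import PART_ORDER

    cols = [f"{domain}_{p}" for p in PART_ORDER[domain]]
    mat = workers[cols].to_numpy(dtype=float)
    kappa = float(mat.sum(axis=1).mean())
    return DomainComposition(domain, tuple(compositional_mean(mat, kappa)))


_sample_mean = sample_compositional_mean


def recover_reallocation_hrs(
    gen_config: GeneratorConfig | None = None,
    seeds=range(1, 51),
    cfg: RunConfig | None = None,
    reallocation_minutes: float = 20.0,
) -> pd.DataFrame:
    """End-to-end parameter recovery across generated cohorts.

    For each seed: generate a cohort, run prepare -> events -> fit, and
    predict the hazard ratio of reallocating ``reallocation_minutes`` into
    MVPA at the sample compositional mean of each domain. Returns one row
    per seed with the recovered hazard ratios, the event fraction, and the
    censored fraction among workers without an event.
    """
    from .substitution import predict_hr, reallocate

    gen_config = gen_config or GeneratorConfig()
    rows = []
    for seed in seeds:
        cohort = generate_cohort(gen_config, seed=seed)
        res = analyze_frames(
            cohort.days, cohort.bed, cohort.covariates, cohort.register,
            cfg=cfg, with_ph_test=False, with_curves=False,
        )
        fit, outcomes, workers = res["fit"], res["outcomes"], res["workers"]
        non_event = outcomes[~outcomes["event"]]
        row = {
            "seed": seed,
            "event_fraction": float(outcomes["event"].mean()),
            "censored_fraction_non_event": float(
                (non_event["censor_reason"] != "admin_end").mean()
            ),
        }
        for domain in ("work", "leisure"):
            base = _sample_mean(workers, domain)
            new = reallocate(base, "mvpa", reallocation_minutes).new_comp
            row[f"hr_{domain}"] = predict_hr(fit, base, new)[0]
            row[f"{domain}_mvpa_mean"] = base.minutes[0]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-based stages


def stage_simulate(cfg: RunConfig, gen_config: GeneratorConfig | None = None) -> dict:
    cohort = generate_cohort(gen_config or GeneratorConfig(), seed=cfg.seed)
    paths = cohort.write(cfg.outdir)
    logger.info("simulated cohort written to %s", cfg.outdir)
    return {str(k): str(v) for k, v in paths.items()}


def _read_inputs(cfg: RunConfig):
    days = pd.read_csv(cfg.path("days"))
    bed = pd.read_csv(cfg.path("bed"))
    cov = pd.read_csv(cfg.path("covariates"))
    return days, bed, cov


def stage_prepare(cfg: RunConfig) -> dict:
    days, bed, cov = _read_inputs(cfg)
    workers, exclusions = prepare_workers(days, bed, cov, rules=cfg.rules, delta=cfg.delta)
    out = Path(cfg.outdir)
    workers.to_csv(out / "workers.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    n_in = days["worker_id"].nunique()
    if len(workers) + len(exclusions) != n_in:
        raise RuntimeError("worker accounting violated in prepare")
    return {"n_input": int(n_in), "n_included": len(workers), "n_excluded": len(exclusions)}


def stage_events(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    workers = pd.read_csv(out / "workers.csv")
    register = pd.read_csv(cfg.path("register"))
    outcomes = outcomes_from_register(
        register, workers, min_run=cfg.min_run, horizon=cfg.horizon,
        event_timing=cfg.event_timing,
    )
    outcomes.to_csv(out / "outcomes.csv", index=False)
    counts = outcomes["censor_reason"].value_counts().to_dict()
    return {
        "n_events": int(outcomes["event"].sum()),
        "n_workers": len(outcomes),
        "censor_reasons": {str(k): int(v) for k, v in counts.items()},
    }


def stage_fit(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    workers = pd.read_csv(out / "workers.csv")
    outcomes = pd.read_csv(out / "outcomes.csv")
    include_ses = cfg.ses_handling == "adjust"
    X, excl = build_model_matrix(
        workers, include_ses=include_ses, delta=cfg.delta,
        composition_mode=cfg.composition_mode,
    )
    excl.to_csv(out / "exclusions_covariates.csv", index=False)
    fit = cox_fit(X, outcomes, ties=cfg.ties)
    wald_table(fit).to_csv(out / "fit.csv", index=False)
    meta = {
        "loglik": fit.loglik,
        "null_loglik": fit.null_loglik,
        "n": fit.n,
        "n_events": fit.n_events,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "ties_method": fit.ties_method,
        "include_ses": include_ses,
    }
    _write_json(out / "fit_meta.json", meta)
    if cfg.ses_handling == "stratify":
        fits = ses_sensitivity(workers, outcomes, ties=cfg.ties)
        for cat, f in fits["stratified"].items():
            if f is not None:
                wald_table(f).to_csv(out / f"fit_ses_{cat}.csv", index=False)
        wald_table(fits["adjusted"]).to_csv(out / "fit_ses_adjusted.csv", index=False)
    return meta


def stage_phtest(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    workers = pd.read_csv(out / "workers.csv")
    outcomes = pd.read_csv(out / "outcomes.csv")
    X, _ = build_model_matrix(
        workers, include_ses=cfg.ses_handling == "adjust", delta=cfg.delta,
        composition_mode=cfg.composition_mode,
    )
    fit = cox_fit(X, outcomes, ties=cfg.ties)
    ph = grambsch_therneau(fit, X, outcomes)
    rows = [
        {"term": name, "chi_square": c, "df": df_, "p": p}
        for name, (c, df_, p) in ph.per_covariate.items()
    ]
    rows.append(
        {
            "term": "GLOBAL",
            "chi_square": ph.global_test[0],
            "df": ph.global_test[1],
            "p": ph.global_test[2],
        }
    )
    pd.DataFrame(rows).to_csv(out / "ph_test.csv", index=False)
    return {"global_p": ph.global_test[2], "transform": ph.time_transform}


def stage_substitute(cfg: RunConfig, plot: bool = False) -> dict:
    out = Path(cfg.outdir)
    workers = pd.read_csv(out / "workers.csv")
    outcomes = pd.read_csv(out / "outcomes.csv")
    if cfg.composition_mode != "separate":
        raise ValueError("substitution curves require the separate-domain composition mode")
    X, _ = build_model_matrix(workers, delta=cfg.delta)
    fit = cox_fit(X, outcomes, ties=cfg.ties)
    curves = []
    for domain in ("work", "leisure"):
        base = _sample_mean(workers, domain)
        curves.append(substitution_curve(fit, base, "mvpa", cfg.grid, cfg.alpha))
    df = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    df.to_csv(out / "substitution.csv", index=False)
    if plot:
        plot_substitution(curves, out / "substitution.png")
    return {"n_rows": len(df), "domains": [c.domain for c in curves]}


def stage_report(cfg: RunConfig, stage_logs: dict | None = None) -> dict:
    out = Path(cfg.outdir)
    report: dict = {"version": __version__, "config": asdict(cfg)}
    if stage_logs:
        report["stages"] = stage_logs
    outcomes_path = out / "outcomes.csv"
    if outcomes_path.exists():
        outcomes = pd.read_csv(outcomes_path)
        ev = outcomes[outcomes["event"]]
        report["cohort"] = {
            "n": len(outcomes),
            "n_events": int(outcomes["event"].sum()),
            "event_fraction": float(outcomes["event"].mean()),
            "median_event_week": float(ev["time_weeks"].median()) if len(ev) else None,
            "censor_reasons": {
                str(k): int(v)
                for k, v in outcomes["censor_reason"].value_counts().items()
            },
        }
    sub_path = out / "substitution.csv"
    if sub_path.exists():
        sub = pd.read_csv(sub_path)
        sel = sub[sub["delta_min"].isin([-20.0, 20.0])]
        report["reallocation_hr"] = [
            {k: row[k] for k in ("domain", "delta_min", "hr", "ci_low", "ci_high")}
            for _, row in sel.iterrows()
        ]
    _write_json(out / "report.json", report)
    return report


def run_all(
    cfg: RunConfig,
    gen_config: GeneratorConfig | None = None,
    simulate: bool = False,
    plot: bool = False,
) -> dict:
    """Execute every stage in order; halts with the stage name on error."""
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    logs: dict = {}
    stages = ([("simulate", lambda: stage_simulate(cfg, gen_config))] if simulate else []) + [
        ("prepare", lambda: stage_prepare(cfg)),
        ("events", lambda: stage_events(cfg)),
        ("fit", lambda: stage_fit(cfg)),
        ("phtest", lambda: stage_phtest(cfg)),
        ("substitute", lambda: stage_substitute(cfg, plot=plot)),
    ]
    for name, fn in stages:
        try:
            logs[name] = fn()
            logger.info("stage %s done: %s", name, logs[name])
        except Exception as err:
            logger.error("stage %s failed: %s", name, err)
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
    report = stage_report(cfg, logs)
    _write_json(Path(cfg.outdir) / "run_log.json", logs)
    return report
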
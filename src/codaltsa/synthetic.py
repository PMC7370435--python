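"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 929-worker accelerometer cohort followed for 212
weeks in a weekly benefit register. Per worker it draws a work-domain and a
leisure-domain time-use composition (Dirichlet around the published
compositional means, scaled to truncated-normal domain durations), ordinary
confounders, and a weekly event process whose log hazard is linear in the
worker's pivot ilr coordinates. The planted effect sizes are expressed on
the interpretable scale — the hazard ratio of reallocating 20 minutes into
MVPA — and inverted into first-pivot coefficients, so the whole pipeline
can be checked for parameter recovery end to end. Day-level tables with raw
activity classes, wear times, occasional invalid days and non-workdays
exercise the preparation rules; the register series carry the planted
sickness runs, decoy five-week spells (the shortest spell the register can
hold, which must never count as an event) and censoring codes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .compositions import (
    DomainComposition,
    LEISURE_PART_ORDER,
    WORK_PART_ORDER,
    ilr,
    sbp_basis,
)
from .substitution import reallocate
from .survival import (
    CONFOUNDER_COLUMNS,
    LEISURE_ILR_COLUMNS,
    WORK_ILR_COLUMNS,
)

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "Cohort", "plant_betas", "generate_cohort", "write_fixture_suite"]

#: Fixed split of each behavior part into raw accelerometer classes.
#: Work MVPA contains no cycling (occupational cycling is not generated).
_WORK_MVPA_SPLIT = {"walking_fast": 0.75, "running": 0.05, "stair_climbing": 0.20}
_LEISURE_MVPA_SPLIT = {
    "walking_fast": 0.55,
    "running": 0.10,
    "stair_climbing": 0.10,
    "cycling": 0.25,
}
_LIPA_SPLIT = {"moving": 0.65, "walking_slow": 0.35}

_CENSOR_REASONS = ("emigrated", "died", "early_retirement", "ordinary_retirement", "pregnancy")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort (defaults are calibrated
    to the published descriptive statistics)."""

    n_workers: int = 929
    seed: int = 0
    # compositional means (minutes); work sums to 451, leisure to 891
    work_mean_minutes: tuple = (64.0, 176.0, 137.0, 74.0)
    leisure_mean_minutes: tuple = (33.0, 311.0, 77.0, 41.0, 429.0)
    concentration: float = 100.0  # Dirichlet precision per domain
    # domain durations (minutes/day), truncated normals
    work_total_mean: float = 451.0
    work_total_sd: float = 80.0
    work_total_min: float = 223.0
    leisure_total_mean: float = 892.0
    leisure_total_sd: float = 109.0
    leisure_total_min: float = 536.0
    # covariates
    age_mean: float = 44.9
    age_sd: float = 9.7
    female_prob: float = 0.45
    bmi_mean: float = 27.1
    bmi_sd: float = 4.8
    smoker_prob: float = 0.30
    lifting_probs: tuple = (0.05, 0.10, 0.20, 0.30, 0.25, 0.10)  # mean 3.9
    ses_probs: tuple = (0.19, 0.39, 0.42)
    ses_missing_prob: float = 0.127
    # hazard / effects
    target_incidence: float = 0.21
    horizon_weeks: int = 212
    min_run_weeks: int = 6
    work_hr_target: float = 1.15     # HR per +20 min work MVPA reallocation
    leisure_hr_target: float = 0.80  # HR per +20 min leisure MVPA reallocation
    reallocation_minutes: float = 20.0
    extra_betas: dict = field(default_factory=dict)  # column -> coefficient
    # censoring among workers without an event; probabilities sum to 0.05
    censor_reason_probs: dict = field(
        default_factory=lambda: {
            "emigrated": 0.015,
            "pregnancy": 0.015,
            "early_retirement": 0.008,
            "ordinary_retirement": 0.009,
            "died": 0.003,
        }
    )
    decoy_5week_spell_prob: float = 0.10
    maternity_lead_weeks: int = 35
    series_length: int = 252
    # day-level structure
    days_per_worker: int = 4
    day_noise_sd: float = 0.05       # lognormal sigma per part per day
    invalid_day_prob: float = 0.08
    non_workday_prob: float = 0.05

    def validate(self):
        if abs(sum(self.work_mean_minutes) - self.work_total_mean) > 1.0:
            raise ValueError("work part means must sum to the mean work duration")
        if abs(sum(self.leisure_mean_minutes) - self.leisure_total_mean) > 1.5:
            raise ValueError("leisure part means must sum to the mean leisure duration")
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        total_censor = sum(self.censor_reason_probs.values())
        probs = list(self.censor_reason_probs.values()) + [
            self.ses_missing_prob,
            self.female_prob,
            self.smoker_prob,
            total_censor,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        return self


@dataclass
class Cohort:
    """One generated cohort: the three pipeline input tables, the sparse
    register table, and the generating truth."""

    days: pd.DataFrame
    bed: pd.DataFrame
    covariates: pd.DataFrame
    register: pd.DataFrame
    truth: dict

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("days", self.days),
            ("bed", self.bed),
            ("covariates", self.covariates),
            ("register", self.register),
        ]:
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        truth = {
            k: v for k, v in self.truth.items() if np.isscalar(v) or isinstance(v, (list, dict))
        }
        truth["betas"] = {k: float(v) for k, v in self.truth["betas"].items()}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, default=float))
        paths["truth"] = outdir / "truth.json"
        return paths


def plant_betas(config: GeneratorConfig) -> pd.Series:
    """Coefficient vector realizing the configured reallocation hazard ratios.

    For each domain the first-pivot coefficient is ``ln(target HR) / dz1``
    where ``dz1`` is the first-ilr change produced by reallocating
    ``reallocation_minutes`` into MVPA at the configured mean composition;
    by construction the predicted HR at that reallocation equals the target
    exactly before any fitting. All other coefficients default to zero
    (overridable through ``extra_betas``).
    """
    if config.work_hr_target <= 0 or config.leisure_hr_target <= 0:
        raise ValueError("target hazard ratios must be positive")
    index = WORK_ILR_COLUMNS + LEISURE_ILR_COLUMNS + CONFOUNDER_COLUMNS
    betas = pd.Series(0.0, index=index)
    for domain, parts, target, col in [
        ("work", config.work_mean_minutes, config.work_hr_target, WORK_ILR_COLUMNS[0]),
        ("leisure", config.leisure_mean_minutes, config.leisure_hr_target, LEISURE_ILR_COLUMNS[0]),
    ]:
        base = DomainComposition(domain, tuple(parts))
        new = reallocate(base, "mvpa", config.reallocation_minutes).new_comp
        basis = sbp_basis(base.n_parts)
        dz1 = float(ilr(new.values, basis)[0] - ilr(base.values, basis)[0])
        if dz1 == 0:
            raise ValueError("zero first-ilr change; cannot invert the target HR")
        betas[col] = np.log(target) / dz1
    for col, val in config.extra_betas.items():
        betas[col] = float(val)
    return betas


def _inv_digamma(y: np.ndarray, iters: int = 20) -> np.ndarray:
    """Inverse of the digamma function (Minka's initialization + Newton)."""
    from scipy.special import digamma, polygamma

    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore"):  # unused branch may divide by zero
        x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(iters):
        x = x - (digamma(x) - y) / polygamma(1, x)
    return x


def _dirichlet_alpha(props: np.ndarray, precision: float) -> np.ndarray:
    """Dirichlet parameters whose *compositional* mean equals ``props``.

    The published part means are compositional (geometric) means, so the
    generator matches them on that scale: solve for alpha with
    ``sum(alpha) = precision`` such that ``exp(psi(alpha_i))`` closed to 1
    equals ``props`` (then ``E[ln p_i] - E[ln p_j] = ln props_i - ln
    props_j``, making the sample compositional mean converge to ``props``).
    """
    from scipy.optimize import brentq

    logm = np.log(np.asarray(props, dtype=float))

    def excess(c):
        return _inv_digamma(c + logm).sum() - precision

    c = brentq(excess, -20.0, 30.0, xtol=1e-12)
    return _inv_digamma(c + logm)


def _trunc_normal(rng, mean, sd, low, size):
    x = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = x < low
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("truncated-normal resampling failed")  # pragma: no cover


def _calibrate_lambda0(eta: np.ndarray, target: float, detect_weeks: int) -> float:
    """Baseline weekly hazard such that the mean probability of an event
    start within ``detect_weeks`` equals ``target``."""

    def detectable_fraction(lam):
        p = -np.expm1(-lam * np.exp(eta))
        return np.mean(-np.expm1(detect_weeks * np.log1p(-p))) - target

    try:
        return optimize.brentq(detectable_fraction, 1e-10, 0.5, xtol=1e-14)
    except ValueError as err:
        raise RuntimeError(f"baseline-hazard calibration failed: {err}") from err


def _split_classes(parts: np.ndarray, domain: str) -> dict:
    """Part minutes (..., 4) -> raw-class minutes for one domain."""
    mvpa, sed, stand, lipa = (parts[..., i] for i in range(4))
    split = _LEISURE_MVPA_SPLIT if domain == "leisure" else _WORK_MVPA_SPLIT
    out = {
        "sedentary": sed,
        "standing_still": stand,
        "moving": lipa * _LIPA_SPLIT["moving"],
        "walking_slow": lipa * _LIPA_SPLIT["walking_slow"],
        "walking_fast": mvpa * split.get("walking_fast", 0.0),
        "running": mvpa * split.get("running", 0.0),
        "stair_climbing": mvpa * split.get("stair_climbing", 0.0),
        "cycling": mvpa * split.get("cycling", 0.0),
    }
    return out


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate one cohort; fully reproducible from the seed."""
    config = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_workers
    ids = np.arange(1, n + 1)

    # ---- worker-level truth: domain totals and compositions
    work_total = _trunc_normal(rng, config.work_total_mean, config.work_total_sd,
                               config.work_total_min, n)
    leis_total = _trunc_normal(rng, config.leisure_total_mean, config.leisure_total_sd,
                               config.leisure_total_min, n)
    work_mean = np.asarray(config.work_mean_minutes)
    leis_mean = np.asarray(config.leisure_mean_minutes)
    work_props = rng.dirichlet(_dirichlet_alpha(work_mean / work_mean.sum(), config.concentration), n)
    leis_props = rng.dirichlet(_dirichlet_alpha(leis_mean / leis_mean.sum(), config.concentration), n)
    work_parts = work_props * work_total[:, None]
    leis_parts = leis_props * leis_total[:, None]

    # ---- covariates
    age = _trunc_normal(rng, config.age_mean, config.age_sd, 18.0, n)
    female = rng.random(n) < config.female_prob
    bmi = _trunc_normal(rng, config.bmi_mean, config.bmi_sd, 15.0, n)
    smoker = rng.random(n) < config.smoker_prob
    lifting = rng.choice(np.arange(1, 7), size=n, p=np.asarray(config.lifting_probs))
    ses = rng.choice(
        ["white_collar", "blue_collar_skilled", "blue_collar_unskilled"],
        size=n,
        p=np.asarray(config.ses_probs),
    ).astype(object)
    ses[rng.random(n) < config.ses_missing_prob] = np.nan

    # ---- linear predictor and weekly event process
    betas = plant_betas(config)
    wb = sbp_basis(4).contrast_matrix
    lb = sbp_basis(5).contrast_matrix
    z_work = np.log(work_props) @ wb.T
    z_leis = np.log(leis_props) @ lb.T
    conf = np.column_stack([age, female.astype(float), bmi, smoker.astype(float), lifting])
    eta = (
        z_work @ betas[WORK_ILR_COLUMNS].to_numpy()
        + z_leis @ betas[LEISURE_ILR_COLUMNS].to_numpy()
        + conf @ betas[CONFOUNDER_COLUMNS].to_numpy()
    )
    detect_weeks = config.horizon_weeks - config.min_run_weeks + 1
    lambda0 = _calibrate_lambda0(eta, config.target_incidence, detect_weeks)
    p_week = -np.expm1(-lambda0 * np.exp(eta))
    u = rng.random(n)
    event_week = np.ceil(np.log1p(-u) / np.log1p(-p_week)).astype(int)
    event = event_week <= detect_weeks

    # ---- censoring among non-event workers (total probability ~5%)
    total_censor = sum(config.censor_reason_probs.values())
    censored = (~event) & (rng.random(n) < total_censor)
    censor_week = rng.integers(1, config.horizon_weeks + 1, size=n)
    reasons = np.asarray(list(config.censor_reason_probs))
    probs = np.asarray([config.censor_reason_probs[r] for r in reasons])
    probs = probs / probs.sum()
    male_probs = probs.copy()
    male_probs[reasons == "pregnancy"] = 0.0
    male_probs /= male_probs.sum()
    censor_reason = np.full(n, "none", dtype=object)
    for i in np.flatnonzero(censored):
        censor_reason[i] = rng.choice(reasons, p=probs if female[i] else male_probs)

    # ---- decoy 5-week spells among non-event workers
    decoy = (~event) & (rng.random(n) < config.decoy_5week_spell_prob)
    decoy_start = rng.integers(1, config.horizon_weeks - 4, size=n)

    # ---- sparse register rows
    run_extra = rng.geometric(0.3, size=n) - 1  # extra sickness weeks past the minimum
    rows_w, rows_week, rows_code = [], [], []

    def emit(wid, week, code):
        rows_w.append(wid)
        rows_week.append(int(week))
        rows_code.append(code)

    for i in range(n):
        wid = ids[i]
        if event[i]:
            start = int(event_week[i])
            stop = min(start + config.min_run_weeks + int(run_extra[i]) - 1, config.series_length)
            for w in range(start, stop + 1):
                emit(wid, w, "sickness")
            continue
        if decoy[i]:
            for w in range(int(decoy_start[i]), int(decoy_start[i]) + 5):
                emit(wid, w, "sickness")
        if censored[i]:
            reason = censor_reason[i]
            if reason == "pregnancy":
                emit(wid, int(censor_week[i]) + config.maternity_lead_weeks, "maternity_start")
            else:
                emit(wid, int(censor_week[i]), reason)
    register = pd.DataFrame({"worker_id": rows_w, "week": rows_week, "code": rows_code})
    # a censoring code silences any decoy sickness in its week
    register = register.drop_duplicates(subset=["worker_id", "week"], keep="last")

    # ---- day-level tables
    days = config.days_per_worker
    shape2 = (n, days)
    work_day = work_parts[:, None, :] * rng.lognormal(0.0, config.day_noise_sd, (n, days, 4))
    leis_day = leis_parts[:, None, :4] * rng.lognormal(0.0, config.day_noise_sd, (n, days, 4))
    bed_day = leis_parts[:, None, 4] * rng.lognormal(0.0, config.day_noise_sd, shape2)

    is_workday = rng.random(shape2) >= config.non_workday_prob
    invalid = (rng.random(shape2) < config.invalid_day_prob) & is_workday
    mechanism = rng.integers(0, 3, size=shape2)
    # short work period (< 4 h wear)
    m0 = invalid & (mechanism == 0)
    short_total = rng.uniform(120.0, 230.0, shape2)
    work_sum = work_day.sum(axis=2)
    work_day[m0] *= (short_total[m0] / work_sum[m0])[:, None]
    # short leisure period (< 75% of the average leisure wear)
    m1 = invalid & (mechanism == 1)
    leis_scale = rng.uniform(0.4, 0.7, shape2)
    leis_day[m1] *= leis_scale[m1][:, None]
    # short time in bed (< 4 h)
    m2 = invalid & (mechanism == 2)
    bed_day[m2] = rng.uniform(100.0, 230.0, shape2)[m2]

    day_index = np.broadcast_to(np.arange(1, days + 1), shape2)
    wid_grid = np.broadcast_to(ids[:, None], shape2)

    frames = []
    for domain, parts_day in [("work", work_day), ("leisure", leis_day)]:
        classes = _split_classes(parts_day, domain)
        for cls, minutes in classes.items():
            frames.append(
                pd.DataFrame(
                    {
                        "worker_id": wid_grid.ravel(),
                        "day_index": day_index.ravel(),
                        "is_workday": is_workday.ravel(),
                        "domain": domain,
                        "class": cls,
                        "minutes": minutes.ravel(),
                    }
                )
            )
    days_df = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["worker_id", "day_index", "domain", "class"], kind="stable")
        .reset_index(drop=True)
    )
    bed_df = pd.DataFrame(
        {
            "worker_id": wid_grid.ravel(),
            "day_index": day_index.ravel(),
            "time_in_bed_min": bed_day.ravel(),
            "wear_work_min": work_day.sum(axis=2).ravel(),
            "wear_leisure_min": leis_day.sum(axis=2).ravel(),
        }
    ).sort_values(["worker_id", "day_index"], kind="stable").reset_index(drop=True)

    covariates_df = pd.DataFrame(
        {
            "worker_id": ids,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "bmi": bmi,
            "smoking": np.where(smoker, "smoker", "non_smoker"),
            "lifting": lifting,
            "ses": ses,
        }
    )

    truth = {
        "betas": betas,
        "lambda0": float(lambda0),
        "eta": eta,
        "event": event,
        "event_week": event_week,
        "censored": censored,
        "censor_reason": censor_reason,
        "work_parts": work_parts,
        "leisure_parts": leis_parts,
        "event_fraction": float(event.mean()),
        "censored_fraction_non_event": float(censored[~event].mean()),
    }
    return Cohort(days=days_df, bed=bed_df, covariates=covariates_df, register=register, truth=truth)


# ---------------------------------------------------------------------------
# Deterministic fixture files for the test suite


def _boundary_register_frame() -> pd.DataFrame:
    """Hand-constructed register series exercising every boundary rule.

    synthetic fixture: worker 1 all-none; worker 2 a 5-week decoy only;
    worker 3 a 6-week run at week 89; worker 4 an event at 89 preceded by a
    death code at week 50; worker 5 (female) maternity at week 100; worker 6
    (male) a spurious maternity code.
    """
    rows = []
    rows += [(2, w, "sickness") for w in range(10, 15)]
    rows += [(3, w, "sickness") for w in range(89, 95)]
    rows += [(4, 50, "died")] + [(4, w, "sickness") for w in range(89, 95)]
    rows += [(5, 100, "maternity_start")]
    rows += [(6, 100, "maternity_start")]
    return pd.DataFrame(rows, columns=["worker_id", "week", "code"])


def _zero_mvpa_days() -> tuple[pd.DataFrame, pd.DataFrame]:
    """synthetic fixture: one worker with zero MVPA in both domains."""
    rows = []
    for domain, sed, stand in [("work", 300.0, 100.0), ("leisure", 500.0, 80.0)]:
        for cls, minutes in [
            ("sedentary", sed),
            ("standing_still", stand),
            ("moving", 30.0),
            ("walking_slow", 20.0),
            ("walking_fast", 0.0),
            ("running", 0.0),
            ("stair_climbing", 0.0),
            ("cycling", 0.0),
        ]:
            rows.append((1, 1, True, domain, cls, minutes))
    days = pd.DataFrame(
        rows, columns=["worker_id", "day_index", "is_workday", "domain", "class", "minutes"]
    )
    bed = pd.DataFrame(
        [{"worker_id": 1, "day_index": 1, "time_in_bed_min": 420.0,
          "wear_work_min": 450.0, "wear_leisure_min": 630.0}]
    )
    return days, bed


def write_fixture_suite(outdir, config: GeneratorConfig | None = None, seeds=(0,)) -> dict:
    """Write deterministic fixture files plus a hash manifest.

    Per seed: a tiny 10-worker cohort (3 days each) and the full
    default-configuration cohort. Alongside: a constructed boundary
    register table and a zero-MVPA worker (both synthetic, hand-written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or GeneratorConfig()
    written = []
    for seed in seeds:
        tiny_cfg = GeneratorConfig(**{**asdict(config), "n_workers": 10, "days_per_worker": 3})
        tiny = generate_cohort(tiny_cfg, seed=seed)
        written += list(tiny.write(outdir / f"tiny_seed{seed}").values())
        full = generate_cohort(config, seed=seed)
        written += list(full.write(outdir / f"full_seed{seed}").values())
    boundary = outdir / "register_boundary_synthetic.csv"
    _boundary_register_frame().to_csv(boundary, index=False)
    written.append(boundary)
    zd, zb = _zero_mvpa_days()
    zdp, zbp = outdir / "days_zero_mvpa_synthetic.csv", outdir / "bed_zero_mvpa_synthetic.csv"
    zd.to_csv(zdp, index=False)
    zb.to_csv(zbp, index=False)
    written += [zdp, zbp]
    manifest = {
        str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest() for p in written
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
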
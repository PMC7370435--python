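"""Day-level accelerometer summaries -> one work and one leisure composition per worker.

Raw thigh-accelerometer activity classes are merged into the four behavior parts
(MVPA = fast walking + running + stair climbing, LIPA = moving + slow
walking, sedentary and standing pass through; leisure MVPA additionally
includes cycling and leisure gains time in bed as a fifth part). Days are
screened with the wear-time validity rules (work period >= 4 h wear,
leisure period >= 75% of the worker's average leisure wear, time in bed
>= 4 h; non-workdays dropped), and valid days are aggregated per worker
(arithmetic means for the awake behaviors, median for time in bed).
Workers without a single fully valid day are excluded with a reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compositions import (
    DomainComposition,
    LEISURE_PART_ORDER,
    WORK_PART_ORDER,
    zero_replace,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RAW_CLASSES",
    "BehaviorDay",
    "WorkerRecord",
    "merge_classes",
    "validate_day",
    "aggregate_worker",
    "prepare_workers",
    "ValidityRules",
]

#: Day-level activity classes from a thigh-accelerometer classifier.
RAW_CLASSES: tuple[str, ...] = (
    "sedentary",
    "standing_still",
    "moving",
    "walking_slow",
    "walking_fast",
    "running",
    "stair_climbing",
    "cycling",
)

#: Which raw classes feed each behavior part, per domain. Cycling counts as
#: MVPA in leisure only; occupational cycling is left out of work MVPA.
_WORK_MVPA = ("walking_fast", "running", "stair_climbing")
_LEISURE_MVPA = ("walking_fast", "running", "stair_climbing", "cycling")
_LIPA = ("moving", "walking_slow")


@dataclass(frozen=True)
class ValidityRules:
    """Day-validity thresholds; defaults are the cohort's published rules."""

    work_min_wear: float = 240.0          # >= 4 h wear at work
    leisure_frac_of_avg: float = 0.75     # >= 75% of average leisure wear
    bed_min: float = 240.0                # >= 4 h in bed


@dataclass
class BehaviorDay:
    worker_id: object
    day_index: int
    domain_minutes: dict           # domain -> {raw class -> minutes}
    time_in_bed: float
    wear_minutes: dict             # domain -> minutes
    is_workday: bool = True

    def __post_init__(self):
        for dom, classes in self.domain_minutes.items():
            s = sum(classes.values())
            if any(v < 0 for v in classes.values()) or self.time_in_bed < 0:
                raise ValueError("negative minutes")
            if self.wear_minutes.get(dom, 0.0) < s - 1e-6:
                raise ValueError(
                    f"{dom} wear {self.wear_minutes.get(dom)} below class total {s}"
                )


@dataclass
class WorkerRecord:
    worker_id: object
    work_comp: DomainComposition
    leisure_comp: DomainComposition
    n_valid_days: int
    covariates: dict = field(default_factory=dict)


def merge_classes(day: BehaviorDay, domain: str) -> np.ndarray:
    """Merge a day's raw classes into the domain's behavior parts.

    Returns the four work parts (MVPA, sedentary, standing, LIPA) or the
    five leisure parts (same plus time in bed). Missing classes count as
    zero with a logged warning.
    """
    if domain not in day.domain_minutes:
        raise KeyError(f"day has no {domain} minutes")
    classes = day.domain_minutes[domain]
    missing = [c for c in RAW_CLASSES if c not in classes]
    if missing:
        logger.warning(
            "worker %s day %s %s: missing classes %s treated as 0",
            day.worker_id, day.day_index, domain, missing,
        )
    get = lambda c: float(classes.get(c, 0.0))
    mvpa_classes = _LEISURE_MVPA if domain == "leisure" else _WORK_MVPA
    parts = [
        sum(get(c) for c in mvpa_classes),
        get("sedentary"),
        get("standing_still"),
        sum(get(c) for c in _LIPA),
    ]
    if domain == "leisure":
        parts.append(float(day.time_in_bed))
    return np.asarray(parts)


def validate_day(
    day: BehaviorDay,
    avg_wear: Mapping[str, float],
    rules: ValidityRules = ValidityRules(),
) -> dict[str, bool]:
    """Apply the wear-time validity rules to one day.

    ``avg_wear`` holds the worker's own average wear per domain across
    measured workdays. Non-workdays are invalid wholesale.
    """
    if not day.is_workday:
        return {"work_valid": False, "leisure_valid": False, "bed_valid": False}
    work_wear = float(day.wear_minutes.get("work", 0.0))
    leisure_wear = float(day.wear_minutes.get("leisure", 0.0))
    return {
        "work_valid": work_wear >= rules.work_min_wear,
        "leisure_valid": leisure_wear
        >= rules.leisure_frac_of_avg * float(avg_wear.get("leisure", np.inf)),
        "bed_valid": float(day.time_in_bed) >= rules.bed_min,
    }


def _average_wear(days: Sequence[BehaviorDay]) -> dict[str, float]:
    workdays = [d for d in days if d.is_workday]
    if not workdays:
        return {"work": np.nan, "leisure": np.nan}
    return {
        dom: float(np.mean([d.wear_minutes.get(dom, 0.0) for d in workdays]))
        for dom in ("work", "leisure")
    }


def aggregate_worker(
    days: Sequence[BehaviorDay],
    covariates: Mapping | None = None,
    rules: ValidityRules = ValidityRules(),
    delta: float = 0.5,
) -> WorkerRecord:
    """Aggregate one worker's valid days into their two compositions.

    A day counts only if its work, leisure and time-in-bed periods are all
    valid. Awake parts are arithmetic means over valid days; time in bed is
    the median. Zero parts are repaired by multiplicative replacement with
    ``delta`` minutes.

    Raises
    ------
    ValueError
        If the worker has no fully valid day ('no_valid_day') or no workday
        at all ('no_workdays'); callers record the reason and exclude the
        worker.
    """
    if not days:
        raise ValueError("no_workdays")
    worker_id = days[0].worker_id
    avg_wear = _average_wear(days)
    if not np.isfinite(avg_wear["leisure"]):
        raise ValueError("no_workdays")
    valid = [
        d for d in days if all(validate_day(d, avg_wear, rules).values())
    ]
    if not valid:
        raise ValueError("no_valid_day")

    work = np.mean([merge_classes(d, "work") for d in valid], axis=0)
    leisure_days = np.vstack([merge_classes(d, "leisure") for d in valid])
    leisure = leisure_days[:, :4].mean(axis=0)
    bed = float(np.median(leisure_days[:, 4]))

    work_comp = DomainComposition("work", tuple(zero_replace(work, delta)), WORK_PART_ORDER)
    leisure_comp = DomainComposition(
        "leisure",
        tuple(zero_replace(np.append(leisure, bed), delta)),
        LEISURE_PART_ORDER,
    )
    return WorkerRecord(
        worker_id=worker_id,
        work_comp=work_comp,
        leisure_comp=leisure_comp,
        n_valid_days=len(valid),
        covariates=dict(covariates or {}),
    )


# ---------------------------------------------------------------------------
# DataFrame front end (the CSV dialect the pipeline reads and writes)

WORKER_PART_COLUMNS = [f"work_{p}" for p in WORK_PART_ORDER] + [
    f"leisure_{p}" for p in LEISURE_PART_ORDER
]
COVARIATE_COLUMNS = ["age", "sex", "bmi", "smoking", "lifting", "ses"]


def _days_from_frames(days_df: pd.DataFrame, bed_df: pd.DataFrame):
    """Yield (worker_id, [BehaviorDay, ...]) from the long-format tables."""
    wide = days_df.pivot_table(
        index=["worker_id", "day_index", "is_workday"],
        columns=["domain", "class"],
        values="minutes",
        aggfunc="sum",
        fill_value=0.0,
    )
    bed = bed_df.set_index(["worker_id", "day_index"])
    for worker_id, grp in wide.groupby(level="worker_id", sort=True):
        day_objs = []
        for (wid, day_index, is_workday), row in grp.iterrows():
            dom_minutes = {}
            for dom in ("work", "leisure"):
                if dom in row.index.get_level_values(0):
                    dom_minutes[dom] = {
                        cls: float(row[(dom, cls)])
                        for cls in row[dom].index
                    }
                else:
                    dom_minutes[dom] = {}
            b = bed.loc[(wid, day_index)]
            day_objs.append(
                BehaviorDay(
                    worker_id=wid,
                    day_index=int(day_index),
                    domain_minutes=dom_minutes,
                    time_in_bed=float(b["time_in_bed_min"]),
                    wear_minutes={
                        "work": float(b["wear_work_min"]),
                        "leisure": float(b["wear_leisure_min"]),
                    },
                    is_workday=bool(is_workday),
                )
            )
        yield worker_id, day_objs


def prepare_workers(
    days_df: pd.DataFrame,
    bed_df: pd.DataFrame,
    covariates_df: pd.DataFrame,
    rules: ValidityRules = ValidityRules(),
    delta: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run merging, validity screening and aggregation over a whole cohort.

    Parameters
    ----------
    days_df : DataFrame
        Long format: worker_id, day_index, is_workday, domain, class, minutes.
    bed_df : DataFrame
        worker_id, day_index, time_in_bed_min, wear_work_min, wear_leisure_min.
    covariates_df : DataFrame
        worker_id plus age, sex, bmi, smoking, lifting, ses.

    Returns
    -------
    workers : DataFrame
        One row per included worker: the nine part durations, n_valid_days
        and covariates.
    exclusions : DataFrame
        worker_id, reason for every excluded worker (conserving counts:
        len(workers) + len(exclusions) == number of input workers).
    """
    cov = covariates_df.set_index("worker_id")
    rows, excluded = [], []
    for worker_id, day_objs in _days_from_frames(days_df, bed_df):
        covariates = (
            cov.loc[worker_id].to_dict() if worker_id in cov.index else {}
        )
        try:
            rec = aggregate_worker(day_objs, covariates, rules, delta)
        except ValueError as err:
            excluded.append({"worker_id": worker_id, "reason": str(err)})
            logger.info("excluding worker %s: %s", worker_id, err)
            continue
        row = {"worker_id": worker_id, "n_valid_days": rec.n_valid_days}
        row.update({f"work_{p}": v for p, v in rec.work_comp.as_dict().items()})
        row.update({f"leisure_{p}": v for p, v in rec.leisure_comp.as_dict().items()})
        for c in COVARIATE_COLUMNS:
            row[c] = rec.covariates.get(c, np.nan)
        rows.append(row)
    workers = pd.DataFrame(
        rows,
        columns=["worker_id"] + WORKER_PART_COLUMNS + ["n_valid_days"] + COVARIATE_COLUMNS,
    )
    exclusions = pd.DataFrame(excluded, columns=["worker_id", "reason"])
    return workers, exclusions


def worker_compositions(workers_df: pd.DataFrame):
    """Rebuild (work, leisure) `DomainComposition` lists from workers.csv."""
    work = [
        DomainComposition("work", tuple(r), WORK_PART_ORDER)
        for r in workers_df[[f"work_{p}" for p in WORK_PART_ORDER]].to_numpy()
    ]
    leisure = [
        DomainComposition("leisure", tuple(r), LEISURE_PART_ORDER)
        for r in workers_df[[f"leisure_{p}" for p in LEISURE_PART_ORDER]].to_numpy()
    ]
    return work, leisure
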
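"""Weekly benefit-register series -> first-event LTSA survival outcomes.

Long-term sickness absence (LTSA) is the first run of at least
``min_run`` (default 6) consecutive sickness weeks whose full run fits
inside the follow-up horizon (default 212 weeks, four years). Runs of
exactly five weeks — the shortest spell the register can contain — never
qualify. Workers leaving the register (emigration, death, early or
ordinary retirement) are censored at the week the code appears; maternity
leave back-dates a pregnancy censoring by 35 weeks (eight months). The
administrative end of follow-up censors everyone else at the horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CODES",
    "RegisterSeries",
    "SurvivalOutcome",
    "detect_ltsa",
    "apply_censoring",
    "outcomes_from_register",
    "series_from_sparse",
]

CODES = (
    "none",
    "sickness",
    "emigrated",
    "died",
    "early_retirement",
    "ordinary_retirement",
    "maternity_start",
)

_CENSOR_CODES = ("emigrated", "died", "early_retirement", "ordinary_retirement")

DEFAULT_HORIZON = 212
DEFAULT_MIN_RUN = 6
MATERNITY_LEAD_WEEKS = 35  # "8 months later": 8 * 30.44 d / 7 d, rounded


@dataclass
class RegisterSeries:
    """One worker's weekly code sequence, week 1 == index 0."""

    worker_id: object
    codes: np.ndarray  # dtype object/str, length >= horizon
    sex: str = "female"

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=object)
        bad = set(self.codes) - set(CODES)
        if bad:
            raise ValueError(f"unknown register codes {bad}")


@dataclass
class SurvivalOutcome:
    worker_id: object
    time_weeks: int
    event: bool
    censor_reason: str = "none"

    def __post_init__(self):
        if self.event and self.censor_reason != "none":
            raise ValueError("an event outcome carries no censoring reason")


def detect_ltsa(
    series: RegisterSeries,
    min_run: int = DEFAULT_MIN_RUN,
    horizon: int = DEFAULT_HORIZON,
    event_timing: str = "start",
) -> SurvivalOutcome:
    """First qualifying sickness run within the follow-up horizon.

    The event is the first week ``w`` such that weeks ``w .. w+min_run-1``
    are all sickness and the run's end still lies within ``horizon``.
    ``event_timing`` dates the event at the run ``start`` (default: risk
    ends when the spell begins) or at its qualifying ``end`` week.
    """
    if len(series.codes) < horizon:
        raise ValueError(
            f"series length {len(series.codes)} shorter than horizon {horizon}"
        )
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if event_timing not in ("start", "end"):
        raise ValueError("event_timing must be 'start' or 'end'")
    sick = series.codes[:horizon] == "sickness"
    if min_run <= horizon:
        windows = np.lib.stride_tricks.sliding_window_view(sick, min_run).all(axis=1)
        hits = np.flatnonzero(windows)
        if hits.size:
            start_week = int(hits[0]) + 1
            time = start_week if event_timing == "start" else start_week + min_run - 1
            return SurvivalOutcome(series.worker_id, time, True, "none")
    return SurvivalOutcome(series.worker_id, horizon, False, "admin_end")


def _censor_candidates(series: RegisterSeries, horizon: int, maternity_lead: int):
    """(week, reason) candidates from the raw codes, maternity back-dated."""
    out = []
    for code in _CENSOR_CODES:
        weeks = np.flatnonzero(series.codes == code)
        if weeks.size:
            out.append((int(weeks[0]) + 1, code))
    maternity = np.flatnonzero(series.codes == "maternity_start")
    if maternity.size:
        if series.sex == "female":
            week = max(1, int(maternity[0]) + 1 - maternity_lead)
            out.append((week, "pregnancy"))
        else:
            logger.warning(
                "worker %s: maternity_start code for a male worker ignored",
                series.worker_id,
            )
    return [(w, r) for w, r in out if w <= horizon]


def apply_censoring(
    series: RegisterSeries,
    outcome: SurvivalOutcome,
    horizon: int = DEFAULT_HORIZON,
    maternity_lead: int = MATERNITY_LEAD_WEEKS,
) -> SurvivalOutcome:
    """Overlay the censoring rules on a detected outcome.

    The censoring time is the earliest of the leave-register codes (with
    pregnancy back-dated ``maternity_lead`` weeks from maternity start,
    floored at week 1). If it precedes the event — ties go to the event —
    the worker is censored there and contributes risk time only up to that
    week.
    """
    candidates = _censor_candidates(series, horizon, maternity_lead)
    if not candidates:
        return outcome
    censor_week, reason = min(candidates)
    if outcome.event and outcome.time_weeks <= censor_week:
        return outcome  # ties go to the observed event
    return SurvivalOutcome(series.worker_id, censor_week, False, reason)


def series_from_sparse(
    register_df: pd.DataFrame,
    worker_ids: Sequence,
    sex: pd.Series | None = None,
    length: int = DEFAULT_HORIZON + MATERNITY_LEAD_WEEKS,
) -> list[RegisterSeries]:
    """Expand a sparse (worker_id, week, code) table to dense weekly series.

    Weeks absent from the table are 'none'. ``length`` must cover the
    horizon plus the maternity lead so back-dated codes are visible.
    """
    out = []
    grouped = dict(tuple(register_df.groupby("worker_id", sort=False)))
    for wid in worker_ids:
        codes = np.full(length, "none", dtype=object)
        if wid in grouped:
            g = grouped[wid]
            weeks = g["week"].to_numpy(dtype=int)
            if (weeks < 1).any() or (weeks > length).any():
                raise ValueError(f"worker {wid}: week index outside 1..{length}")
            codes[weeks - 1] = g["code"].to_numpy(dtype=object)
        out.append(
            RegisterSeries(
                wid,
                codes,
                sex=str(sex.get(wid, "female")) if sex is not None else "female",
            )
        )
    return out


def outcomes_from_register(
    register_df: pd.DataFrame,
    workers_df: pd.DataFrame,
    min_run: int = DEFAULT_MIN_RUN,
    horizon: int = DEFAULT_HORIZON,
    event_timing: str = "start",
    maternity_lead: int = MATERNITY_LEAD_WEEKS,
) -> pd.DataFrame:
    """Survival outcomes for every worker in ``workers_df``.

    Returns a DataFrame with worker_id, time_weeks, event, censor_reason.
    """
    sex = workers_df.set_index("worker_id")["sex"] if "sex" in workers_df else None
    series = series_from_sparse(
        register_df,
        workers_df["worker_id"].tolist(),
        sex=sex,
        length=horizon + maternity_lead + 5,
    )
    rows = []
    for s in series:
        o = detect_ltsa(s, min_run, horizon, event_timing)
        o = apply_censoring(s, o, horizon, maternity_lead)
        rows.append(
            {
                "worker_id": o.worker_id,
                "time_weeks": o.time_weeks,
                "event": bool(o.event),
                "censor_reason": o.censor_reason,
            }
        )
    return pd.DataFrame(rows)
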
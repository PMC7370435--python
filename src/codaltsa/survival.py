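"""Cox proportional-hazards estimation on ilr covariates plus confounders.

The model is the standard semiparametric proportional-hazards regression:
``h_i(t) = h_0(t) exp(x_i' beta)`` with the partial likelihood maximized by
Newton-Raphson. Event times are weeks, so ties are heavy; the Efron
correction is the default (Breslow available for comparison). Inference is
Wald (z = beta / se from the inverse observed information), and the
proportional-hazards assumption is checked with the Grambsch-Therneau
score test on scaled Schoenfeld residuals against a transform of event
time (Kaplan-Meier transform by default).

Covariates are the three work-domain and four leisure-domain pivot ilr
coordinates plus the confounders (age, sex, BMI, smoking, occupational
lifting/carrying duration, optionally socioeconomic-status indicators).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .compositions import (
    LEISURE_PART_ORDER,
    WORK_PART_ORDER,
    PivotIlr,
    sbp_basis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "PhTestResult",
    "CoxPH",
    "ConvergenceError",
    "build_model_matrix",
    "cox_fit",
    "wald_test",
    "wald_table",
    "grambsch_therneau",
    "ses_sensitivity",
    "WORK_ILR_COLUMNS",
    "LEISURE_ILR_COLUMNS",
    "CONFOUNDER_COLUMNS",
    "SES_DUMMY_COLUMNS",
]

WORK_ILR_COLUMNS = [f"work_ilr{k}" for k in range(1, len(WORK_PART_ORDER))]
LEISURE_ILR_COLUMNS = [f"leisure_ilr{k}" for k in range(1, len(LEISURE_PART_ORDER))]
CONFOUNDER_COLUMNS = ["age", "sex", "bmi", "smoking", "lifting"]
SES_DUMMY_COLUMNS = ["ses_blue_collar_skilled", "ses_blue_collar_unskilled"]
SES_CATEGORIES = ("white_collar", "blue_collar_skilled", "blue_collar_unskilled")

_SEX_CODE = {"male": 0.0, "female": 1.0}
_SMOKING_CODE = {"non_smoker": 0.0, "smoker": 1.0}


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """Result of one partial-likelihood maximization."""

    beta: pd.Series
    covariance: pd.DataFrame
    loglik: float
    null_loglik: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    ties_method: str

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.beta.index)


@dataclass
class PhTestResult:
    """Grambsch-Therneau proportional-hazards test."""

    per_covariate: dict  # name -> (chi_square, df, p)
    global_test: tuple   # (chi_square, df, p)
    time_transform: str


# ---------------------------------------------------------------------------
# Partial likelihood machinery


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR with column pivoting localizes the dependent columns
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if i >= rank or diag[i] <= tol]
        raise ValueError(f"rank-deficient model matrix; offending columns: {sorted(set(bad))}")


def _efron_quantities(X, time, event, beta, ties):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Subjects must be sorted by time ascending; censored subjects at an
    event week stay in that week's risk set.
    """
    n, p = X.shape
    eta = X @ beta
    eta_c = eta - eta.max()  # stabilize exp; constant shift cancels
    phi = np.exp(eta_c)
    phix = phi[:, None] * X

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    R = 0.0
    Rx = np.zeros(p)
    Rxx = np.zeros((p, p))

    # group boundaries of equal times, iterated from the latest time
    uniq, starts = np.unique(time, return_index=True)
    bounds = list(zip(starts, np.append(starts[1:], n)))
    for lo, hi in reversed(bounds):
        sl = slice(lo, hi)
        R += phi[sl].sum()
        Rx += phix[sl].sum(axis=0)
        Rxx += np.einsum("ij,ik->jk", phix[sl], X[sl])
        ev = event[sl]
        d = int(ev.sum())
        if d == 0:
            continue
        Xd = X[sl][ev]
        Dphi = phi[sl][ev].sum()
        Dx = phix[sl][ev].sum(axis=0)
        Dxx = np.einsum("ij,ik->jk", phix[sl][ev], Xd)
        ll += eta_c[sl][ev].sum()
        grad += Xd.sum(axis=0)
        ls = np.arange(d) / d if ties == "efron" else np.zeros(d)
        for f in ls:
            denom = R - f * Dphi
            num = Rx - f * Dx
            numxx = Rxx - f * Dxx
            ll -= np.log(denom)
            grad -= num / denom
            hess -= numxx / denom - np.outer(num, num) / denom**2
    return ll, grad, hess


def _schoenfeld_residuals(X, time, event, beta, ties="efron"):
    """Efron-weighted Schoenfeld residuals for event subjects (sorted order).

    Within a tied event week each event subject gets ``x_i`` minus the same
    Efron-averaged risk-set mean.
    """
    n, p = X.shape
    eta = X @ beta
    phi = np.exp(eta - eta.max())
    phix = phi[:, None] * X

    R = 0.0
    Rx = np.zeros(p)
    resids = []
    times_out = []
    uniq, starts = np.unique(time, return_index=True)
    bounds = list(zip(starts, np.append(starts[1:], n)))
    for lo, hi in reversed(bounds):
        sl = slice(lo, hi)
        R += phi[sl].sum()
        Rx += phix[sl].sum(axis=0)
        ev = event[sl]
        d = int(ev.sum())
        if d == 0:
            continue
        Dphi = phi[sl][ev].sum()
        Dx = phix[sl][ev].sum(axis=0)
        ls = np.arange(d) / d if ties == "efron" else np.zeros(d)
        mean = np.zeros(p)
        for f in ls:
            mean += (Rx - f * Dx) / (R - f * Dphi)
        mean /= d
        for xi in X[sl][ev]:
            resids.append(xi - mean)
            times_out.append(time[lo])
    order = np.argsort(times_out, kind="stable")
    return np.asarray(resids)[order], np.asarray(times_out)[order]


class CoxPH(BaseEstimator):
    """Cox proportional-hazards estimator (Efron ties, Newton-Raphson).

    Parameters
    ----------
    ties : {'efron', 'breslow'}, default 'efron'
        Tie correction for the partial likelihood.
    tol : float, default 1e-9
        Convergence threshold on the gradient max-norm.
    max_iter : int, default 50
        Newton-Raphson iteration cap (with step-halving on likelihood
        decrease).

    Attributes
    ----------
    coef_ : Series of fitted log-hazard ratios.
    covariance_ : DataFrame, inverse observed information at the optimum.
    loglik_ : float, maximized log partial likelihood.
    null_loglik_ : float, log partial likelihood at beta = 0.
    converged_ : bool.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9, max_iter: int = 50):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _split_y(y):
        if isinstance(y, pd.DataFrame):
            time = y["time_weeks"].to_numpy(dtype=float)
            event = y["event"].to_numpy(dtype=bool)
        else:
            y = np.asarray(y)
            time = y[:, 0].astype(float)
            event = y[:, 1].astype(bool)
        return time, event

    def fit(self, X, y):
        """Fit to covariates ``X`` and outcomes ``y``.

        ``y`` is a DataFrame with ``time_weeks`` and ``event`` columns or a
        2-column array ``[time, event]`` aligned with ``X`` rows.
        """
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        if np.isnan(Xv).any():
            raise ValueError("model matrix contains missing values")
        time, event = self._split_y(y)
        if event.sum() < 1:
            raise ValueError("at least one event is required")
        _check_rank(Xv - Xv.mean(axis=0), names)

        order = np.argsort(time, kind="stable")
        Xs, ts, es = Xv[order], time[order], event[order]

        p = Xv.shape[1]
        beta = np.zeros(p)
        ll, grad, hess = _efron_quantities(Xs, ts, es, beta, self.ties)
        self.null_loglik_ = ll
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                n_iter -= 1
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as err:  # pragma: no cover
                raise ConvergenceError(f"singular information matrix: {err}") from err
            new_beta = beta + step
            new = _efron_quantities(Xs, ts, es, new_beta, self.ties)
            halvings = 0
            while new[0] < ll - 1e-12 and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new = _efron_quantities(Xs, ts, es, new_beta, self.ties)
                halvings += 1
            beta = new_beta
            ll, grad, hess = new
            if np.max(np.abs(beta)) > 50:
                logger.warning(
                    "monotone partial likelihood suspected (|beta| > 50); flagging non-convergence"
                )
                break
        else:
            n_iter = self.max_iter
        if not converged and np.max(np.abs(grad)) < self.tol:
            converged = True

        self.coef_ = pd.Series(beta, index=names)
        self.covariance_ = pd.DataFrame(np.linalg.inv(-hess), index=names, columns=names)
        self.loglik_ = float(ll)
        self.converged_ = bool(converged)
        self.n_iter_ = int(n_iter)
        self.n_events_ = int(es.sum())
        self.n_ = int(len(ts))
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self._sorted = (Xs, ts, es)
        return self

    def predict(self, X) -> np.ndarray:
        """Linear predictor ``x' beta`` (log relative hazard)."""
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return Xv @ self.coef_.to_numpy()

    def schoenfeld_residuals(self) -> tuple[np.ndarray, np.ndarray]:
        r, t = _schoenfeld_residuals(*self._sorted, self.coef_.to_numpy(), self.ties)
        return r, t

    def baseline_cumulative_hazard(self) -> pd.Series:
        """Breslow baseline cumulative hazard (for simulation checks)."""
        Xs, ts, es = self._sorted
        phi = np.exp(Xs @ self.coef_.to_numpy())
        uniq, starts = np.unique(ts, return_index=True)
        bounds = list(zip(starts, np.append(starts[1:], len(ts))))
        R = 0.0
        incs = []
        for lo, hi in reversed(bounds):
            R += phi[lo:hi].sum()
            d = es[lo:hi].sum()
            incs.append(d / R)
        h0 = np.cumsum(incs[::-1])
        return pd.Series(h0, index=uniq)

    def to_fit(self) -> CoxFit:
        return CoxFit(
            beta=self.coef_.copy(),
            covariance=self.covariance_.copy(),
            loglik=self.loglik_,
            null_loglik=self.null_loglik_,
            n=self.n_,
            n_events=self.n_events_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            ties_method=self.ties,
        )


# ---------------------------------------------------------------------------
# Model matrix


def build_model_matrix(
    workers_df: pd.DataFrame,
    include_ses: bool = False,
    delta: float = 0.5,
    composition_mode: str = "separate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ilr coordinates plus coded confounders, one row per analyzable worker.

    In the default ``separate`` mode work and leisure enter as two
    compositions (three plus four pivot coordinates). The ``whole_day``
    sensitivity mode instead treats all nine behaviors as sub-compositions
    of the measured day (eight pivot coordinates, work MVPA first).

    Workers missing any required covariate (socioeconomic status counts
    only when ``include_ses``) are excluded with a reason, mirroring the
    shrinkage of the analysis set when SES enters the model.

    Returns
    -------
    X : DataFrame indexed by worker_id.
    excluded : DataFrame with worker_id, reason.
    """
    df = workers_df.set_index("worker_id")
    work_parts = df[[f"work_{p}" for p in WORK_PART_ORDER]].to_numpy(dtype=float)
    leis_parts = df[[f"leisure_{p}" for p in LEISURE_PART_ORDER]].to_numpy(dtype=float)
    if composition_mode == "separate":
        work_ilr = PivotIlr(delta=delta).fit(work_parts).transform(work_parts)
        leis_ilr = PivotIlr(delta=delta).fit(leis_parts).transform(leis_parts)
        X = pd.DataFrame(work_ilr, columns=WORK_ILR_COLUMNS, index=df.index)
        X[LEISURE_ILR_COLUMNS] = leis_ilr
        ilr_columns = WORK_ILR_COLUMNS + LEISURE_ILR_COLUMNS
    elif composition_mode == "whole_day":
        day_parts = np.hstack([work_parts, leis_parts])
        day_ilr = PivotIlr(delta=delta).fit(day_parts).transform(day_parts)
        cols = [f"day_ilr{k}" for k in range(1, day_parts.shape[1])]
        X = pd.DataFrame(day_ilr, columns=cols, index=df.index)
        ilr_columns = cols
    else:
        raise ValueError("composition_mode must be 'separate' or 'whole_day'")
    X["age"] = pd.to_numeric(df["age"], errors="coerce")
    X["sex"] = df["sex"].map(_SEX_CODE) if df["sex"].dtype == object else df["sex"]
    X["bmi"] = pd.to_numeric(df["bmi"], errors="coerce")
    X["smoking"] = (
        df["smoking"].map(_SMOKING_CODE) if df["smoking"].dtype == object else df["smoking"]
    )
    X["lifting"] = pd.to_numeric(df["lifting"], errors="coerce")

    required = ilr_columns + CONFOUNDER_COLUMNS
    if include_ses:
        ses = df["ses"].where(df["ses"].isin(SES_CATEGORIES))
        X[SES_DUMMY_COLUMNS[0]] = (ses == "blue_collar_skilled").astype(float)
        X[SES_DUMMY_COLUMNS[1]] = (ses == "blue_collar_unskilled").astype(float)
        X.loc[ses.isna(), SES_DUMMY_COLUMNS] = np.nan
        required = required + SES_DUMMY_COLUMNS

    bad = X[required].isna().any(axis=1)
    excluded = pd.DataFrame(
        {
            "worker_id": X.index[bad],
            "reason": [
                "missing_" + ",".join(X.columns[X.loc[i].isna()]) for i in X.index[bad]
            ],
        }
    )
    if bad.any():
        logger.info("excluding %d workers with missing covariates", int(bad.sum()))
    return X.loc[~bad, required], excluded


# ---------------------------------------------------------------------------
# Functional wrappers


def _align_outcomes(X: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    o = outcomes.set_index("worker_id").loc[X.index]
    return o[["time_weeks", "event"]]


def cox_fit(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit the Cox model; thin wrapper over the :class:`CoxPH` estimator."""
    y = (
        _align_outcomes(X, outcomes)
        if isinstance(outcomes, pd.DataFrame) and "worker_id" in outcomes.columns
        else outcomes
    )
    est = CoxPH(ties=ties, tol=tol, max_iter=max_iter).fit(X, y)
    fit = est.to_fit()
    fit._estimator = est
    return fit


def wald_test(fit: CoxFit, column: str) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p-value for one coefficient."""
    if not fit.converged:
        raise ConvergenceError("Wald inference on a non-converged fit")
    beta = float(fit.beta[column])
    se = float(np.sqrt(fit.covariance.loc[column, column]))
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def wald_table(fit: CoxFit) -> pd.DataFrame:
    """term, beta, se, z, p for every coefficient."""
    rows = []
    for name in fit.beta.index:
        z, p = wald_test(fit, name)
        rows.append(
            {"term": name, "beta": fit.beta[name], "se": fit.se[name], "z": z, "p": p}
        )
    return pd.DataFrame(rows)


def _km_transform(time: np.ndarray, event: np.ndarray) -> dict:
    """1 - KM(t) at each time, KM over all subjects (right-continuous at t)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, starts = np.unique(t, return_index=True)
    n = len(t)
    surv = {}
    s = 1.0
    counts = np.append(starts[1:], n) - starts
    at_risk = n
    for u, lo, c in zip(uniq, starts, counts):
        d = e[lo : lo + c].sum()
        s *= 1.0 - d / at_risk
        at_risk -= c
        surv[u] = s
    return {u: 1.0 - s for u, s in surv.items()}


def grambsch_therneau(
    fit: CoxFit,
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    transform: str = "km",
) -> PhTestResult:
    """Grambsch-Therneau proportional-hazards test.

    Regresses scaled Schoenfeld residuals ``s* = d * s * V`` on a transform
    ``g(t)`` of event time; the score-test chi-square per covariate is
    ``[sum (g-gbar) s*_j]^2 / (d V_jj sum (g-gbar)^2)`` and the global
    statistic is ``d u' V u / sum (g-gbar)^2`` with ``u = sum (g-gbar) s``.
    This is the classical approximation (average information ``I / d``)
    used by the reference zph implementations.
    """
    if not fit.converged:
        raise ConvergenceError("PH test on a non-converged fit")
    y = (
        _align_outcomes(X, outcomes)
        if isinstance(outcomes, pd.DataFrame) and "worker_id" in outcomes.columns
        else outcomes
    )
    time, event = CoxPH._split_y(y)
    d = int(event.sum())
    if d < 3:
        raise ValueError("insufficient events for PH test")
    order = np.argsort(time, kind="stable")
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    resid, etimes = _schoenfeld_residuals(
        Xv[order], time[order], event[order], fit.beta.to_numpy(), fit.ties_method
    )

    if transform == "km":
        mapping = _km_transform(time, event)
        g = np.array([mapping[t] for t in etimes])
    elif transform == "identity":
        g = etimes.astype(float)
    elif transform == "rank":
        # event rank among sorted subjects (tied events get distinct ranks,
        # matching the reference implementation's cumulative-count quirk)
        g = np.cumsum(event[order])[event[order]].astype(float)
    else:
        raise ValueError("transform must be 'km', 'rank' or 'identity'")

    w = g - g.mean()
    ssw = float(w @ w)
    V = fit.covariance.to_numpy()
    u = w @ resid
    uV = u @ V
    names = list(fit.beta.index)
    per = {}
    for j, name in enumerate(names):
        chi = d * uV[j] ** 2 / (V[j, j] * ssw)
        per[name] = (float(chi), 1, float(stats.chi2.sf(chi, 1)))
    chi_g = float(d * uV @ u / ssw)
    p_g = float(stats.chi2.sf(chi_g, len(names)))
    return PhTestResult(per_covariate=per, global_test=(chi_g, len(names), p_g), time_transform=transform)


# ---------------------------------------------------------------------------
# SES sensitivity


def ses_sensitivity(
    workers_df: pd.DataFrame,
    outcomes_df: pd.DataFrame,
    ties: str = "efron",
) -> dict:
    """SES sensitivity analyses on the SES-complete subset.

    Returns ``unadjusted`` and SES-``adjusted`` fits plus ``stratified``
    subgroup fits per SES category; a stratum without events is flagged as
    ``None`` with a logged warning.
    """
    complete = workers_df[workers_df["ses"].isin(SES_CATEGORIES)]
    X_adj, _ = build_model_matrix(complete, include_ses=True)
    X_un = X_adj[WORK_ILR_COLUMNS + LEISURE_ILR_COLUMNS + CONFOUNDER_COLUMNS]
    out = {
        "unadjusted": cox_fit(X_un, outcomes_df, ties=ties),
        "adjusted": cox_fit(X_adj, outcomes_df, ties=ties),
        "stratified": {},
    }
    ses = complete.set_index("worker_id")["ses"]
    y = outcomes_df.set_index("worker_id")
    for cat in SES_CATEGORIES:
        ids = ses.index[ses == cat]
        Xc = X_un.loc[X_un.index.intersection(ids)]
        if y.loc[Xc.index, "event"].sum() == 0:
            logger.warning("SES stratum %s has no events; fit skipped", cat)
            out["stratified"][cat] = None
            continue
        out["stratified"][cat] = cox_fit(Xc, outcomes_df, ties=ties)
    return out
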
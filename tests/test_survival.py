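import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from codaltsa.survival import (
    CONFOUNDER_COLUMNS,
    LEISURE_ILR_COLUMNS,
    SES_DUMMY_COLUMNS,
    WORK_ILR_COLUMNS,
    ConvergenceError,
    CoxFit,
    CoxPH,
    build_model_matrix,
    cox_fit,
    grambsch_therneau,
    ses_sensitivity,
    wald_table,
    wald_test,
)
from conftest import random_survival_frame


def toy_fit(beta, var=None, names=None, converged=True):
    names = names or [f"x{i}" for i in range(len(beta))]
    var = np.zeros((len(beta), len(beta))) if var is None else np.asarray(var)
    return CoxFit(
        beta=pd.Series(beta, index=names),
        covariance=pd.DataFrame(var, index=names, columns=names),
        loglik=0.0, null_loglik=0.0, n=10, n_events=5, n_iter=1,
        converged=converged, ties_method="efron",
    )


def test_cox_matches_brute_force_on_three_subject_dataset():
    # subjects: times 1 < 2 < 3, events at 1 and 2, covariate x = (1, 0, 1)
    # explicit partial likelihood:
    #   L(b) = e^b/(e^b + 1 + e^b) * 1/(1 + e^b)
    x = np.array([[1.0], [0.0], [1.0]])
    y = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 0.0]])

    def neg_logpl(b):
        return -(b - np.log(2 * np.exp(b) + 1) + 0.0 - np.log(1 + np.exp(b)))

    oracle = minimize_scalar(neg_logpl, bounds=(-5, 5), method="bounded",
                             options={"xatol": 1e-12}).x
    fit = CoxPH().fit(x, y)
    # the 1-d numeric oracle is good to ~1e-7; the closed form is -ln(2)/2
    assert fit.coef_.iloc[0] == pytest.approx(oracle, abs=1e-6)
    assert fit.coef_.iloc[0] == pytest.approx(-np.log(2.0) / 2.0, abs=1e-10)
    assert fit.loglik_ == pytest.approx(-neg_logpl(fit.coef_.iloc[0]), abs=1e-10)


def test_negating_a_covariate_negates_its_coefficient(rng):
    X, y = random_survival_frame(rng, n=100, p=2, beta=[0.4, -0.2])
    f1 = CoxPH().fit(X, y)
    X2 = X.copy()
    X2["x0"] = -X2["x0"]
    f2 = CoxPH().fit(X2, y)
    assert f1.coef_["x0"] == pytest.approx(-f2.coef_["x0"], abs=1e-9)
    assert f1.coef_["x1"] == pytest.approx(f2.coef_["x1"], abs=1e-9)


def test_efron_equals_breslow_without_ties(rng):
    X, y = random_survival_frame(rng, n=80, p=2, beta=[0.5, 0.0], weekly=False)
    assert y.loc[y["event"], "time_weeks"].nunique() == y["event"].sum()  # no tied events
    fe = CoxPH(ties="efron").fit(X, y)
    fb = CoxPH(ties="breslow").fit(X, y)
    np.testing.assert_allclose(fe.coef_, fb.coef_, atol=1e-10)
    assert fe.loglik_ == pytest.approx(fb.loglik_, abs=1e-10)


def test_fit_improves_on_null_and_time_scaling_invariance(rng):
    X, y = random_survival_frame(rng, n=120, p=3, beta=[0.5, -0.3, 0.0])
    f = CoxPH().fit(X, y)
    assert f.converged_ and f.loglik_ >= f.null_loglik_
    y2 = y.copy()
    y2["time_weeks"] *= 7.0  # weeks -> days: rank-based, beta unchanged
    f2 = CoxPH().fit(X, y2)
    np.testing.assert_allclose(f.coef_, f2.coef_, atol=1e-9)
    # covariance symmetric positive semi-definite
    cov = f.covariance_.to_numpy()
    np.testing.assert_allclose(cov, cov.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(cov) > 0)


def test_rank_deficiency_names_offending_columns(rng):
    X, y = random_survival_frame(rng, n=60, p=2)
    X["dup"] = X["x0"] * 2.0
    with pytest.raises(ValueError, match="rank-deficient"):
        CoxPH().fit(X, y)


def test_missing_values_and_no_events_rejected(rng):
    X, y = random_survival_frame(rng, n=30, p=2)
    Xm = X.copy()
    Xm.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        CoxPH().fit(Xm, y)
    y0 = y.copy()
    y0["event"] = False
    with pytest.raises(ValueError, match="event"):
        CoxPH().fit(X, y0)


def test_wald_test_scales():
    f = toy_fit([0.0, 2 * 0.5], var=np.diag([1.0, 0.25]))
    z0, p0 = wald_test(f, "x0")
    assert (z0, p0) == (0.0, 1.0)
    z1, p1 = wald_test(f, "x1")
    assert z1 == pytest.approx(2.0)
    assert p1 == pytest.approx(0.0455, abs=1e-3)
    with pytest.raises(ConvergenceError):
        wald_test(toy_fit([0.1], converged=False), "x0")


def test_wald_table_matches_fit(rng):
    X, y = random_survival_frame(rng, n=100, p=2, beta=[0.6, 0.0])
    fit = cox_fit(X, y)
    tab = wald_table(fit).set_index("term")
    np.testing.assert_allclose(tab["beta"], fit.beta, atol=1e-12)
    np.testing.assert_allclose(tab["z"], fit.beta / fit.se, atol=1e-12)


# ---------------------------------------------------------------------------
# model matrix


def _workers_frame(n=40, seed=5, missing_ses=4):
    from codaltsa.synthetic import GeneratorConfig, generate_cohort
    from codaltsa.accel_prep import prepare_workers

    cohort = generate_cohort(GeneratorConfig(n_workers=n, ses_missing_prob=0.0), seed=seed)
    workers, _ = prepare_workers(cohort.days, cohort.bed, cohort.covariates)
    workers.loc[workers.index[:missing_ses], "ses"] = np.nan
    return workers


def test_build_model_matrix_columns_and_ses_dummies():
    workers = _workers_frame()
    X, excl = build_model_matrix(workers)
    assert list(X.columns) == WORK_ILR_COLUMNS + LEISURE_ILR_COLUMNS + CONFOUNDER_COLUMNS
    assert len(X.columns) == 12 and len(excl) == 0
    assert set(X["sex"].unique()) <= {0.0, 1.0}
    assert set(X["smoking"].unique()) <= {0.0, 1.0}

    X2, excl2 = build_model_matrix(workers, include_ses=True)
    assert list(X2.columns[-2:]) == SES_DUMMY_COLUMNS
    assert len(X2.columns) == 14
    assert len(excl2) == 4  # missing SES drops workers only when SES enters
    assert len(X2) + len(excl2) == len(workers)
    # white-collar reference: dummies both zero
    ses = workers.set_index("worker_id")["ses"]
    wc = ses[ses == "white_collar"].index
    assert (X2.loc[X2.index.intersection(wc), SES_DUMMY_COLUMNS] == 0).all().all()


def test_build_model_matrix_whole_day_mode():
    workers = _workers_frame(missing_ses=0)
    X, _ = build_model_matrix(workers, composition_mode="whole_day")
    ilr_cols = [c for c in X.columns if c.startswith("day_ilr")]
    assert len(ilr_cols) == 8  # nine day parts -> eight coordinates


# ---------------------------------------------------------------------------
# proportional hazards diagnostics


def test_grambsch_therneau_requires_events(rng):
    X, y = random_survival_frame(rng, n=20, p=2)
    y.loc[y.index[:len(y)], "event"] = False
    y.iloc[0, y.columns.get_loc("event")] = True
    fit = toy_fit([0.0, 0.0], var=np.eye(2))
    with pytest.raises(ValueError, match="insufficient events"):
        grambsch_therneau(fit, X, y)


def test_grambsch_therneau_detects_planted_time_interaction(rng):
    # effect flips sign halfway through follow-up: grossly non-proportional
    n = 400
    x = rng.normal(size=(n, 1))
    early = rng.random(n) < 0.5
    lam = 0.05 * np.exp(np.where(early, 1.5, -1.5) * x[:, 0])
    t = np.ceil(-np.log(rng.random(n)) / lam)
    t = np.where(early, np.minimum(t, 30), 30 + np.minimum(t, 100))
    y = pd.DataFrame({"time_weeks": t, "event": np.ones(n, dtype=bool)})
    X = pd.DataFrame(x, columns=["x0"])
    fit = cox_fit(X, y)
    ph = grambsch_therneau(fit, X, y)
    assert ph.global_test[2] < 1e-6
    assert ph.per_covariate["x0"][0] > 30


def test_ph_test_result_shapes(small_analysis):
    ph = small_analysis["ph_test"]
    fit = small_analysis["fit"]
    assert set(ph.per_covariate) == set(fit.beta.index)
    chi, df, p = ph.global_test
    assert chi >= 0 and df == len(fit.beta) and 0 <= p <= 1


# ---------------------------------------------------------------------------
# SES sensitivity


@pytest.fixture(scope="module")
def ses_cohort():
    from codaltsa.synthetic import GeneratorConfig, generate_cohort
    from codaltsa.accel_prep import prepare_workers
    from codaltsa.register import outcomes_from_register

    cohort = generate_cohort(GeneratorConfig(n_workers=500), seed=21)
    workers, _ = prepare_workers(cohort.days, cohort.bed, cohort.covariates)
    outcomes = outcomes_from_register(cohort.register, workers)
    return workers, outcomes


def test_ses_sensitivity_fit_families(ses_cohort):
    workers, outcomes = ses_cohort
    fits = ses_sensitivity(workers, outcomes)
    n_complete = workers["ses"].notna().sum()
    assert fits["unadjusted"].n == fits["adjusted"].n == n_complete
    # SES independent of behaviors by construction: adjustment barely moves
    # the MVPA coefficients
    for col in (WORK_ILR_COLUMNS[0], LEISURE_ILR_COLUMNS[0]):
        diff = abs(fits["adjusted"].beta[col] - fits["unadjusted"].beta[col])
        assert diff < 2 * fits["unadjusted"].se[col]
    # subgroup fits partition the events of the SES-complete subset
    pooled = sum(
        f.n_events for f in fits["stratified"].values() if f is not None
    )
    assert pooled == fits["unadjusted"].n_events


def test_ses_category_split_matches_configuration(small_cohort):
    _, cohort = small_cohort
    ses = cohort.covariates["ses"].dropna()
    frac = ses.value_counts(normalize=True)
    assert frac["blue_collar_unskilled"] == pytest.approx(0.42, abs=0.08)
    assert frac["blue_collar_skilled"] == pytest.approx(0.39, abs=0.08)
    assert frac["white_collar"] == pytest.approx(0.19, abs=0.08)


def test_coxph_sklearn_protocol():
    est = CoxPH(ties="breslow", tol=1e-8)
    params = est.get_params()
    assert params["ties"] == "breslow"
    from sklearn.base import clone

    est2 = clone(est)
    assert est2.get_params() == params
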
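import numpy as np
import pandas as pd
import pytest

from codaltsa.compositions import DomainComposition, sbp_basis
from codaltsa.register import outcomes_from_register
from codaltsa.substitution import predict_hr, reallocate
from codaltsa.survival import LEISURE_ILR_COLUMNS, WORK_ILR_COLUMNS
from codaltsa.synthetic import (
    GeneratorConfig,
    _dirichlet_alpha,
    _inv_digamma,
    generate_cohort,
    plant_betas,
    write_fixture_suite,
)
from test_survival import toy_fit


def test_inv_digamma_inverts_digamma():
    from scipy.special import digamma

    x = np.array([0.3, 1.0, 4.7, 40.0, 500.0])
    np.testing.assert_allclose(_inv_digamma(digamma(x)), x, rtol=1e-10)


def test_dirichlet_alpha_targets_compositional_mean():
    from scipy.special import digamma

    props = np.array([33, 311, 77, 41, 429.0]) / 891.0
    alpha = _dirichlet_alpha(props, 100.0)
    assert alpha.sum() == pytest.approx(100.0, abs=1e-8)
    logm = digamma(alpha)
    implied = np.exp(logm) / np.exp(logm).sum()
    np.testing.assert_allclose(implied, props, rtol=1e-10)


def test_plant_betas_inversion_identity():
    cfg = GeneratorConfig()
    betas = plant_betas(cfg)
    assert betas[LEISURE_ILR_COLUMNS[0]] < 0  # protective leisure target
    # round trip: the planted coefficients reproduce the target HRs exactly
    fit = toy_fit(
        betas.to_numpy(), var=np.zeros((len(betas), len(betas))), names=list(betas.index)
    )
    for domain, parts, target in [
        ("work", cfg.work_mean_minutes, cfg.work_hr_target),
        ("leisure", cfg.leisure_mean_minutes, cfg.leisure_hr_target),
    ]:
        base = DomainComposition(domain, tuple(parts))
        new = reallocate(base, "mvpa", cfg.reallocation_minutes).new_comp
        hr, _, _ = predict_hr(fit, base, new)
        assert hr == pytest.approx(target, rel=1e-12)
    # null targets plant null coefficients
    null = plant_betas(GeneratorConfig(work_hr_target=1.0, leisure_hr_target=1.0))
    np.testing.assert_allclose(null.to_numpy(), 0.0, atol=1e-15)


def test_generator_reproducible_from_seed():
    cfg = GeneratorConfig(n_workers=30)
    a = generate_cohort(cfg, seed=3)
    b = generate_cohort(cfg, seed=3)
    for x, y in [(a.days, b.days), (a.bed, b.bed), (a.covariates, b.covariates),
                 (a.register, b.register)]:
        pd.testing.assert_frame_equal(x, y)
    c = generate_cohort(cfg, seed=4)
    assert not a.register.equals(c.register)


def test_generated_day_tables_are_consistent(small_cohort):
    _, cohort = small_cohort
    # all class minutes non-negative, strictly positive behavior totals
    assert (cohort.days["minutes"] >= 0).all()
    # wear columns equal the summed class minutes per worker-day-domain
    sums = (
        cohort.days.groupby(["worker_id", "day_index", "domain"])["minutes"]
        .sum()
        .unstack("domain")
    )
    merged = cohort.bed.set_index(["worker_id", "day_index"])
    np.testing.assert_allclose(merged["wear_work_min"], sums["work"], rtol=1e-9)
    np.testing.assert_allclose(merged["wear_leisure_min"], sums["leisure"], rtol=1e-9)
    assert (cohort.bed["time_in_bed_min"] > 0).all()


def test_incidence_and_censoring_near_configured_rates():
    cfg = GeneratorConfig()
    cohort = generate_cohort(cfg, seed=5)
    assert cohort.truth["event_fraction"] == pytest.approx(0.21, abs=0.04)
    assert cohort.truth["censored_fraction_non_event"] == pytest.approx(0.05, abs=0.025)


def test_register_reflects_planted_events_and_decoys(small_cohort):
    _, cohort = small_cohort
    outcomes = outcomes_from_register(cohort.register, cohort.covariates).set_index("worker_id")
    truth_event = pd.Series(cohort.truth["event"], index=cohort.covariates["worker_id"])
    truth_cens = pd.Series(cohort.truth["censored"], index=cohort.covariates["worker_id"])
    # every planted event is detected at its planted start week; decoy spells
    # never produce an event; planted censoring is recovered
    pd.testing.assert_series_equal(
        outcomes["event"], truth_event, check_names=False
    )
    week = pd.Series(cohort.truth["event_week"], index=truth_event.index)
    assert (outcomes.loc[truth_event, "time_weeks"] == week[truth_event]).all()
    recovered = outcomes.loc[~truth_event, "censor_reason"] != "admin_end"
    assert (recovered == truth_cens[~truth_event]).all()


def test_null_configuration_centers_fitted_betas_on_zero():
    cfg = GeneratorConfig(
        n_workers=250, work_hr_target=1.0, leisure_hr_target=1.0,
        days_per_worker=1, decoy_5week_spell_prob=0.0,
    )
    from codaltsa.survival import CoxPH

    wb, lb = sbp_basis(4).contrast_matrix, sbp_basis(5).contrast_matrix
    coefs = []
    for s in range(12):
        c = generate_cohort(cfg, seed=100 + s)
        t = c.truth
        X = pd.DataFrame(
            np.hstack([np.log(t["work_parts"]) @ wb.T, np.log(t["leisure_parts"]) @ lb.T]),
            columns=WORK_ILR_COLUMNS + LEISURE_ILR_COLUMNS,
        )
        tw = np.where(t["event"], t["event_week"], 212)
        f = CoxPH().fit(X, np.column_stack([tw, t["event"]]))
        coefs.append(f.coef_[[WORK_ILR_COLUMNS[0], LEISURE_ILR_COLUMNS[0]]])
    mean = pd.concat(coefs, axis=1).mean(axis=1)
    se = pd.concat(coefs, axis=1).std(axis=1) / np.sqrt(len(coefs))
    assert (mean.abs() < 3 * se + 0.05).all()


def test_write_fixture_suite_deterministic(tmp_path):
    cfg = GeneratorConfig(n_workers=12, days_per_worker=2)
    m1 = write_fixture_suite(tmp_path / "a", cfg, seeds=(0,))
    m2 = write_fixture_suite(tmp_path / "b", cfg, seeds=(0,))
    assert m1 == m2  # byte-identical files, identical hashes
    files = [p for p in (tmp_path / "a").rglob("*") if p.is_file() and p.name != "manifest.json"]
    assert len(m1) == len(files)
    assert (tmp_path / "a" / "register_boundary_synthetic.csv").exists()


def test_config_validation():
    with pytest.raises(ValueError, match="sum"):
        GeneratorConfig(work_mean_minutes=(10, 10, 10, 10)).validate()
    with pytest.raises(ValueError, match="concentration"):
        GeneratorConfig(concentration=-1).validate()
    with pytest.raises(ValueError, match="positive"):
        plant_betas(GeneratorConfig(work_hr_target=-2.0))
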
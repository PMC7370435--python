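import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from codaltsa.compositions import DomainComposition, ilr, sbp_basis
from codaltsa.substitution import (
    SubstitutionCurve,
    default_grid,
    predict_hr,
    reallocate,
    substitution_curve,
)
from codaltsa.survival import ConvergenceError, LEISURE_ILR_COLUMNS, WORK_ILR_COLUMNS
from test_survival import toy_fit

WORK_MEAN = DomainComposition("work", (64.0, 176.0, 137.0, 74.0))
ALL_COLUMNS = WORK_ILR_COLUMNS + LEISURE_ILR_COLUMNS


def model_fit(work_beta1=0.0, leisure_beta1=0.0, var_scale=0.0):
    beta = pd.Series(0.0, index=ALL_COLUMNS)
    beta[WORK_ILR_COLUMNS[0]] = work_beta1
    beta[LEISURE_ILR_COLUMNS[0]] = leisure_beta1
    var = var_scale * np.eye(len(ALL_COLUMNS))
    return toy_fit(beta.to_numpy(), var=var, names=ALL_COLUMNS)


def test_reallocate_zero_delta_is_identity():
    r = reallocate(WORK_MEAN, "mvpa", 0.0)
    np.testing.assert_allclose(r.new_comp.values, WORK_MEAN.values)


def test_reallocate_proportional_removal_arithmetic():
    r = reallocate(WORK_MEAN, "mvpa", 20.0)
    rest = 176.0 + 137.0 + 74.0  # 387
    expected = [84.0, 176 - 20 * 176 / rest, 137 - 20 * 137 / rest, 74 - 20 * 74 / rest]
    np.testing.assert_allclose(r.new_comp.values, expected, rtol=1e-12)
    np.testing.assert_allclose(r.new_comp.values, [84.0, 166.90, 129.92, 70.18], atol=0.005)


def test_reallocate_preserves_non_focal_ratios_and_total():
    r = reallocate(WORK_MEAN, "sedentary", -35.0)
    base, new = WORK_MEAN.values, r.new_comp.values
    assert new.sum() == pytest.approx(base.sum(), rel=1e-14)
    others = [0, 2, 3]
    ratios_base = base[others] / base[others].sum()
    ratios_new = new[others] / new[others].sum()
    np.testing.assert_allclose(ratios_new, ratios_base, rtol=1e-12)


def test_reallocate_infeasible_deltas():
    with pytest.raises(ValueError, match="bound"):
        reallocate(WORK_MEAN, "mvpa", -64.0)
    with pytest.raises(ValueError, match="bound"):
        reallocate(WORK_MEAN, "mvpa", 400.0)
    with pytest.raises(ValueError, match="focal"):
        reallocate(WORK_MEAN, "napping", 5.0)


@given(
    st.lists(st.floats(min_value=5.0, max_value=500.0), min_size=4, max_size=4),
    st.floats(min_value=-4.9, max_value=4.9),
)
def test_reallocate_conserves_total_exactly(parts, delta):
    base = DomainComposition("work", tuple(parts))
    new = reallocate(base, "mvpa", delta).new_comp
    assert new.total_minutes == pytest.approx(base.total_minutes, rel=1e-12)
    assert all(v > 0 for v in new.minutes)


def test_predict_hr_identity_at_zero_reallocation():
    fit = model_fit(work_beta1=0.7, var_scale=0.1)
    hr, lo, hi = predict_hr(fit, WORK_MEAN, WORK_MEAN)
    assert (hr, lo, hi) == (1.0, 1.0, 1.0)


def test_predict_hr_closed_form_single_coefficient():
    # beta = ln 2 on the first work ilr, zero covariance: an ilr shift of
    # exactly +1 on that coordinate doubles the hazard
    fit = model_fit(work_beta1=np.log(2.0))
    basis = sbp_basis(4)
    z = ilr(WORK_MEAN.values, basis)
    z_new = z.copy()
    z_new[0] += 1.0
    from codaltsa.compositions import inverse_ilr

    new = WORK_MEAN.with_values(inverse_ilr(z_new, basis, WORK_MEAN.total_minutes))
    hr, lo, hi = predict_hr(fit, WORK_MEAN, new)
    assert hr == pytest.approx(2.0, rel=1e-9)
    assert lo == pytest.approx(hr) and hi == pytest.approx(hr)


def test_predict_hr_validates_inputs():
    fit = model_fit()
    leisure = DomainComposition("leisure", (33.0, 311.0, 77.0, 41.0, 429.0))
    with pytest.raises(ValueError, match="domain"):
        predict_hr(fit, WORK_MEAN, leisure)
    with pytest.raises(ValueError, match="total"):
        predict_hr(fit, WORK_MEAN, WORK_MEAN.closed(500.0))
    with pytest.raises(ConvergenceError):
        bad = model_fit()
        bad.converged = False
        predict_hr(bad, WORK_MEAN, WORK_MEAN)


def test_predict_hr_reciprocity_for_small_reallocations():
    fit = model_fit(work_beta1=0.5, leisure_beta1=-0.4)
    for delta in (1.0, 2.5, 5.0):
        up = reallocate(WORK_MEAN, "mvpa", delta).new_comp
        dn = reallocate(WORK_MEAN, "mvpa", -delta).new_comp
        prod = predict_hr(fit, WORK_MEAN, up)[0] * predict_hr(fit, WORK_MEAN, dn)[0]
        assert prod == pytest.approx(1.0, abs=0.01)


def test_ci_width_grows_with_reallocation_size():
    fit = model_fit(work_beta1=0.3, var_scale=0.05)
    widths = []
    for delta in (0.0, 5.0, 10.0, 20.0, 30.0):
        new = reallocate(WORK_MEAN, "mvpa", delta).new_comp
        hr, lo, hi = predict_hr(fit, WORK_MEAN, new)
        assert lo <= hr <= hi
        widths.append(np.log(hi) - np.log(lo))
    assert all(b >= a for a, b in zip(widths, widths[1:]))


def test_substitution_curve_grid_and_monotonicity():
    fit = model_fit(work_beta1=0.5, var_scale=0.02)
    curve = substitution_curve(fit, WORK_MEAN, "mvpa")
    df = curve.to_frame()
    assert list(df["delta_min"]) == default_grid()
    at_zero = df[df["delta_min"] == 0].iloc[0]
    assert at_zero["hr"] == pytest.approx(1.0)
    # single positive first-pivot coefficient: hr monotone in delta
    assert df["hr"].is_monotonic_increasing
    # +-5 min sits closer to 1 than +-20 min
    hr = df.set_index("delta_min")["hr"]
    assert abs(np.log(hr[5.0])) < abs(np.log(hr[20.0]))
    assert abs(np.log(hr[-5.0])) < abs(np.log(hr[-20.0]))


def test_substitution_curve_drops_infeasible_points(caplog):
    fit = model_fit(work_beta1=0.5)
    with caplog.at_level("WARNING"):
        curve = substitution_curve(fit, WORK_MEAN, "mvpa", grid=[-100.0, 0.0, 10.0])
    assert [g[0] for g in curve.grid] == [0.0, 10.0]
    assert any("infeasible" in r.message for r in caplog.records)


def test_curve_frame_layout():
    fit = model_fit(leisure_beta1=-0.5)
    leisure = DomainComposition("leisure", (33.0, 311.0, 77.0, 41.0, 429.0))
    df = substitution_curve(fit, leisure, "mvpa").to_frame()
    assert list(df.columns) == ["domain", "focal_part", "delta_min", "hr", "ci_low", "ci_high"]
    assert (df["domain"] == "leisure").all()
    assert (df["ci_low"] <= df["hr"]).all() and (df["hr"] <= df["ci_high"]).all()
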
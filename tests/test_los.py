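"""LOS pmf/survival conversions and the expected-census operator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mixplan as mp
from mixplan.los import LOSPmf
from mixplan.instance import LOSSurvival


# -- conversions -------------------------------------------------------------

def test_survival_from_pmf_simple():
    surv = mp.survival_from_pmf(LOSPmf((0.5, 0.5)))
    assert surv.values == (1.0, 0.5)


def test_survival_degenerate_one_day():
    surv = mp.survival_from_pmf(LOSPmf((1.0, 0.0, 0.0)))
    assert surv.values == (1.0, 0.0, 0.0)


def test_pmf_from_survival_simple():
    pmf = mp.pmf_from_survival(LOSSurvival((1.0, 0.5)))
    assert pmf.values == (0.5, 0.5)


def test_pmf_from_base_curve_matches_successive_differences(base):
    # day-5 mass of the third patient class: survival drops 0.93 -> 0.90
    pmf = mp.pmf_from_survival(base.patient_type("III").survival)
    assert pmf.values[4] == pytest.approx(0.03)


def test_base_curve_roundtrip(base):
    for pt in base.patient_types:
        back = mp.survival_from_pmf(mp.pmf_from_survival(pt.survival))
        np.testing.assert_allclose(back.as_array(), pt.survival.as_array(), atol=1e-12)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        mp.pmf_from_survival(LOSSurvival((1.0, 0.5, 0.7)))
    with pytest.raises(ValueError):
        mp.survival_from_pmf(LOSPmf((0.8, 0.4)))
    with pytest.raises(ValueError):
        mp.survival_from_pmf(LOSPmf((-0.1, 0.5)))


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
@settings(deadline=None)
def test_roundtrip_property(diffs):
    # build a valid survival curve from arbitrary nonnegative drops
    v = np.concatenate([[1.0], 1.0 - np.cumsum(diffs)])
    v = np.clip(v, 0.0, 1.0)
    v = np.minimum.accumulate(v)
    surv = LOSSurvival(tuple(v))
    back = mp.survival_from_pmf(mp.pmf_from_survival(surv))
    np.testing.assert_allclose(back.as_array(), surv.as_array(), atol=1e-9)


# -- expected LOS ------------------------------------------------------------

@pytest.mark.parametrize("values, expected", [
    ((1.0, 0.0, 0.0), 1.0),
    (tuple([1.0] * 28), 28.0),
])
def test_expected_los_degenerate(values, expected):
    assert mp.expected_los(LOSSurvival(values)) == expected


def test_expected_los_base_type_I(base):
    # sum of the 28 stored survival values of the first patient class
    assert mp.expected_los(base.patient_type("I").survival) == pytest.approx(12.06)


# -- census ------------------------------------------------------------------

def test_census_single_cohort():
    x = np.array([[2.0, 0.0, 0.0]])
    M = mp.census_matrix(x, [LOSSurvival((1.0, 0.5, 0.0))])
    np.testing.assert_allclose(M, [[2.0, 1.0, 0.0]])


def test_census_empty_hospital(base):
    x = np.zeros((3, base.horizon))
    M = mp.census_matrix(x, [pt.survival for pt in base.patient_types])
    assert np.all(M == 0)


def test_census_day_one_equals_admissions(base):
    rng = np.random.default_rng(7)
    x = rng.integers(0, 10, size=(3, base.horizon)).astype(float)
    M = mp.census_matrix(x, [pt.survival for pt in base.patient_types])
    np.testing.assert_allclose(M[:, 0], x[:, 0])


def test_census_linearity(base):
    rng = np.random.default_rng(11)
    survs = [pt.survival for pt in base.patient_types]
    x = rng.integers(0, 8, size=(3, 28)).astype(float)
    y = rng.integers(0, 8, size=(3, 28)).astype(float)
    lhs = mp.census_matrix(2.0 * x + 3.0 * y, survs)
    rhs = 2.0 * mp.census_matrix(x, survs) + 3.0 * mp.census_matrix(y, survs)
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def test_census_shift_of_single_day_cohort(base):
    # a cohort admitted on day u traces the survival curve shifted to day u
    surv = base.patient_type("II").survival
    x = np.zeros((1, 28))
    x[0, 10] = 5
    M = mp.census_matrix(x, [surv])
    np.testing.assert_allclose(M[0, 10:], 5 * surv.as_array()[:18])
    assert np.all(M[0, :10] == 0)


def test_census_conservation(base):
    # total patient-days equal admissions times the horizon-truncated mean
    # stay of each cohort, hence never exceed admissions times expected LOS
    rng = np.random.default_rng(3)
    x = rng.integers(0, 10, size=(3, 28)).astype(float)
    survs = [pt.survival for pt in base.patient_types]
    M = mp.census_matrix(x, survs)
    for i, pt in enumerate(base.patient_types):
        s = pt.survival.as_array()
        truncated = np.array([s[: 28 - u].sum() for u in range(28)])
        assert M[i].sum() == pytest.approx(float(x[i] @ truncated))
        assert M[i].sum() <= x[i].sum() * mp.expected_los(pt.survival) + 1e-9


def test_census_dimension_mismatch(base):
    with pytest.raises(ValueError):
        mp.census_matrix(np.zeros((2, 28)), [base.patient_types[0].survival])
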
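"""Core conversion algorithm: worked examples and algebraic properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctximpact import (
    ConversionInputs,
    ValidationError,
    conversion_factor,
    estimate_beneficiaries,
    estimate_unique_patients,
    usable_ctx,
)

# parameter strategies spanning the algorithm's legal domain
ctx_st = st.floats(min_value=0.0, max_value=1e8, allow_nan=False)
d_st = st.floats(min_value=0.0, max_value=1.0)
cbar_st = st.floats(min_value=0.01, max_value=50.0)
r_st = st.floats(min_value=1.0, max_value=50.0)


@pytest.mark.parametrize(
    "cbar, r, expected",
    [
        (1.0, 1.0, 1.0),
        (288 / 843, 843 / 100, 100 / 288),  # pilot clinic: 0.34722...
        (2.47, 1395 / 378, 378 / (2.47 * 1395)),  # ~0.10970
    ],
)
def test_conversion_factor_examples(cbar, r, expected):
    assert conversion_factor(cbar, r) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "ctx, d, expected",
    [(13_319, 0.0, 13_319.0), (13_319, 0.24, 10_122.44), (100, 1.0, 0.0)],
)
def test_usable_ctx_examples(ctx, d, expected):
    assert usable_ctx(ctx, d) == pytest.approx(expected)


def test_pilot_point_estimates():
    """With the pilot clinic's printed inputs the estimator gives ~4,625 at
    zero wastage and ~3,515 at the 24% base case."""
    base = dict(ctx_per_visit=288 / 843, revisit_rate=843 / 100)
    no_waste = estimate_unique_patients(ConversionInputs(13_319, 0.0, **base))
    revised = estimate_unique_patients(ConversionInputs(13_319, 0.24, **base))
    assert no_waste == pytest.approx(4624.6528, abs=0.01)
    assert revised == pytest.approx(3514.7361, abs=0.01)


def test_zero_donation_zero_patients():
    assert estimate_unique_patients(ConversionInputs(0, 0.5, 2.0, 3.0)) == 0.0


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(ctx_donated=-1, destruction_rate=0, ctx_per_visit=1, revisit_rate=1),
        dict(ctx_donated=1, destruction_rate=1.5, ctx_per_visit=1, revisit_rate=1),
        dict(ctx_donated=1, destruction_rate=0, ctx_per_visit=0, revisit_rate=1),
        dict(ctx_donated=1, destruction_rate=0, ctx_per_visit=1, revisit_rate=0.5),
    ],
)
def test_domain_errors(kwargs):
    with pytest.raises(ValidationError):
        ConversionInputs(**kwargs)


def test_conversion_factor_domain_errors():
    with pytest.raises(ValidationError):
        conversion_factor(0.0, 2.0)
    with pytest.raises(ValidationError):
        conversion_factor(2.0, 0.9)


@settings(derandomize=True, max_examples=200)
@given(ctx=ctx_st, d=d_st, cbar=cbar_st, r=r_st, k=st.floats(min_value=0.0, max_value=100.0))
def test_scale_equivariance(ctx, d, cbar, r, k):
    """Doubling the donation doubles the estimate: estimate(kC) = k estimate(C)."""
    base = estimate_unique_patients(ConversionInputs(ctx, d, cbar, r))
    scaled = estimate_unique_patients(ConversionInputs(k * ctx, d, cbar, r))
    assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-9)


@settings(derandomize=True, max_examples=200)
@given(d=st.floats(min_value=0.0, max_value=0.99), cbar=cbar_st, r=r_st,
       bump=st.floats(min_value=1e-3, max_value=0.5))
def test_monotonicity(d, cbar, r, bump):
    """The estimate strictly decreases as wastage, prescribing intensity or
    revisit frequency increase (donation fixed and positive)."""
    C = 10_000.0
    base = estimate_unique_patients(ConversionInputs(C, d, cbar, r))
    assert estimate_unique_patients(ConversionInputs(C, min(d + bump, 1.0), cbar, r)) < base
    assert estimate_unique_patients(ConversionInputs(C, d, cbar * (1 + bump), r)) < base
    assert estimate_unique_patients(ConversionInputs(C, d, cbar, r * (1 + bump))) < base


@settings(derandomize=True, max_examples=200)
@given(cbar=cbar_st, r=r_st)
def test_conversion_factor_identity(cbar, r):
    assert abs(conversion_factor(cbar, r) * cbar * r - 1.0) < 1e-12


@settings(derandomize=True, max_examples=200)
@given(ctx=ctx_st, d=d_st, cbar=cbar_st, r=r_st)
def test_estimator_is_usable_ctx_times_factor(ctx, d, cbar, r):
    est = estimate_unique_patients(ConversionInputs(ctx, d, cbar, r))
    assert est == usable_ctx(ctx, d) * conversion_factor(cbar, r)


class TestEstimateBeneficiaries:
    def test_all_zero(self):
        zero = ConversionInputs(0, 0.0, 2.0, 2.0)
        est = estimate_beneficiaries(zero, zero, conditions_per_patient=1.5)
        assert est.total_beneficiaries == est.unique_patients == 0.0

    def test_no_comorbidity_means_unique_equals_total(self):
        inputs = ConversionInputs(500, 0.1, 2.0, 2.0)
        est = estimate_beneficiaries(inputs, inputs, conditions_per_patient=1.0)
        assert est.unique_patients == est.total_beneficiaries

    def test_hand_computed_strata(self):
        chronic = ConversionInputs(1000, 0.0, 2.0, 4.0)
        acute = ConversionInputs(1000, 0.0, 2.0, 1.0)
        est = estimate_beneficiaries(chronic, acute, conditions_per_patient=1.25)
        assert est.chronic_beneficiaries == pytest.approx(125.0)
        assert est.acute_beneficiaries == pytest.approx(500.0)
        assert est.total_beneficiaries == pytest.approx(625.0)
        assert est.unique_patients == pytest.approx(500.0)

    def test_strata_sum_exactly(self):
        chronic = ConversionInputs(777, 0.12, 1.7, 3.3)
        acute = ConversionInputs(1234, 0.12, 2.9, 1.4)
        est = estimate_beneficiaries(chronic, acute, conditions_per_patient=1.3)
        assert est.chronic_beneficiaries + est.acute_beneficiaries == est.total_beneficiaries

    def test_rejects_sub_unit_conditions_per_patient(self):
        inputs = ConversionInputs(100, 0.0, 2.0, 2.0)
        with pytest.raises(ValidationError):
            estimate_beneficiaries(inputs, inputs, conditions_per_patient=0.9)
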
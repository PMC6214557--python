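"""Country and region extrapolation of pooled parameters."""

import pytest

from ctximpact import (
    ConfigurationError,
    CountryParameters,
    ValidationError,
    load_table1_fixture,
    load_table2_fixture,
    project_country,
    project_region,
)


def params_from_sample_row(row, conditions_per_patient=1.15) -> CountryParameters:
    """Country parameters straight from a published sample-table row:
    printed destruction and CTX/visit, revisit = visits / unique patients."""
    return CountryParameters(
        country=row.country,
        destruction_rate=row.destruction_rate,
        ctx_per_visit=row.ctx_per_visit_mean,
        ctx_per_visit_se=(row.ctx_ci_high - row.ctx_ci_low) / (2 * 1.96),
        revisit_rate=row.revisit_rate,
        revisit_rate_se=0.0,
        conditions_per_patient=conditions_per_patient,
    )


@pytest.fixture(scope="module")
def tables():
    t1 = {r.country: r for r in load_table1_fixture()}
    t2 = {r.country: r for r in load_table2_fixture()}
    return t1, t2


@pytest.mark.parametrize(
    "country, expected",
    [("Philippines", 114_376), ("Romania", 2_014)],
)
def test_country_point_estimates_from_published_inputs(tables, country, expected):
    t1, t2 = tables
    proj = project_country(
        t2[country].total_ctx_donated,
        t2[country].chronic_ctx_donated,
        t2[country].acute_ctx_donated,
        params_from_sample_row(t1[country]),
        n_facilities=t2[country].n_facilities,
    )
    assert proj.estimate.unique_patients == pytest.approx(expected, abs=1.0)


def test_all_countries_inside_published_credible_intervals(tables):
    """For every study country, unique patients recomputed from the sample
    table's parameters and the projection table's CTX totals fall inside the
    published 95% credible interval."""
    t1, t2 = tables
    for country in t1:
        proj = project_country(
            t2[country].total_ctx_donated,
            t2[country].chronic_ctx_donated,
            t2[country].acute_ctx_donated,
            params_from_sample_row(t1[country]),
        )
        assert (
            t2[country].unique_ci_low
            <= proj.estimate.unique_patients
            <= t2[country].unique_ci_high
        ), country


def test_zero_ctx_gives_zero_projection(tables):
    t1, _ = tables
    proj = project_country(0, 0, 0, params_from_sample_row(t1["Peru"]))
    est = proj.estimate
    assert est.unique_patients == est.total_beneficiaries == 0.0


def test_negative_ctx_rejected(tables):
    t1, _ = tables
    with pytest.raises(ValidationError):
        project_country(-5, 0, -5, params_from_sample_row(t1["Peru"]))


def test_stratum_ctx_must_sum_to_total(tables):
    t1, _ = tables
    with pytest.raises(ValidationError):
        project_country(1000, 100, 100, params_from_sample_row(t1["Peru"]))


def _simple_params(country, cbar, r, d=0.1, cpp=1.2):
    return CountryParameters(
        country=country, destruction_rate=d,
        ctx_per_visit=cbar, ctx_per_visit_se=0.0,
        revisit_rate=r, revisit_rate_se=0.0,
        conditions_per_patient=cpp,
    )


class TestProjectRegion:
    def test_single_country_region_scales_to_region_ctx(self):
        """A one-country region is that country's parameterization applied to
        the region's (larger) CTX total."""
        p = _simple_params("A", cbar=2.0, r=2.0)
        cp = project_country(1000, 600, 400, p)
        region = project_region(
            "R", [cp], {"total": 2000, "chronic": 1200, "acute": 800}
        )
        assert region.estimate.unique_patients == pytest.approx(
            2 * cp.estimate.unique_patients
        )
        assert region.extrapolated_beyond_sample

    def test_equal_weights_average_parameters(self):
        a = project_country(1000, 500, 500, _simple_params("A", cbar=2.0, r=2.0))
        b = project_country(1000, 500, 500, _simple_params("B", cbar=4.0, r=2.0))
        region = project_region("R", [a, b], {"total": 2000, "chronic": 1000, "acute": 1000})
        assert region.params.ctx_per_visit == pytest.approx(3.0)
        assert not region.extrapolated_beyond_sample

    def test_weights_concentrated_on_one_country(self):
        """With all CTX weight on one member, the pooled parameters are that
        country's own."""
        a = project_country(5000, 2500, 2500, _simple_params("A", cbar=2.0, r=3.0))
        b = project_country(0, 0, 0, _simple_params("B", cbar=9.0, r=9.0))
        region = project_region("R", [a, b], {"total": 5000, "chronic": 2500, "acute": 2500})
        assert region.params.ctx_per_visit == pytest.approx(2.0)
        assert region.params.revisit_rate == pytest.approx(3.0)
        assert region.estimate.unique_patients == pytest.approx(a.estimate.unique_patients)

    def test_care_level_mix_apportions_beneficiaries(self):
        a = project_country(1000, 500, 500, _simple_params("A", cbar=2.0, r=2.0))
        region = project_region(
            "R", [a], {"total": 1000, "chronic": 500, "acute": 500},
            care_level_mix={"outpatient": 0.76, "inpatient": 0.24},
        )
        by = region.beneficiaries_by_care_level
        assert sum(by.values()) == pytest.approx(region.estimate.total_beneficiaries)
        assert by["outpatient"] == pytest.approx(0.76 * region.estimate.total_beneficiaries)

    def test_mix_must_sum_to_one(self):
        a = project_country(1000, 500, 500, _simple_params("A", cbar=2.0, r=2.0))
        with pytest.raises(ValidationError):
            project_region("R", [a], {"total": 1000, "chronic": 500, "acute": 500},
                           care_level_mix={"outpatient": 0.7, "inpatient": 0.2})

    def test_empty_region_rejected(self):
        with pytest.raises(ConfigurationError):
            project_region("R", [], {"total": 0, "chronic": 0, "acute": 0})

    def test_region_ctx_below_member_sum_rejected(self):
        a = project_country(1000, 500, 500, _simple_params("A", cbar=2.0, r=2.0))
        with pytest.raises(ConfigurationError):
            project_region("R", [a], {"total": 500, "chronic": 250, "acute": 250})


def test_chronic_beneficiary_points_sum_to_study_total():
    """Per-country chronic beneficiary point estimates in the published table
    sum exactly to the study's reported chronic total."""
    rows = load_table2_fixture()
    assert sum(r.chronic_beneficiaries for r in rows) == 181_665
    # the other reported study totals carry a one-unit rounding discrepancy
    assert abs(sum(r.unique_patients for r in rows) - 700_377) <= 1
    assert abs(sum(r.total_beneficiaries for r in rows) - 1_946_659) <= 1
    assert abs(sum(r.acute_beneficiaries for r in rows) - 1_764_994) <= 1
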
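import datetime as dt

import pytest

from ctximpact import (
    DiseaseType,
    CareLevel,
    FacilityProfile,
    PilotParameters,
    SyntheticConfig,
    VisitRecord,
    generate_study,
)

D = dt.date(2015, 6, 1)


def visit(pid, dtype=DiseaseType.ACUTE, meds=2, ctx=1, fid="F001", day=0):
    return VisitRecord(
        patient_id=pid,
        facility_id=fid,
        visit_date=D + dt.timedelta(days=day),
        disease_type=dtype,
        n_medications=meds,
        n_ctx=ctx,
    )


@pytest.fixture
def pilot() -> PilotParameters:
    return PilotParameters()


@pytest.fixture
def tiny_records():
    """Hand-checkable facility sample: 3 patients, 4 visits, 8 meds, 7 CTX.

    Patient A: 2 visits (2 meds / 1 CTX each, chronic); B: 1 visit
    (3 meds / 3 CTX, acute); C: 1 visit (1 med / 2 CTX, acute).
    Pooled means: meds/visit = 2.00, CTX/visit = 1.75, revisit = 4/3.
    """
    return [
        visit("A", DiseaseType.CHRONIC, meds=2, ctx=1, day=0),
        visit("A", DiseaseType.CHRONIC, meds=2, ctx=1, day=30),
        visit("B", DiseaseType.ACUTE, meds=3, ctx=3, day=1),
        visit("C", DiseaseType.ACUTE, meds=1, ctx=2, day=2),
    ]


@pytest.fixture
def tiny_profile():
    return FacilityProfile(
        facility_id="F001",
        country="Synthetica",
        care_level=CareLevel.PRIMARY,
        total_patients=3,
        total_visits=4,
        destruction_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_study():
    """A deterministic 2-facility synthetic study shared across tests."""
    config = SyntheticConfig(
        seed=20150101,
        n_facilities=2,
        patients_per_facility=400,
        chronic_fraction=0.4,
        comorbidity_rate=0.1,
        visit_mean_chronic=4.0,
        visit_mean_acute=2.0,
        ctx_mean=2.5,
        meds_mean=2.7,
        destruction_rate=0.08,
    )
    return config, generate_study(config)
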
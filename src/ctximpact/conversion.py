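"""Core algorithm: convert donated course treatments into patients served.

The estimator is a chain of three ratios. Let C be the number of course
treatments (CTX) donated, d the facility destruction rate (proportion of
medication destroyed, expired or unused), c̄ the mean CTX prescribed per
patient visit (the WHO/INRUD prescribing indicator), and r the revisit rate
(mean visits per unique patient over the observation window). Then

    usable CTX        U = C (1 - d)
    prescription visits supported      V = U / c̄
    unique patients served             P = V / r = U / (c̄ r)

The factor 1 / (c̄ r) is the *conversion factor*: patients served per usable
course treatment. A patient treated for several conditions benefits once per
condition, so *total beneficiaries* B (one per treated condition) are
estimated per chronic/acute stratum and summed; unique patients are B divided
by the mean number of conditions treated per patient.

Estimates are kept as reals throughout; rounding to whole patients is a
reporting concern (see :func:`report_round`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "ConversionInputs",
    "BeneficiaryEstimate",
    "conversion_factor",
    "usable_ctx",
    "estimate_unique_patients",
    "estimate_beneficiaries",
    "report_round",
]


@dataclass(frozen=True)
class ConversionInputs:
    """The four-parameter bundle the algorithm consumes.

    ctx_donated
        C, course treatments donated (>= 0).
    destruction_rate
        d, proportion of medication destroyed/expired/unused, in [0, 1].
    ctx_per_visit
        c̄, pooled mean course treatments per prescription visit (> 0).
    revisit_rate
        r, mean visits per unique patient over the window (>= 1).
    """

    ctx_donated: float
    destruction_rate: float
    ctx_per_visit: float
    revisit_rate: float

    def __post_init__(self) -> None:
        if self.ctx_donated < 0:
            raise ValidationError(f"ctx_donated must be >= 0, got {self.ctx_donated}")
        if not 0.0 <= self.destruction_rate <= 1.0:
            raise ValidationError(
                f"destruction_rate must lie in [0, 1], got {self.destruction_rate}"
            )
        if self.ctx_per_visit <= 0:
            raise ValidationError(f"ctx_per_visit must be > 0, got {self.ctx_per_visit}")
        if self.revisit_rate < 1:
            raise ValidationError(f"revisit_rate must be >= 1, got {self.revisit_rate}")


@dataclass(frozen=True)
class BeneficiaryEstimate:
    """Point estimates of unique patients and per-stratum beneficiaries.

    ``total_beneficiaries`` counts treated conditions (chronic + acute,
    exactly); ``unique_patients`` divides out ``conditions_per_patient``,
    the mean number of conditions treated per patient, so
    total >= unique always.
    """

    unique_patients: float
    total_beneficiaries: float
    chronic_beneficiaries: float
    acute_beneficiaries: float
    conditions_per_patient: float

    def __post_init__(self) -> None:
        if not math.isclose(
            self.chronic_beneficiaries + self.acute_beneficiaries,
            self.total_beneficiaries,
            rel_tol=1e-9,
            abs_tol=1e-9,
        ):
            raise ValidationError("chronic + acute beneficiaries must equal the total")
        if self.total_beneficiaries < self.unique_patients - 1e-9:
            raise ValidationError("total beneficiaries cannot be fewer than unique patients")


def conversion_factor(ctx_per_visit: float, revisit_rate: float) -> float:
    """Patients served per usable course treatment: 1 / (c̄ · r).

    Strictly decreasing in both arguments.
    """
    if ctx_per_visit <= 0:
        raise ValidationError(f"ctx_per_visit must be > 0, got {ctx_per_visit}")
    if revisit_rate < 1:
        raise ValidationError(f"revisit_rate must be >= 1, got {revisit_rate}")
    return 1.0 / (ctx_per_visit * revisit_rate)


def usable_ctx(ctx_donated: float, destruction_rate: float) -> float:
    """Course treatments actually available after wastage: C (1 - d)."""
    if ctx_donated < 0:
        raise ValidationError(f"ctx_donated must be >= 0, got {ctx_donated}")
    if not 0.0 <= destruction_rate <= 1.0:
        raise ValidationError(f"destruction_rate must lie in [0, 1], got {destruction_rate}")
    return ctx_donated * (1.0 - destruction_rate)


def estimate_unique_patients(inputs: ConversionInputs) -> float:
    """Estimated unique patients served: C (1 - d) / (c̄ r).

    Linear in the donated quantity and equal, by construction, to
    ``usable_ctx(...) * conversion_factor(...)``.
    """
    return usable_ctx(inputs.ctx_donated, inputs.destruction_rate) * conversion_factor(
        inputs.ctx_per_visit, inputs.revisit_rate
    )


def estimate_beneficiaries(
    chronic_inputs: ConversionInputs,
    acute_inputs: ConversionInputs,
    conditions_per_patient: float,
) -> BeneficiaryEstimate:
    """Stratified estimate: beneficiaries per stratum, summed, then deduplicated.

    Each stratum's beneficiary count is the unique-patient estimator applied
    to that stratum's donations with stratum-specific prescribing and revisit
    parameters (a beneficiary is one treated condition, so within a stratum
    the two notions coincide). Unique patients are the total divided by
    ``conditions_per_patient`` (mean conditions treated per patient, >= 1).
    """
    if conditions_per_patient < 1:
        raise ValidationError(
            f"conditions_per_patient must be >= 1, got {conditions_per_patient}"
        )
    chronic = estimate_unique_patients(chronic_inputs)
    acute = estimate_unique_patients(acute_inputs)
    total = chronic + acute
    return BeneficiaryEstimate(
        unique_patients=total / conditions_per_patient,
        total_beneficiaries=total,
        chronic_beneficiaries=chronic,
        acute_beneficiaries=acute,
        conditions_per_patient=conditions_per_patient,
    )


def report_round(value: float) -> int:
    """Round-half-up to a whole number of patients, for reporting only."""
    return int(math.floor(value + 0.5))
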
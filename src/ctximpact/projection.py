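"""Country- and region-level extrapolation of facility-sample parameters.

A country projection applies the conversion algorithm to the country's total
donated course treatments using parameters pooled across its sample
facilities. Stratum-specific (chronic/acute) prescribing and revisit
parameters drive the per-stratum beneficiary estimates; unique patients are
additionally computed from total CTX with the overall (non-stratified)
parameters.

A region projection pools member-country parameters with weights
proportional to each country's CTX donations — the only weight observable
for every member — and applies the algorithm to the region's CTX total,
which may exceed the member sum when the region contains countries outside
the sample (those implicitly inherit the pooled parameters; the projection
carries an explicit flag when this extrapolation happens). Beneficiaries are
apportioned across facility care levels by a supplied mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aggregation import CountryParameters
from .conversion import BeneficiaryEstimate, ConversionInputs, estimate_unique_patients
from .errors import ConfigurationError, ValidationError

__all__ = ["CountryProjection", "RegionProjection", "project_country", "project_region"]


@dataclass(frozen=True)
class CountryProjection:
    country: str
    ctx_total: float
    ctx_chronic: float
    ctx_acute: float
    estimate: BeneficiaryEstimate
    params: CountryParameters
    n_facilities: int | None = None  # metadata only; never enters the estimator
    intervals: Mapping[str, tuple[float, float]] | None = None


@dataclass(frozen=True)
class RegionProjection:
    region: str
    countries: tuple[str, ...]
    ctx_total: float
    ctx_chronic: float
    ctx_acute: float
    params: CountryParameters
    estimate: BeneficiaryEstimate
    beneficiaries_by_care_level: Mapping[str, float] = field(default_factory=dict)
    extrapolated_beyond_sample: bool = False


def _stratified_estimate(
    ctx_total: float, ctx_chronic: float, ctx_acute: float, params: CountryParameters
) -> BeneficiaryEstimate:
    """Shared core of country and region projection."""
    if abs(ctx_chronic + ctx_acute - ctx_total) > max(1.0, 1e-9 * ctx_total):
        raise ValidationError(
            f"chronic ({ctx_chronic}) + acute ({ctx_acute}) CTX must equal total ({ctx_total})"
        )
    d = params.destruction_rate

    def stratum(ctx: float, cbar: float | None, rr: float | None) -> float:
        if ctx == 0:
            return 0.0
        cbar = cbar if cbar is not None else params.ctx_per_visit
        rr = rr if rr is not None else params.revisit_rate
        return estimate_unique_patients(
            ConversionInputs(ctx_donated=ctx, destruction_rate=d,
                             ctx_per_visit=cbar, revisit_rate=max(rr, 1.0))
        )

    chronic = stratum(ctx_chronic, params.chronic_ctx_per_visit, params.chronic_revisit_rate)
    acute = stratum(ctx_acute, params.acute_ctx_per_visit, params.acute_revisit_rate)
    if ctx_total == 0:
        unique = 0.0
    else:
        unique = estimate_unique_patients(
            ConversionInputs(ctx_donated=ctx_total, destruction_rate=d,
                             ctx_per_visit=params.ctx_per_visit,
                             revisit_rate=params.revisit_rate)
        )
    return BeneficiaryEstimate(
        unique_patients=unique,
        total_beneficiaries=chronic + acute,
        chronic_beneficiaries=chronic,
        acute_beneficiaries=acute,
        conditions_per_patient=max(params.conditions_per_patient, 1.0),
    )


def project_country(
    ctx_total: float,
    ctx_chronic: float,
    ctx_acute: float,
    params: CountryParameters,
    n_facilities: int | None = None,
) -> CountryProjection:
    """Project a country's donated CTX into beneficiaries served.

    ``n_facilities`` is descriptive metadata (how many facilities received
    donations); it does not affect the estimate.
    """
    if min(ctx_total, ctx_chronic, ctx_acute) < 0:
        raise ValidationError("CTX counts must be >= 0")
    est = _stratified_estimate(ctx_total, ctx_chronic, ctx_acute, params)
    return CountryProjection(
        country=params.country,
        ctx_total=ctx_total,
        ctx_chronic=ctx_chronic,
        ctx_acute=ctx_acute,
        estimate=est,
        params=params,
        n_facilities=n_facilities,
    )


def project_region(
    region: str,
    country_projections: Sequence[CountryProjection],
    region_ctx_totals: Mapping[str, float],
    care_level_mix: Mapping[str, float] | None = None,
) -> RegionProjection:
    """Project a region's CTX total using CTX-weighted member-country parameters.

    ``region_ctx_totals`` requires keys ``total``, ``chronic`` and ``acute``
    and must be at least the member-country sums; the surplus is attributed
    to unsampled countries, which inherit the pooled parameters.
    ``care_level_mix`` (proportions summing to 1) apportions total
    beneficiaries across facility care levels.
    """
    if not country_projections:
        raise ConfigurationError(f"region {region!r} has no member country projections")
    for key in ("total", "chronic", "acute"):
        if key not in region_ctx_totals:
            raise ConfigurationError(f"region_ctx_totals missing key {key!r}")
    member_total = sum(p.ctx_total for p in country_projections)
    if region_ctx_totals["total"] + 1e-9 < member_total:
        raise ConfigurationError(
            f"region CTX total ({region_ctx_totals['total']}) below member sum ({member_total})"
        )
    if care_level_mix is not None:
        if abs(sum(care_level_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("care_level_mix proportions must sum to 1")

    weights = np.asarray([p.ctx_total for p in country_projections], dtype=float)
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()

    def pooled(getter, default=None):
        vals = [getter(p.params) for p in country_projections]
        if any(v is None for v in vals):
            vals = [v if v is not None else default for v in vals]
            if any(v is None for v in vals):
                return None
        return float(np.dot(weights, np.asarray(vals, dtype=float)))

    params = CountryParameters(
        country=region,
        destruction_rate=pooled(lambda p: p.destruction_rate),
        ctx_per_visit=pooled(lambda p: p.ctx_per_visit),
        ctx_per_visit_se=float(
            np.sqrt(np.dot(weights**2,
                           np.asarray([p.params.ctx_per_visit_se for p in country_projections]) ** 2))
        ),
        revisit_rate=pooled(lambda p: p.revisit_rate),
        revisit_rate_se=float(
            np.sqrt(np.dot(weights**2,
                           np.asarray([p.params.revisit_rate_se for p in country_projections]) ** 2))
        ),
        conditions_per_patient=pooled(lambda p: p.conditions_per_patient),
        chronic_ctx_per_visit=pooled(lambda p: p.chronic_ctx_per_visit,
                                     default=pooled(lambda p: p.ctx_per_visit)),
        chronic_revisit_rate=pooled(lambda p: p.chronic_revisit_rate,
                                    default=pooled(lambda p: p.revisit_rate)),
        acute_ctx_per_visit=pooled(lambda p: p.acute_ctx_per_visit,
                                   default=pooled(lambda p: p.ctx_per_visit)),
        acute_revisit_rate=pooled(lambda p: p.acute_revisit_rate,
                                  default=pooled(lambda p: p.revisit_rate)),
        n_facilities_sampled=sum(p.params.n_facilities_sampled for p in country_projections),
    )

    est = _stratified_estimate(
        region_ctx_totals["total"], region_ctx_totals["chronic"],
        region_ctx_totals["acute"], params,
    )
    by_level = (
        {level: share * est.total_beneficiaries for level, share in care_level_mix.items()}
        if care_level_mix
        else {}
    )
    return RegionProjection(
        region=region,
        countries=tuple(p.country for p in country_projections),
        ctx_total=region_ctx_totals["total"],
        ctx_chronic=region_ctx_totals["chronic"],
        ctx_acute=region_ctx_totals["acute"],
        params=params,
        estimate=est,
        beneficiaries_by_care_level=by_level,
        extrapolated_beyond_sample=region_ctx_totals["total"] > member_total + 1e-9,
    )
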
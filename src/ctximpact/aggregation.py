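"""Facility-level descriptive statistics and country-level parameter pooling.

This stage turns raw visit records into the parameters the conversion
algorithm needs: pooled CTX-per-visit prescribing indicators, revisit rates,
destruction rates and the mean number of conditions treated per patient.
Statistics are computed per facility, then averaged across a country's
sample facilities (unweighted by default; visit-weighted pooling is
available as a configuration switch).

Facilities that report a destruction rate of exactly 0% are treated as
under-reporting: a conservative analysis assumes some wastage always occurs,
so zero reports are replaced by the mean reported rate of designated proxy
countries from the same region (see :func:`impute_destruction`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .records import DiseaseType, FacilityProfile, VisitRecord

__all__ = [
    "StratumStats",
    "FacilitySummary",
    "CountryParameters",
    "RegionMap",
    "summarize_facility",
    "impute_destruction",
    "pool_country",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class StratumStats:
    """Prescribing statistics restricted to one disease stratum."""

    n_visits: int
    n_unique_patients: int
    ctx_per_visit: float
    ctx_se: float
    revisit_rate: float


@dataclass(frozen=True)
class FacilitySummary:
    """Descriptive statistics of one facility's visit-record sample.

    Means are pooled ratios over visits (total count / total visits), the
    convention of the WHO/INRUD prescribing indicators; standard errors are
    the sample SD of per-visit counts divided by sqrt(n_visits). The revisit
    rate is total visits / unique patients, hence always >= 1. Patients seen
    for both a chronic and an acute condition appear in both stratum counts
    but once in ``n_unique_patients``.
    """

    facility_id: str
    n_unique_patients: int
    n_visits: int
    n_unique_chronic: int
    n_unique_acute: int
    meds_per_visit_mean: float
    meds_per_visit_se: float
    ctx_per_visit_mean: float
    ctx_per_visit_se: float
    revisit_rate: float
    destruction_rate: float
    chronic: StratumStats | None = None
    acute: StratumStats | None = None

    @property
    def conditions_per_patient(self) -> float:
        """Mean disease strata treated per patient (total beneficiaries / unique patients)."""
        return (self.n_unique_chronic + self.n_unique_acute) / self.n_unique_patients

    def ci95(self, which: Literal["meds", "ctx"]) -> tuple[float, float]:
        """Normal-approximation 95% CI for a pooled per-visit mean."""
        mean, se = {
            "meds": (self.meds_per_visit_mean, self.meds_per_visit_se),
            "ctx": (self.ctx_per_visit_mean, self.ctx_per_visit_se),
        }[which]
        return (mean - Z95 * se, mean + Z95 * se)


@dataclass(frozen=True)
class CountryParameters:
    """Country-pooled inputs for projection: central values with standard errors."""

    country: str
    destruction_rate: float
    ctx_per_visit: float
    ctx_per_visit_se: float
    revisit_rate: float
    revisit_rate_se: float
    conditions_per_patient: float
    chronic_ctx_per_visit: float | None = None
    chronic_revisit_rate: float | None = None
    acute_ctx_per_visit: float | None = None
    acute_revisit_rate: float | None = None
    n_facilities_sampled: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.destruction_rate <= 1.0:
            raise ValidationError("destruction_rate must lie in [0, 1]")


@dataclass(frozen=True)
class RegionMap:
    """Country -> region labels plus destruction-imputation proxy lists."""

    regions: Mapping[str, str]
    proxies: Mapping[str, Sequence[str]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionMap":
        """Build from a frame with columns country, region, destruction_proxies
        (semicolon-separated, possibly empty)."""
        regions = dict(zip(frame["country"], frame["region"]))
        proxies = {}
        for _, row in frame.iterrows():
            raw = row.get("destruction_proxies")
            if isinstance(raw, str) and raw.strip():
                proxies[row["country"]] = [p.strip() for p in raw.split(";") if p.strip()]
        return cls(regions=regions, proxies=proxies)

    def region_of(self, country: str) -> str:
        try:
            return self.regions[country]
        except KeyError:
            raise ConfigurationError(f"country {country!r} missing from region map") from None


def _pooled(values: Sequence[int]) -> tuple[float, float]:
    """Pooled per-visit mean and its standard error."""
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, se


def _stratum(records: Sequence[VisitRecord], kind: DiseaseType) -> StratumStats | None:
    sub = [r for r in records if r.disease_type is kind]
    if not sub:
        return None
    ctx_mean, ctx_se = _pooled([r.n_ctx for r in sub])
    uniq = len({r.patient_id for r in sub})
    return StratumStats(
        n_visits=len(sub),
        n_unique_patients=uniq,
        ctx_per_visit=ctx_mean,
        ctx_se=ctx_se,
        revisit_rate=len(sub) / uniq,
    )


def summarize_facility(
    records: Iterable[VisitRecord], profile: FacilityProfile
) -> FacilitySummary:
    """Descriptive statistics of one facility's sampled visit records.

    Raises :class:`InsufficientDataError` if no records are supplied and
    :class:`ValidationError` if any record belongs to another facility.
    """
    records = list(records)
    if not records:
        raise InsufficientDataError(f"no visit records for facility {profile.facility_id}")
    foreign = {r.facility_id for r in records} - {profile.facility_id}
    if foreign:
        raise ValidationError(
            f"records from facilities {sorted(foreign)} mixed into {profile.facility_id}"
        )

    n_visits = len(records)
    uniq = len({r.patient_id for r in records})
    meds_mean, meds_se = _pooled([r.n_medications for r in records])
    ctx_mean, ctx_se = _pooled([r.n_ctx for r in records])
    chronic = _stratum(records, DiseaseType.CHRONIC)
    acute = _stratum(records, DiseaseType.ACUTE)

    return FacilitySummary(
        facility_id=profile.facility_id,
        n_unique_patients=uniq,
        n_visits=n_visits,
        n_unique_chronic=chronic.n_unique_patients if chronic else 0,
        n_unique_acute=acute.n_unique_patients if acute else 0,
        meds_per_visit_mean=meds_mean,
        meds_per_visit_se=meds_se,
        ctx_per_visit_mean=ctx_mean,
        ctx_per_visit_se=ctx_se,
        revisit_rate=n_visits / uniq,
        destruction_rate=profile.destruction_rate,
        chronic=chronic,
        acute=acute,
    )


def impute_destruction(
    rates: Mapping[str, float], region_map: RegionMap
) -> dict[str, float]:
    """Replace reported 0% destruction rates with the mean of proxy countries.

    Nonzero reports pass through unchanged. A zero reporter with no proxy
    list configured is a :class:`ConfigurationError`; proxies must themselves
    have reported a rate.
    """
    for country, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"{country}: rate {rate} outside [0, 1]")
    out: dict[str, float] = {}
    for country, rate in rates.items():
        if rate > 0.0:
            out[country] = rate
            continue
        proxies = region_map.proxies.get(country)
        if not proxies:
            raise ConfigurationError(
                f"{country} reported 0% destruction but has no imputation proxies configured"
            )
        try:
            proxy_rates = [rates[p] for p in proxies]
        except KeyError as exc:
            raise ConfigurationError(
                f"{country}: proxy country {exc.args[0]!r} has no reported rate"
            ) from None
        out[country] = float(np.mean(proxy_rates))
    return out


def pool_country(
    summaries: Sequence[FacilitySummary],
    country: str = "",
    weighting: Literal["unweighted", "visits"] = "unweighted",
) -> CountryParameters:
    """Pool facility summaries into country-level parameters.

    Each parameter is averaged across the country's sample facilities —
    unweighted by default, matching an equal-facility-voice convention;
    ``weighting="visits"`` averages with facility visit counts as weights.
    Standard errors of pooled means are propagated as the SE of the mean,
    sqrt(sum se_i^2) / n (or its weighted analogue). Pooling a single
    summary returns that summary's own values.
    """
    summaries = list(summaries)
    if not summaries:
        raise InsufficientDataError("cannot pool an empty collection of facility summaries")

    if weighting == "unweighted":
        w = np.ones(len(summaries))
    elif weighting == "visits":
        w = np.asarray([s.n_visits for s in summaries], dtype=float)
    else:
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    w = w / w.sum()

    def wmean(vals):
        return float(np.dot(w, np.asarray(vals, dtype=float)))

    def wse(ses):
        # SE of a weighted mean of independent estimates
        return float(math.sqrt(float(np.dot(w**2, np.square(np.asarray(ses, dtype=float))))))

    def stratum_mean(attr_outer, attr_inner):
        pairs = [
            (wi, getattr(getattr(s, attr_outer), attr_inner))
            for wi, s in zip(w, summaries)
            if getattr(s, attr_outer) is not None
        ]
        if not pairs:
            return None
        ws = np.asarray([p[0] for p in pairs])
        vs = np.asarray([p[1] for p in pairs])
        return float(np.dot(ws / ws.sum(), vs))

    return CountryParameters(
        country=country or "pooled",
        destruction_rate=wmean([s.destruction_rate for s in summaries]),
        ctx_per_visit=wmean([s.ctx_per_visit_mean for s in summaries]),
        ctx_per_visit_se=wse([s.ctx_per_visit_se for s in summaries]),
        revisit_rate=wmean([s.revisit_rate for s in summaries]),
        revisit_rate_se=0.0 if len(summaries) == 1 else float(
            np.std([s.revisit_rate for s in summaries], ddof=1) / math.sqrt(len(summaries))
        ),
        conditions_per_patient=wmean([s.conditions_per_patient for s in summaries]),
        chronic_ctx_per_visit=stratum_mean("chronic", "ctx_per_visit"),
        chronic_revisit_rate=stratum_mean("chronic", "revisit_rate"),
        acute_ctx_per_visit=stratum_mean("acute", "ctx_per_visit"),
        acute_revisit_rate=stratum_mean("acute", "revisit_rate"),
        n_facilities_sampled=len(summaries),
    )
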
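"""Synthetic study generator with known ground truth.

Emulates the statistical structure of the pipeline's three inputs — visit
records, facility profiles, donation inventories — from a handful of
interpretable parameters, so that every pipeline stage can be tested for
parameter recovery without external data.

Generative process, per facility:

1. Each patient carries a chronic condition, an acute condition, or both
   (comorbidity), drawn from configured proportions.
2. Each condition generates ``1 + NB`` visits (a shifted negative binomial,
   so the floor of one visit is respected while the configured mean is
   preserved exactly).
3. Each visit carries medication and course-treatment counts drawn from
   negative-binomial-style distributions parameterized by mean and a
   dispersion knob (dispersion 0 collapses to a degenerate constant, which
   makes zero-noise recovery tests exact).
4. The donated inventory is sized from the *configured expected* totals:
   donated = expected prescribed CTX / (1 - destruction rate). Because the
   inventory reflects expectations rather than the realized records, the
   end-to-end recovery of the patient count is a genuine statistical check
   of the ratio estimator, not an algebraic identity.

All randomness flows from a single mandatory seed through one
``numpy.random.Generator``, with draws in a fixed documented order
(facility -> patient -> condition -> visit), so a config is a complete
recipe for a byte-identical dataset.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import pool_country, summarize_facility
from .conversion import ConversionInputs, estimate_unique_patients
from .errors import ValidationError
from .records import CareLevel, DiseaseType, FacilityProfile, InventoryRecord, VisitRecord

__all__ = ["SyntheticConfig", "GroundTruth", "generate_study", "recovery_report"]

_EPOCH = _dt.date(2015, 1, 1)
_CARE_LEVELS = [CareLevel.PRIMARY, CareLevel.SECONDARY, CareLevel.TERTIARY, CareLevel.OUTREACH]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative process. ``seed`` is mandatory.

    ``visit_mean_*`` are mean visits per condition over the window (the
    stratum revisit rates); ``ctx_mean``/``meds_mean`` are per-visit count
    means. Dispersions scale the negative-binomial excess variance
    (variance = mean + dispersion x mean^2); 0 means a degenerate constant.
    ``comorbidity_rate`` is the probability a patient has both a chronic and
    an acute condition; among the rest, ``chronic_fraction`` are chronic-only.
    ``ctx_donated_per_facility`` overrides the expectation-based inventory
    sizing when given.
    """

    seed: int
    n_facilities: int = 1
    patients_per_facility: int = 1_000
    chronic_fraction: float = 0.35
    comorbidity_rate: float = 0.10
    visit_mean_chronic: float = 3.0
    visit_mean_acute: float = 3.0
    visit_dispersion: float = 0.3
    meds_mean: float = 2.7
    meds_dispersion: float = 0.2
    ctx_mean: float = 2.5
    ctx_dispersion: float = 0.2
    destruction_rate: float = 0.10
    country: str = "Synthetica"
    ctx_donated_per_facility: int | None = None

    def __post_init__(self) -> None:
        for name in ("chronic_fraction", "comorbidity_rate", "destruction_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.destruction_rate >= 1.0:
            raise ValidationError("destruction_rate must be < 1 (some medicine must survive)")
        for name in ("visit_mean_chronic", "visit_mean_acute", "meds_mean", "ctx_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if min(self.visit_mean_chronic, self.visit_mean_acute) < 1.0:
            raise ValidationError("visit means must be >= 1 (every condition has a visit)")
        for name in ("visit_dispersion", "meds_dispersion", "ctx_dispersion"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_facilities < 1 or self.patients_per_facility < 1:
            raise ValidationError("need at least one facility and one patient")
        for mean, disp, floor in (
            (self.visit_mean_chronic - 1.0, self.visit_dispersion, "visit_mean_chronic"),
            (self.visit_mean_acute - 1.0, self.visit_dispersion, "visit_mean_acute"),
            (self.meds_mean, self.meds_dispersion, "meds_mean"),
            (self.ctx_mean, self.ctx_dispersion, "ctx_mean"),
        ):
            if disp == 0.0 and abs(mean - round(mean)) > 1e-9:
                raise ValidationError(
                    f"{floor}: dispersion 0 requires an integer-valued mean, got {mean + (1 if 'visit' in floor else 0)}"
                )

    @property
    def expected_visits_per_patient(self) -> float:
        """Configured mean visits per patient across both strata."""
        p_both = self.comorbidity_rate
        p_chronic = p_both + (1 - p_both) * self.chronic_fraction
        p_acute = p_both + (1 - p_both) * (1 - self.chronic_fraction)
        return p_chronic * self.visit_mean_chronic + p_acute * self.visit_mean_acute

    @property
    def expected_ctx_per_facility(self) -> float:
        return self.patients_per_facility * self.expected_visits_per_patient * self.ctx_mean


@dataclass(frozen=True)
class GroundTruth:
    """True quantities implied by the generative process and realized data."""

    unique_patients: int
    total_beneficiaries: int  # one per treated condition; comorbid patients count twice
    chronic_patients: int
    acute_patients: int
    conditions_per_patient: float
    realized_ctx_per_visit: float
    realized_revisit_rate: float
    destruction_rate: float
    ctx_donated_total: int
    ctx_donated_chronic: int
    ctx_donated_acute: int
    total_visits: int
    total_ctx_prescribed: int


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with variance mean + dispersion*mean^2; dispersion 0 => constant."""
    if size == 0:
        return np.zeros(0, dtype=int)
    if mean == 0.0:
        return np.zeros(size, dtype=int)
    if dispersion == 0.0:
        return np.full(size, int(round(mean)))
    n = 1.0 / dispersion  # NB "successes" parameter
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def generate_study(
    config: SyntheticConfig,
) -> tuple[list[VisitRecord], list[FacilityProfile], list[InventoryRecord], GroundTruth]:
    """Generate a full synthetic study: visits, profiles, inventory, truth."""
    rng = np.random.default_rng(config.seed)
    visits: list[VisitRecord] = []
    profiles: list[FacilityProfile] = []
    inventory: list[InventoryRecord] = []

    tot_patients = tot_chronic = tot_acute = 0
    tot_donated_chronic = tot_donated_acute = 0

    for f in range(config.n_facilities):
        fid = f"F{f + 1:03d}"
        fac_visits: list[VisitRecord] = []
        for p in range(config.patients_per_facility):
            pid = f"{fid}-P{p + 1:05d}"
            u = rng.random()
            if u < config.comorbidity_rate:
                conditions = [DiseaseType.CHRONIC, DiseaseType.ACUTE]
            elif u < config.comorbidity_rate + (1 - config.comorbidity_rate) * config.chronic_fraction:
                conditions = [DiseaseType.CHRONIC]
            else:
                conditions = [DiseaseType.ACUTE]
            tot_chronic += DiseaseType.CHRONIC in conditions
            tot_acute += DiseaseType.ACUTE in conditions
            for cond in conditions:
                mean_v = (
                    config.visit_mean_chronic
                    if cond is DiseaseType.CHRONIC
                    else config.visit_mean_acute
                )
                n_visits = 1 + int(_draw_counts(rng, mean_v - 1.0, config.visit_dispersion, 1)[0])
                meds = _draw_counts(rng, config.meds_mean, config.meds_dispersion, n_visits)
                ctxs = _draw_counts(rng, config.ctx_mean, config.ctx_dispersion, n_visits)
                days = rng.integers(0, 365, size=n_visits)
                for k in range(n_visits):
                    fac_visits.append(
                        VisitRecord(
                            patient_id=pid,
                            facility_id=fid,
                            visit_date=_EPOCH + _dt.timedelta(days=int(days[k])),
                            disease_type=cond,
                            n_medications=int(meds[k]),
                            n_ctx=int(ctxs[k]),
                        )
                    )
        tot_patients += config.patients_per_facility

        # Inventory sized from configured expectations (or an explicit override),
        # split across strata by expected prescribing share.
        keep = 1.0 - config.destruction_rate
        if config.ctx_donated_per_facility is not None:
            donated = config.ctx_donated_per_facility
        else:
            donated = int(round(config.expected_ctx_per_facility / keep))
        p_both = config.comorbidity_rate
        p_chr = p_both + (1 - p_both) * config.chronic_fraction
        p_ac = p_both + (1 - p_both) * (1 - config.chronic_fraction)
        exp_chronic_visits = p_chr * config.visit_mean_chronic
        chronic_share = exp_chronic_visits / (exp_chronic_visits + p_ac * config.visit_mean_acute)
        donated_chronic = int(round(donated * chronic_share))
        donated_acute = donated - donated_chronic
        tot_donated_chronic += donated_chronic
        tot_donated_acute += donated_acute

        inventory.append(
            InventoryRecord(
                country=config.country, facility_id=fid, ctx_count=donated_chronic,
                care_type=DiseaseType.CHRONIC, shipment_date=_EPOCH,
            )
        )
        inventory.append(
            InventoryRecord(
                country=config.country, facility_id=fid, ctx_count=donated_acute,
                care_type=DiseaseType.ACUTE, shipment_date=_EPOCH,
            )
        )
        profiles.append(
            FacilityProfile(
                facility_id=fid,
                country=config.country,
                care_level=_CARE_LEVELS[f % len(_CARE_LEVELS)],
                total_patients=config.patients_per_facility,
                total_visits=len(fac_visits),
                destruction_rate=config.destruction_rate,
            )
        )
        visits.extend(fac_visits)

    n_visits_total = len(visits)
    ctx_prescribed = sum(v.n_ctx for v in visits)
    truth = GroundTruth(
        unique_patients=tot_patients,
        total_beneficiaries=tot_chronic + tot_acute,
        chronic_patients=tot_chronic,
        acute_patients=tot_acute,
        conditions_per_patient=(tot_chronic + tot_acute) / tot_patients,
        realized_ctx_per_visit=ctx_prescribed / n_visits_total,
        realized_revisit_rate=n_visits_total / tot_patients,
        destruction_rate=config.destruction_rate,
        ctx_donated_total=tot_donated_chronic + tot_donated_acute,
        ctx_donated_chronic=tot_donated_chronic,
        ctx_donated_acute=tot_donated_acute,
        total_visits=n_visits_total,
        total_ctx_prescribed=ctx_prescribed,
    )
    return visits, profiles, inventory, truth


def _pipeline_estimate(
    visits: Sequence[VisitRecord],
    profiles: Sequence[FacilityProfile],
    inventory: Sequence[InventoryRecord],
) -> float:
    """Run summarize -> pool -> estimate on a synthetic study; returns unique patients."""
    by_fac: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_fac.setdefault(v.facility_id, []).append(v)
    summaries = [summarize_facility(by_fac[p.facility_id], p) for p in profiles]
    params = pool_country(summaries, country=profiles[0].country)
    donated = sum(r.ctx_count for r in inventory)
    return estimate_unique_patients(
        ConversionInputs(
            ctx_donated=donated,
            destruction_rate=params.destruction_rate,
            ctx_per_visit=params.ctx_per_visit,
            revisit_rate=params.revisit_rate,
        )
    )


def recovery_report(
    config: SyntheticConfig, n_replicates: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Replicate the full pipeline on fresh synthetic datasets; report bias and RMSE.

    Rows: the final unique-patient estimate plus the pooled CTX-per-visit and
    revisit-rate parameters, each with the true value, mean estimate, mean
    bias, relative bias and RMSE across replicates. Replicate seeds are
    spawned deterministically from *seed*, independent of ``config.seed``.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)

    rows = {"unique_patients": [], "ctx_per_visit": [], "revisit_rate": []}
    truths = {"unique_patients": [], "ctx_per_visit": [], "revisit_rate": []}
    for s in rep_seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        visits, profiles, inventory, truth = generate_study(cfg)
        est = _pipeline_estimate(visits, profiles, inventory)
        rows["unique_patients"].append(est)
        truths["unique_patients"].append(truth.unique_patients)
        rows["ctx_per_visit"].append(truth.realized_ctx_per_visit)
        truths["ctx_per_visit"].append(cfg.ctx_mean)
        rows["revisit_rate"].append(truth.realized_revisit_rate)
        truths["revisit_rate"].append(cfg.expected_visits_per_patient)

    out = []
    for name in rows:
        est = np.asarray(rows[name], dtype=float)
        tru = np.asarray(truths[name], dtype=float)
        bias = est - tru
        out.append(
            {
                "quantity": name,
                "true_mean": tru.mean(),
                "estimate_mean": est.mean(),
                "bias": bias.mean(),
                "relative_bias": bias.mean() / tru.mean(),
                "rmse": math.sqrt(float(np.mean(bias**2))),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(out).set_index("quantity")
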
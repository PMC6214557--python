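"""End-to-end orchestration: summarize -> pool -> project -> PSA.

This module glues the pipeline stages together for the CLI (and for anyone
who wants a one-call run from files on disk): it reads visit records,
facility profiles and a donation inventory, computes facility summaries,
pools them into country parameters (with destruction-rate imputation for
zero reporters), projects each country's donated CTX into beneficiaries, and
attaches Monte Carlo credible intervals. Outputs are plain CSV/JSON files
plus a manifest recording input hashes, the seed, and the package version,
so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import (
    CountryParameters,
    FacilitySummary,
    RegionMap,
    impute_destruction,
    pool_country,
    summarize_facility,
)
from .conversion import ConversionInputs, estimate_unique_patients, report_round
from .errors import ConfigurationError
from .projection import CountryProjection, project_country
from .records import (
    DiseaseType,
    FacilityProfile,
    InventoryRecord,
    VisitRecord,
    load_inventory,
    load_profiles,
    load_visits,
)
from .uncertainty import (
    DEFAULT_ITERATIONS,
    ParameterDistribution,
    nearest_rank_percentile,
    sample_parameter,
)

__all__ = ["RunConfig", "run_pipeline", "run_projection_psa", "projection_distributions"]


@dataclass(frozen=True)
class RunConfig:
    visits_path: Path
    profiles_path: Path
    inventory_path: Path
    region_map_path: Path | None
    output_dir: Path
    n_iter: int = DEFAULT_ITERATIONS
    seed: int = 0
    weighting: str = "unweighted"


def projection_distributions(params: CountryParameters) -> list[ParameterDistribution]:
    """PSA distributions for a country's pooled parameters.

    Probabilities (destruction rate) get a beta; everything else a truncated
    normal. Standard errors from the sample drive the spreads where they are
    positive; otherwise the default +/-20% relative range applies.
    """
    def normal(name: str, central: float, se: float | None, lo: float) -> ParameterDistribution:
        return ParameterDistribution(
            name, "normal", central,
            se=se if se else None,
            domain=(lo, float("inf")),
        )

    dists = [
        ParameterDistribution("destruction_rate", "beta", params.destruction_rate),
        normal("ctx_per_visit", params.ctx_per_visit, params.ctx_per_visit_se, 1e-9),
        normal("revisit_rate", params.revisit_rate, params.revisit_rate_se, 1.0),
        normal("conditions_per_patient", params.conditions_per_patient, None, 1.0),
    ]
    for name, central in (
        ("chronic_ctx_per_visit", params.chronic_ctx_per_visit),
        ("chronic_revisit_rate", params.chronic_revisit_rate),
        ("acute_ctx_per_visit", params.acute_ctx_per_visit),
        ("acute_revisit_rate", params.acute_revisit_rate),
    ):
        if central is not None:
            lo = 1.0 if name.endswith("revisit_rate") else 1e-9
            dists.append(normal(name, central, None, lo))
    return dists


def run_projection_psa(
    projection: CountryProjection, n_iter: int = DEFAULT_ITERATIONS, seed: int = 0
) -> CountryProjection:
    """Attach 95% credible intervals to a country projection via Monte Carlo.

    All pooled parameters are drawn simultaneously each iteration (beta for
    the destruction rate, truncated normals elsewhere); the four outputs
    (unique patients, total/chronic/acute beneficiaries) are recomputed per
    draw and summarized by nearest-rank 2.5/97.5 percentiles.
    """
    dists = projection_distributions(projection.params)
    rng = np.random.default_rng(seed)
    draws = {d.name: sample_parameter(d, rng, size=n_iter) for d in dists}

    keep = 1.0 - draws["destruction_rate"]
    unique = projection.ctx_total * keep / (draws["ctx_per_visit"] * draws["revisit_rate"])
    chronic_c = draws.get("chronic_ctx_per_visit", draws["ctx_per_visit"])
    chronic_r = draws.get("chronic_revisit_rate", draws["revisit_rate"])
    acute_c = draws.get("acute_ctx_per_visit", draws["ctx_per_visit"])
    acute_r = draws.get("acute_revisit_rate", draws["revisit_rate"])
    chronic = projection.ctx_chronic * keep / (chronic_c * chronic_r)
    acute = projection.ctx_acute * keep / (acute_c * acute_r)
    total = chronic + acute

    def interval(arr: np.ndarray) -> tuple[float, float]:
        s = np.sort(arr)
        return (nearest_rank_percentile(s, 0.025), nearest_rank_percentile(s, 0.975))

    return dataclasses.replace(
        projection,
        intervals={
            "unique_patients": interval(unique),
            "total_beneficiaries": interval(total),
            "chronic_beneficiaries": interval(chronic),
            "acute_beneficiaries": interval(acute),
        },
    )


def _group_by_facility(visits: Sequence[VisitRecord]) -> dict[str, list[VisitRecord]]:
    grouped: dict[str, list[VisitRecord]] = {}
    for v in visits:
        grouped.setdefault(v.facility_id, []).append(v)
    return grouped


def _country_ctx(inventory: Sequence[InventoryRecord]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for rec in inventory:
        bucket = out.setdefault(rec.country, {"total": 0.0, "chronic": 0.0, "acute": 0.0})
        bucket["total"] += rec.ctx_count
        bucket[rec.care_type.value] += rec.ctx_count
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts to ``config.output_dir``.

    Writes ``facility_summaries.csv``, ``country_parameters.csv``,
    ``projection.csv``, ``psa.json`` and ``manifest.json``; returns the
    manifest dictionary. Facility destruction rates are averaged per country
    and countries reporting exactly 0% are imputed from their region-map
    proxies (a missing region map is only an error if imputation is needed).
    """
    visits = load_visits(config.visits_path)
    profiles = load_profiles(config.profiles_path)
    inventory = load_inventory(config.inventory_path)

    region_map = None
    if config.region_map_path is not None:
        if not Path(config.region_map_path).exists():
            raise ConfigurationError(f"region map not found: {config.region_map_path}")
        region_map = RegionMap.from_frame(pd.read_csv(config.region_map_path))

    grouped = _group_by_facility(visits)
    summaries: list[tuple[FacilityProfile, FacilitySummary]] = []
    for profile in profiles:
        if profile.facility_id not in grouped:
            raise ConfigurationError(f"no visit records for facility {profile.facility_id}")
        summaries.append((profile, summarize_facility(grouped[profile.facility_id], profile)))

    by_country: dict[str, list[FacilitySummary]] = {}
    for profile, summary in summaries:
        by_country.setdefault(profile.country, []).append(summary)
    params = {
        c: pool_country(s, country=c, weighting=config.weighting)  # type: ignore[arg-type]
        for c, s in by_country.items()
    }

    # impute zero destruction reports from region-map proxies
    rates = {c: p.destruction_rate for c, p in params.items()}
    if any(r == 0.0 for r in rates.values()):
        if region_map is None:
            raise ConfigurationError(
                "a country reports 0% destruction but no region map was supplied"
            )
        effective = impute_destruction(rates, region_map)
        params = {
            c: dataclasses.replace(p, destruction_rate=effective[c]) for c, p in params.items()
        }

    ctx = _country_ctx(inventory)
    projections: list[CountryProjection] = []
    for country, p in params.items():
        if country not in ctx:
            raise ConfigurationError(f"no inventory records for country {country!r}")
        proj = project_country(
            ctx[country]["total"], ctx[country]["chronic"], ctx[country]["acute"], p
        )
        projections.append(run_projection_psa(proj, n_iter=config.n_iter, seed=config.seed))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([dataclasses.asdict(s) for _, s in summaries]).drop(
        columns=["chronic", "acute"]
    ).to_csv(out / "facility_summaries.csv", index=False)
    pd.DataFrame([dataclasses.asdict(p) for p in params.values()]).to_csv(
        out / "country_parameters.csv", index=False
    )

    proj_rows = []
    psa_payload = {}
    for proj in projections:
        est = proj.estimate
        proj_rows.append(
            {
                "country": proj.country,
                "total_ctx_donated": proj.ctx_total,
                "chronic_ctx_donated": proj.ctx_chronic,
                "acute_ctx_donated": proj.ctx_acute,
                "unique_patients": report_round(est.unique_patients),
                "total_beneficiaries": report_round(est.total_beneficiaries),
                "chronic_beneficiaries": report_round(est.chronic_beneficiaries),
                "acute_beneficiaries": report_round(est.acute_beneficiaries),
            }
        )
        psa_payload[proj.country] = {
            k: {"lower": lo, "upper": hi} for k, (lo, hi) in (proj.intervals or {}).items()
        }
    pd.DataFrame(proj_rows).to_csv(out / "projection.csv", index=False)
    (out / "psa.json").write_text(json.dumps(psa_payload, indent=2))

    manifest = {
        "package": "ctximpact",
        "version": __version__,
        "seed": config.seed,
        "iterations": config.n_iter,
        "weighting": config.weighting,
        "inputs": {
            "visits": _sha256(Path(config.visits_path)),
            "profiles": _sha256(Path(config.profiles_path)),
            "inventory": _sha256(Path(config.inventory_path)),
            "region_map": (
                _sha256(Path(config.region_map_path)) if config.region_map_path else None
            ),
        },
        "outputs": [
            "facility_summaries.csv",
            "country_parameters.csv",
            "projection.csv",
            "psa.json",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
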
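"""Packaged study fixtures: published per-country tables and pilot-clinic parameters.

The package ships two small CSV fixtures transcribed verbatim from the
published study of the Americares 2015 donation program:

* the per-country sample table (visits, unique patients by stratum,
  prescribing indicators with 95% CIs, destruction rates) for the ten study
  countries, and
* the per-country projection table (facilities, CTX donated by stratum, and
  projected unique patients / beneficiaries with 95% credible intervals).

A handful of cells in the published tables are internally inconsistent
(e.g. a confidence bound printed below its mean). The fixtures store every
cell verbatim; the inconsistencies are enumerated in
:data:`KNOWN_INCONSISTENCIES` so that consistency checks can exempt them
explicitly rather than silently "fixing" published numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = [
    "PilotParameters",
    "CountrySampleRow",
    "CountryProjectionRow",
    "load_table1_fixture",
    "load_table2_fixture",
    "load_region_map_fixture",
    "export_fixtures",
    "KNOWN_INCONSISTENCIES",
]


@dataclass(frozen=True)
class PilotParameters:
    """Parameters of the pilot validation clinic (a U.S. clinic with an EMR).

    The clinic received 13,319 donated course treatments in the study year;
    a systematic sample of 100 patients accounted for 843 visits and 288
    prescribed course treatments. The EMR independently recorded 3,071
    unique patients, the ground truth the algorithm is validated against.
    The base-case destruction rate of 24% is the average across the U.S.
    study sites, varied over 0-40% in sensitivity analysis.
    """

    ctx_donated: int = 13_319
    ctx_prescribed_in_sample: int = 288
    sample_patients: int = 100
    sample_visits: int = 843
    destruction_rate_base: float = 0.24
    destruction_range: tuple[float, float] = (0.0, 0.40)
    emr_true_unique_patients: int = 3_071

    def __post_init__(self) -> None:
        if min(self.ctx_donated, self.ctx_prescribed_in_sample,
               self.sample_patients, self.sample_visits,
               self.emr_true_unique_patients) <= 0:
            raise ValidationError("pilot counts must be positive")
        lo, hi = self.destruction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("destruction_range must lie within [0, 1]")

    @property
    def ctx_per_visit(self) -> float:
        """Pooled CTX-per-visit prescribing indicator (288/843)."""
        return self.ctx_prescribed_in_sample / self.sample_visits

    @property
    def revisit_rate(self) -> float:
        """Mean visits per unique patient over the window (843/100)."""
        return self.sample_visits / self.sample_patients


@dataclass(frozen=True)
class CountrySampleRow:
    """One row of the per-country sample-statistics table."""

    country: str
    total_visits: int
    total_unique_patients: int
    unique_chronic_patients: int
    unique_acute_patients: int
    meds_per_patient_mean: float
    meds_ci_low: float
    meds_ci_high: float
    ctx_per_visit_mean: float
    ctx_ci_low: float
    ctx_ci_high: float
    destruction_rate: float

    @property
    def revisit_rate(self) -> float:
        return self.total_visits / self.total_unique_patients


@dataclass(frozen=True)
class CountryProjectionRow:
    """One row of the per-country donation/projection table."""

    country: str
    n_facilities: int
    total_ctx_donated: int
    chronic_ctx_donated: int
    acute_ctx_donated: int
    unique_patients: int
    unique_ci_low: int
    unique_ci_high: int
    total_beneficiaries: int
    total_ci_low: int
    total_ci_high: int
    chronic_beneficiaries: int
    chronic_ci_low: int
    chronic_ci_high: int
    acute_beneficiaries: int
    acute_ci_low: int
    acute_ci_high: int


#: Cells of the published tables that are internally inconsistent. Stored
#: verbatim in the fixtures; consistency checks exempt exactly these.
KNOWN_INCONSISTENCIES: dict[str, str] = {
    "table1:U.S.:ctx_ci": "CTX/visit CI printed as (3.39, 3.32) — upper bound below the 3.61 mean",
    "table1:West Bank:stratum_counts": "unique chronic (15) + unique acute (199) = 214 < total unique (216)",
    "table2:Total:chronic_acute_ctx": (
        "printed Total-row chronic/acute CTX (4,037,836 / 2,757,600) disagree with "
        "their own column sums (4,670,767 / 2,067,336); per-country cells are "
        "stored verbatim and totals are recomputed from columns"
    ),
}

_DATA_PKG = "ctximpact.data"


def _data_frame(name: str) -> pd.DataFrame:
    with resources.files(_DATA_PKG).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_table1_fixture() -> list[CountrySampleRow]:
    """Per-country sample statistics for the ten study countries.

    Destruction rates are post-imputation as published (zero reporters
    already replaced by their regional proxies) and stored as proportions.
    """
    frame = _data_frame("country_sample.csv")
    return [CountrySampleRow(**row) for row in frame.to_dict("records")]


def load_table2_fixture() -> list[CountryProjectionRow]:
    """Per-country CTX donations and projected beneficiaries with 95% credible intervals."""
    frame = _data_frame("country_projection.csv")
    return [CountryProjectionRow(**row) for row in frame.to_dict("records")]


def load_region_map_fixture() -> pd.DataFrame:
    """Country -> region mapping plus destruction-imputation proxy lists.

    ``destruction_proxies`` is a semicolon-separated list of countries whose
    mean reported destruction rate substitutes for a reported 0%.
    """
    return _data_frame("region_map.csv")


def export_fixtures(directory: str | Path) -> list[Path]:
    """Write the packaged fixture CSVs into *directory*; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("country_sample.csv", "country_projection.csv", "region_map.csv"):
        target = directory / name
        target.write_text(
            resources.files(_DATA_PKG).joinpath(name).read_text(encoding="utf-8"),
            encoding="utf-8",
        )
        written.append(target)
    return written
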
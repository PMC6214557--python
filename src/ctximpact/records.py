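"""Domain record types and CSV readers/writers.

Three record kinds flow through the pipeline:

* :class:`VisitRecord` — one prescription encounter at a facility; the atomic
  observation from which prescribing indicators (course treatments per visit,
  revisit rate) are computed.
* :class:`FacilityProfile` — facility-level metadata: patient and visit
  census plus the self-reported medication destruction rate.
* :class:`InventoryRecord` — donated course treatments (CTX) shipped to a
  country or facility, stratified by chronic/acute care type.

All CSVs are UTF-8, comma-separated, with a header row and ISO-8601 dates.
Rates are stored as proportions in [0, 1], never as percentages.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "DiseaseType",
    "CareLevel",
    "VisitRecord",
    "FacilityProfile",
    "InventoryRecord",
    "load_visits",
    "write_visits",
    "load_profiles",
    "write_profiles",
    "load_inventory",
    "write_inventory",
]


class DiseaseType(str, enum.Enum):
    """Whether an encounter (or a donated medicine) treats a long-term or short-term condition."""

    CHRONIC = "chronic"
    ACUTE = "acute"


class CareLevel(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"
    OUTREACH = "outreach"


@dataclass(frozen=True)
class VisitRecord:
    """One prescription encounter.

    ``n_ctx`` counts course treatments: the standard amount of a medicine
    needed to treat one patient for one condition for a defined period.
    """

    patient_id: str
    facility_id: str
    visit_date: _dt.date
    disease_type: DiseaseType
    n_medications: int
    n_ctx: int

    def __post_init__(self) -> None:
        if self.n_medications < 0:
            raise ValidationError(f"n_medications must be >= 0, got {self.n_medications}")
        if self.n_ctx < 0:
            raise ValidationError(f"n_ctx must be >= 0, got {self.n_ctx}")
        if not isinstance(self.disease_type, DiseaseType):
            object.__setattr__(self, "disease_type", DiseaseType(self.disease_type))


@dataclass(frozen=True)
class FacilityProfile:
    facility_id: str
    country: str
    care_level: CareLevel
    total_patients: int
    total_visits: int
    destruction_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.destruction_rate <= 1.0:
            raise ValidationError(
                f"destruction_rate must lie in [0, 1], got {self.destruction_rate}"
            )
        if self.total_patients < 0:
            raise ValidationError("total_patients must be >= 0")
        if self.total_visits < self.total_patients:
            # every patient contributes at least one visit
            raise ValidationError(
                f"total_visits ({self.total_visits}) < total_patients ({self.total_patients})"
            )
        if not isinstance(self.care_level, CareLevel):
            object.__setattr__(self, "care_level", CareLevel(self.care_level))


@dataclass(frozen=True)
class InventoryRecord:
    """Donated course treatments. ``facility_id`` may be empty: shipments are
    often recorded at country level only."""

    country: str
    ctx_count: int
    care_type: DiseaseType
    shipment_date: _dt.date
    facility_id: str | None = None

    def __post_init__(self) -> None:
        if self.ctx_count < 0:
            raise ValidationError(f"ctx_count must be >= 0, got {self.ctx_count}")
        if not isinstance(self.care_type, DiseaseType):
            object.__setattr__(self, "care_type", DiseaseType(self.care_type))


# ---------------------------------------------------------------------------
# CSV plumbing

_VISIT_COLUMNS = ["patient_id", "facility_id", "visit_date", "disease_type", "n_medications", "n_ctx"]
_PROFILE_COLUMNS = ["facility_id", "country", "care_level", "total_patients", "total_visits", "destruction_rate"]
_INVENTORY_COLUMNS = ["country", "facility_id", "ctx_count", "care_type", "shipment_date"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return frame


def _parse_date(raw: str, path, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(raw)
    except ValueError as exc:
        raise FormatError(f"{path} row {row}: bad ISO date {raw!r}") from exc


def _parse_int(raw: str, name: str, path, row: int) -> int:
    try:
        return int(raw)
    except ValueError as exc:
        raise FormatError(f"{path} row {row}: column {name} is not an integer: {raw!r}") from exc


def load_visits(path: str | Path) -> list[VisitRecord]:
    """Read visit records, validating every row.

    Raises :class:`FormatError` for schema problems and
    :class:`ValidationError` (annotated with the offending row number) for
    invariant violations such as negative counts.
    """
    frame = _read_csv(path, _VISIT_COLUMNS)
    out: list[VisitRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        try:
            out.append(
                VisitRecord(
                    patient_id=row.patient_id,
                    facility_id=row.facility_id,
                    visit_date=_parse_date(row.visit_date, path, i),
                    disease_type=DiseaseType(row.disease_type),
                    n_medications=_parse_int(row.n_medications, "n_medications", path, i),
                    n_ctx=_parse_int(row.n_ctx, "n_ctx", path, i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        except ValueError as exc:  # bad enum literal
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def write_visits(records: Iterable[VisitRecord], path: str | Path) -> None:
    _to_frame(records).to_csv(path, index=False)


def load_profiles(path: str | Path) -> list[FacilityProfile]:
    frame = _read_csv(path, _PROFILE_COLUMNS)
    out = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(
                FacilityProfile(
                    facility_id=row.facility_id,
                    country=row.country,
                    care_level=CareLevel(row.care_level),
                    total_patients=_parse_int(row.total_patients, "total_patients", path, i),
                    total_visits=_parse_int(row.total_visits, "total_visits", path, i),
                    destruction_rate=float(row.destruction_rate),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def write_profiles(profiles: Iterable[FacilityProfile], path: str | Path) -> None:
    _to_frame(profiles).to_csv(path, index=False)


def load_inventory(path: str | Path) -> list[InventoryRecord]:
    frame = _read_csv(path, _INVENTORY_COLUMNS)
    out = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(
                InventoryRecord(
                    country=row.country,
                    facility_id=row.facility_id or None,
                    ctx_count=_parse_int(row.ctx_count, "ctx_count", path, i),
                    care_type=DiseaseType(row.care_type),
                    shipment_date=_parse_date(row.shipment_date, path, i),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def write_inventory(records: Iterable[InventoryRecord], path: str | Path) -> None:
    frame = _to_frame(records)
    # keep the canonical column order; facility_id may be None -> empty cell
    frame = frame[_INVENTORY_COLUMNS]
    frame.to_csv(path, index=False)


def _to_frame(records: Iterable) -> pd.DataFrame:
    records = list(records)
    if not records:
        raise ValidationError("cannot serialize an empty record collection")
    cols = [f.name for f in _dc_fields(records[0])]
    data = {}
    for c in cols:
        vals = [getattr(r, c) for r in records]
        data[c] = [v.value if isinstance(v, enum.Enum) else v for v in vals]
    return pd.DataFrame(data)
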
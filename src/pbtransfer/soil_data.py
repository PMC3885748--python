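"""Soil panels, Pb treatments, and grain/soil concentration records.

The data model mirrors a spiked-pot transfer experiment: a panel of soils
characterised by pH (1:5 in water), organic matter (OM, g/kg) and cation
exchange capacity (CEC, cmol/kg), dosed with exogenous Pb at levels set by
the Chinese soil environmental quality standard (GB15618-1995) Grade Two
limit for the soil's pH class, and paired grain/soil Pb concentrations per
(soil, cultivar, treatment).

File formats are comma-separated UTF-8 text with a header row and ``.``
decimal marks; see :data:`SOIL_PANEL_COLUMNS` and :data:`RECORD_COLUMNS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SoilProfile",
    "PbTreatment",
    "ConcentrationRecord",
    "SoilDataError",
    "InvalidTreatmentLevel",
    "TREATMENT_LEVELS",
    "assign_dose",
    "read_soil_panel",
    "write_soil_panel",
    "read_concentration_records",
    "write_concentration_records",
]

#: Recognised exogenous-Pb treatment levels.
TREATMENT_LEVELS = ("control", "low", "high")

#: Added Pb (mg/kg) by treatment level and pH class (<6.5, 6.5-7.5, >7.5).
#: "high" equals the GB15618-1995 Grade Two standard; "low" is half of it.
DOSE_TABLE = {
    "low": (125.0, 150.0, 175.0),
    "high": (250.0, 300.0, 350.0),
}

SOIL_PANEL_COLUMNS = (
    "soil_id",
    "location",
    "pH",
    "om_g_per_kg",
    "cec_cmol_per_kg",
    "tn_g_per_kg",
    "tp",
    "tk_g_per_kg",
    "background_pb_mg_per_kg",
)
_REQUIRED_SOIL_COLUMNS = ("soil_id", "pH", "om_g_per_kg", "cec_cmol_per_kg")

RECORD_COLUMNS = (
    "soil_id",
    "species",
    "level",
    "c_grain_mg_per_kg",
    "c_soil_mg_per_kg",
)


class SoilDataError(ValueError):
    """Invalid soil, treatment, or concentration data."""


class InvalidTreatmentLevel(SoilDataError):
    """A treatment level outside {control, low, high}."""


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise SoilDataError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class SoilProfile:
    """One soil's identity and measured properties.

    pH, OM and CEC drive the transfer model; total N/P/K and the aqua-regia
    background Pb are carried for completeness but never modelled. OM and
    CEC may be absent (``None``) for literature soils reported without them.
    """

    soil_id: str
    ph: float
    om: float | None = None
    cec: float | None = None
    location: str | None = None
    tn: float | None = None
    tp: float | None = None
    tk: float | None = None
    background_pb: float | None = None

    def __post_init__(self) -> None:
        if not self.soil_id:
            raise SoilDataError("soil_id must be a non-empty label")
        if not (0.0 < self.ph < 14.0):
            raise SoilDataError(f"pH must lie in (0, 14), got {self.ph!r}")
        if self.om is not None:
            _require_positive("organic matter", self.om)
        if self.cec is not None:
            _require_positive("CEC", self.cec)


@dataclass(frozen=True)
class PbTreatment:
    """An exogenous-Pb treatment: a level label and the added dose in mg/kg."""

    level: str
    added_pb: float

    def __post_init__(self) -> None:
        if self.level not in TREATMENT_LEVELS:
            raise InvalidTreatmentLevel(
                f"level must be one of {TREATMENT_LEVELS}, got {self.level!r}"
            )
        if self.level == "control" and self.added_pb != 0:
            raise SoilDataError("control treatment must add no Pb")
        if self.level != "control" and self.added_pb <= 0:
            raise SoilDataError(f"{self.level} treatment must add Pb > 0")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One (soil, cultivar, treatment) observation of grain and soil Pb (mg/kg)."""

    soil_id: str
    species: str
    level: str
    c_grain: float
    c_soil: float

    def __post_init__(self) -> None:
        if self.level not in TREATMENT_LEVELS:
            raise InvalidTreatmentLevel(
                f"level must be one of {TREATMENT_LEVELS}, got {self.level!r}"
            )
        if not math.isfinite(self.c_grain) or self.c_grain < 0:
            raise SoilDataError(f"c_grain must be >= 0, got {self.c_grain!r}")
        _require_positive("c_soil", self.c_soil)


def assign_dose(ph: float, level: str) -> float:
    """Added exogenous Pb (mg/kg) for a soil of given pH at a treatment level.

    pH classes follow the printed standard bands ``<6.5``, ``6.5-7.5`` and
    ``>7.5``; both band edges belong to the middle class. Control adds 0.
    """
    if level not in TREATMENT_LEVELS:
        raise InvalidTreatmentLevel(
            f"level must be one of {TREATMENT_LEVELS}, got {level!r}"
        )
    if not (0.0 < ph < 14.0):
        raise SoilDataError(f"pH must lie in (0, 14), got {ph!r}")
    if level == "control":
        return 0.0
    if ph < 6.5:
        idx = 0
    elif ph <= 7.5:
        idx = 1
    else:
        idx = 2
    return DOSE_TABLE[level][idx]


def _parse_float(frame_value, column: str, row: int, required: bool) -> float | None:
    if pd.isna(frame_value) or frame_value == "":
        if required:
            raise SoilDataError(f"row {row}: missing value in column {column!r}")
        return None
    try:
        return float(frame_value)
    except (TypeError, ValueError):
        raise SoilDataError(
            f"row {row}: non-numeric value {frame_value!r} in column {column!r}"
        ) from None


def read_soil_panel(path: str | Path) -> list[SoilProfile]:
    """Read a soil panel CSV into a list of :class:`SoilProfile`.

    Row order is preserved; row numbers in error messages count data rows
    from 1. Duplicate soil ids are rejected.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_SOIL_COLUMNS if c not in frame.columns]
    if missing:
        raise SoilDataError(f"soil panel {path}: missing required columns {missing}")
    profiles: list[SoilProfile] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        soil_id = data["soil_id"]
        if pd.isna(soil_id) or not str(soil_id).strip():
            raise SoilDataError(f"row {i}: missing soil_id")
        soil_id = str(soil_id).strip()
        if soil_id in seen:
            raise SoilDataError(f"row {i}: duplicate soil_id {soil_id!r}")
        seen.add(soil_id)
        location = data.get("location")
        try:
            profile = SoilProfile(
                soil_id=soil_id,
                ph=_parse_float(data["pH"], "pH", i, required=True),
                om=_parse_float(data["om_g_per_kg"], "om_g_per_kg", i, required=True),
                cec=_parse_float(
                    data["cec_cmol_per_kg"], "cec_cmol_per_kg", i, required=True
                ),
                location=None if pd.isna(location) else str(location),
                tn=_parse_float(data.get("tn_g_per_kg"), "tn_g_per_kg", i, False),
                tp=_parse_float(data.get("tp"), "tp", i, False),
                tk=_parse_float(data.get("tk_g_per_kg"), "tk_g_per_kg", i, False),
                background_pb=_parse_float(
                    data.get("background_pb_mg_per_kg"),
                    "background_pb_mg_per_kg",
                    i,
                    False,
                ),
            )
        except SoilDataError as exc:
            if str(exc).startswith("row "):
                raise
            raise SoilDataError(f"row {i}: {exc}") from None
        profiles.append(profile)
    return profiles


def write_soil_panel(soils: Iterable[SoilProfile], path: str | Path) -> None:
    """Write soils to CSV in the documented column order."""
    rows = [
        {
            "soil_id": s.soil_id,
            "location": s.location,
            "pH": s.ph,
            "om_g_per_kg": s.om,
            "cec_cmol_per_kg": s.cec,
            "tn_g_per_kg": s.tn,
            "tp": s.tp,
            "tk_g_per_kg": s.tk,
            "background_pb_mg_per_kg": s.background_pb,
        }
        for s in soils
    ]
    pd.DataFrame(rows, columns=list(SOIL_PANEL_COLUMNS)).to_csv(path, index=False)


def read_concentration_records(
    path: str | Path, panel: Sequence[SoilProfile] | None = None
) -> list[ConcentrationRecord]:
    """Read grain/soil Pb concentration records from CSV.

    When ``panel`` is given, every record's soil_id must resolve to it
    (referential integrity with the soil panel).
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SoilDataError(f"records {path}: missing required columns {missing}")
    known = None if panel is None else {s.soil_id for s in panel}
    records: list[ConcentrationRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        soil_id = str(data["soil_id"]).strip()
        if known is not None and soil_id not in known:
            raise SoilDataError(f"row {i}: unknown soil_id {soil_id!r}")
        try:
            record = ConcentrationRecord(
                soil_id=soil_id,
                species=str(data["species"]).strip(),
                level=str(data["level"]).strip(),
                c_grain=_parse_float(
                    data["c_grain_mg_per_kg"], "c_grain_mg_per_kg", i, True
                ),
                c_soil=_parse_float(
                    data["c_soil_mg_per_kg"], "c_soil_mg_per_kg", i, True
                ),
            )
        except SoilDataError as exc:
            if str(exc).startswith("row "):
                raise
            raise SoilDataError(f"row {i}: {exc}") from None
        records.append(record)
    return records


def write_concentration_records(
    records: Iterable[ConcentrationRecord], path: str | Path
) -> None:
    rows = [
        {
            "soil_id": r.soil_id,
            "species": r.species,
            "level": r.level,
            "c_grain_mg_per_kg": r.c_grain,
            "c_soil_mg_per_kg": r.c_soil,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, index=False)
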
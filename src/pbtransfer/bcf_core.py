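"""Bioconcentration factors (BCF) and their log10 transforms.

BCF = C_grain / C_soil, the dimensionless ratio of the Pb concentration in
corn grain to that in the soil. All downstream modelling is on log10 BCF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .soil_data import ConcentrationRecord, SoilDataError

__all__ = [
    "BCFRecord",
    "compute_bcf",
    "compute_bcf_table",
    "summarize_bcf",
    "correlate_grain_pb",
    "bcf_records_to_frame",
    "write_bcf_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BCFRecord:
    """One (soil, species, treatment) bioconcentration factor."""

    soil_id: str
    species: str
    level: str
    bcf: float
    log_bcf: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.bcf) and self.bcf > 0):
            raise SoilDataError(f"bcf must be > 0, got {self.bcf!r}")
        if not math.isclose(self.log_bcf, math.log10(self.bcf), rel_tol=0, abs_tol=1e-12):
            raise SoilDataError("log_bcf inconsistent with log10(bcf)")


def compute_bcf(record: ConcentrationRecord) -> BCFRecord:
    """BCF of a concentration record; rejects zero grain Pb (log undefined)."""
    if record.c_grain <= 0:
        raise SoilDataError(
            f"record ({record.soil_id}, {record.species}, {record.level}): "
            "c_grain must be > 0 to form a BCF on the log scale"
        )
    bcf = record.c_grain / record.c_soil
    return BCFRecord(
        soil_id=record.soil_id,
        species=record.species,
        level=record.level,
        bcf=bcf,
        log_bcf=math.log10(bcf),
    )


def compute_bcf_table(records: Iterable[ConcentrationRecord]) -> list[BCFRecord]:
    """BCFs for all records with detectable grain Pb.

    Records with c_grain = 0 (non-detects) are excluded, not imputed; the
    excluded count is logged so the exclusion is auditable.
    """
    kept: list[BCFRecord] = []
    dropped = 0
    for record in records:
        if record.c_grain <= 0:
            dropped += 1
            continue
        kept.append(compute_bcf(record))
    if dropped:
        logger.warning("excluded %d record(s) with non-detect grain Pb", dropped)
    return kept


def bcf_records_to_frame(records: Iterable[BCFRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "soil_id": r.soil_id,
                "species": r.species,
                "level": r.level,
                "bcf": r.bcf,
                "log_bcf": r.log_bcf,
            }
            for r in records
        ],
        columns=["soil_id", "species", "level", "bcf", "log_bcf"],
    )


def write_bcf_table(records: Iterable[BCFRecord], path: str | Path) -> None:
    bcf_records_to_frame(records).to_csv(path, index=False)


def summarize_bcf(
    records: Iterable[BCFRecord], group_keys: Sequence[str] = ("level",)
) -> pd.DataFrame:
    """Per-group min, max and max/min fold of BCF values.

    The fold quantifies the spread attributable to soils within a group
    (e.g. 0.0030/0.0010 = 3.0 across a panel at one dose level).
    """
    frame = bcf_records_to_frame(records)
    if frame.empty:
        logger.warning("summarize_bcf: no records, empty summary")
        return pd.DataFrame(columns=[*group_keys, "n", "bcf_min", "bcf_max", "fold"])
    grouped = frame.groupby(list(group_keys), sort=True)["bcf"]
    out = grouped.agg(n="size", bcf_min="min", bcf_max="max").reset_index()
    out["fold"] = out["bcf_max"] / out["bcf_min"]
    return out


def correlate_grain_pb(
    values: Sequence[float], soil_property: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of grain Pb against one soil property.

    Returns (r, two-sided p). Used to screen which properties (pH, OM, CEC)
    track grain Pb before regression modelling. Requires >= 3 finite pairs
    and a non-constant property vector.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(soil_property, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise SoilDataError("values and soil_property must be 1-D and paired")
    if y.size < 3:
        raise SoilDataError("correlation requires at least 3 pairs")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise SoilDataError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SoilDataError("correlation undefined for a constant vector")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)
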
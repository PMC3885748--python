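"""BCF normalization to a reference soil condition and variability reduction.

Normalization divides the model-implied soil effect out of a measured BCF
and replaces it with the effect at a chosen reference condition:

    BCF_norm = BCF_meas * 10^(log-pred(reference) - log-pred(record's soil))

If the model fully captured the soil effect, all of a cultivar's normalized
BCFs would be equal; the residual spread is quantified by the intra-species
variability f, the sample coefficient of variation (sd with n-1 denominator
over the mean). The drop from f_raw to f_norm measures how much soil-driven
variance the model removes — the property that makes normalized endpoints
usable in species sensitivity distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bcf_core import BCFRecord
from .soil_data import SoilDataError, SoilProfile
from .transfer_model import TransferModel, predict_log_bcf

__all__ = [
    "ReferenceCondition",
    "DEFAULT_REFERENCE",
    "NormalizationResult",
    "normalize_bcf",
    "intra_species_variability",
    "normalize_species",
    "variability_reduction_report",
]


@dataclass(frozen=True)
class ReferenceCondition:
    """Reference soil condition for normalization (pH, OM g/kg, CEC cmol/kg)."""

    ph: float = 7.0
    om: float = 20.0
    cec: float = 20.0

    def as_soil(self) -> SoilProfile:
        return SoilProfile(soil_id="__reference__", ph=self.ph, om=self.om, cec=self.cec)


#: Central to the reference panel's property ranges.
DEFAULT_REFERENCE = ReferenceCondition()


@dataclass(frozen=True)
class NormalizationResult:
    """One cultivar's normalized BCFs and variability before/after."""

    species: str
    reference: ReferenceCondition
    normalized_bcfs: tuple[float, ...]
    f_raw: float
    f_norm: float

    @property
    def reduction(self) -> float:
        return self.f_raw - self.f_norm


def normalize_bcf(
    model: TransferModel,
    record: BCFRecord,
    soil: SoilProfile,
    reference: ReferenceCondition | SoilProfile = DEFAULT_REFERENCE,
) -> float:
    """Rescale one measured BCF to the reference soil condition."""
    ref_soil = reference.as_soil() if isinstance(reference, ReferenceCondition) else reference
    if record.soil_id != soil.soil_id:
        raise SoilDataError(
            f"record soil_id {record.soil_id!r} does not match soil {soil.soil_id!r}"
        )
    shift = predict_log_bcf(model, ref_soil) - predict_log_bcf(model, soil)
    return record.bcf * 10.0 ** shift


def intra_species_variability(bcfs: Sequence[float]) -> float:
    """Sample coefficient of variation f = sd(BCF; ddof=1) / mean(BCF)."""
    values = np.asarray(bcfs, dtype=float)
    if values.size < 2:
        raise SoilDataError("variability requires at least 2 values")
    if not (np.isfinite(values).all() and (values > 0).all()):
        raise SoilDataError("BCF values must be positive and finite")
    return float(values.std(ddof=1) / values.mean())


def normalize_species(
    model: TransferModel,
    species_records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
    reference: ReferenceCondition = DEFAULT_REFERENCE,
) -> NormalizationResult:
    """Normalize one cultivar's BCFs and compute f before and after."""
    records = list(species_records)
    if len(records) < 2:
        raise SoilDataError("need at least 2 records per species")
    species = {r.species for r in records}
    if len(species) != 1:
        raise SoilDataError(f"records span multiple species: {sorted(species)}")
    by_id = soils if isinstance(soils, Mapping) else {s.soil_id: s for s in soils}
    normalized = []
    for record in records:
        soil = by_id.get(record.soil_id)
        if soil is None:
            raise SoilDataError(f"record soil_id {record.soil_id!r} not in panel")
        normalized.append(normalize_bcf(model, record, soil, reference))
    raw = [r.bcf for r in records]
    return NormalizationResult(
        species=records[0].species,
        reference=reference,
        normalized_bcfs=tuple(normalized),
        f_raw=intra_species_variability(raw),
        f_norm=intra_species_variability(normalized),
    )


def variability_reduction_report(
    models: Sequence[TransferModel],
    species_records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
    reference: ReferenceCondition = DEFAULT_REFERENCE,
) -> pd.DataFrame:
    """Per-(species, model) table of f_raw, f_norm and their difference.

    ``increased`` flags any combination where normalization failed to
    reduce variability (f_norm >= f_raw), the diagnostic of a model that
    does not transfer to that cultivar.
    """
    by_species: dict[str, list[BCFRecord]] = {}
    for record in species_records:
        by_species.setdefault(record.species, []).append(record)
    rows = []
    for label_idx, model in enumerate(models):
        label = model.level_label if model.level_label is not None else f"model{label_idx + 1}"
        for species in sorted(by_species):
            result = normalize_species(model, by_species[species], soils, reference)
            rows.append(
                {
                    "species": species,
                    "model": label,
                    "n": len(by_species[species]),
                    "f_raw": result.f_raw,
                    "f_norm": result.f_norm,
                    "reduction": result.reduction,
                    "increased": result.f_norm >= result.f_raw,
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "model", "n", "f_raw", "f_norm", "reduction", "increased"]
    )
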
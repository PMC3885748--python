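"""Cross-species extrapolation of a fitted transfer model.

A model developed on one cultivar is carried to related cultivars by
holding the soil-property slopes fixed and refitting only the intercept k
(the intrinsic sensitivity) to that cultivar's observations, minimising the
squared error between predicted and measured BCF. In log space the optimum
has the closed form k = mean(log10 BCF_i - slope terms_i); linear-space
minimisation is offered as a sensitivity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .bcf_core import BCFRecord
from .soil_data import SoilDataError, SoilProfile
from .transfer_model import TransferModel, predict_log_bcf

__all__ = [
    "SpeciesIntercept",
    "FoldAgreement",
    "fit_species_intercept",
    "evaluate_fold_agreement",
]

OBJECTIVE_SPACES = ("log", "linear")


@dataclass(frozen=True)
class SpeciesIntercept:
    """A non-model cultivar's refitted intrinsic sensitivity."""

    species: str
    k: float
    objective: float
    space: str
    n: int

    def __post_init__(self) -> None:
        if self.space not in OBJECTIVE_SPACES:
            raise SoilDataError(f"space must be one of {OBJECTIVE_SPACES}")
        if self.objective < 0:
            raise SoilDataError("objective must be >= 0")


@dataclass(frozen=True)
class FoldAgreement:
    """Predicted-vs-measured BCF agreement expressed as fold deviations.

    fold deviation = max(pred/meas, meas/pred) >= 1; coverage is the
    fraction of records inside the fold threshold.
    """

    pairs: tuple[tuple[float, float], ...]
    fold_deviations: tuple[float, ...]
    threshold: float
    coverage: float


def _soil_terms(
    model: TransferModel,
    records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
) -> np.ndarray:
    """Per-record slope contribution a*pH + b*logOM + c*logCEC (no intercept)."""
    by_id = soils if isinstance(soils, Mapping) else {s.soil_id: s for s in soils}
    terms = np.empty(len(records))
    for i, record in enumerate(records):
        soil = by_id.get(record.soil_id)
        if soil is None:
            raise SoilDataError(f"record soil_id {record.soil_id!r} not in panel")
        terms[i] = predict_log_bcf(model, soil) - model.k
    return terms


def fit_species_intercept(
    model: TransferModel,
    species_records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
    space: str = "log",
) -> SpeciesIntercept:
    """Refit only the intercept k for one cultivar's records.

    ``space`` selects the squared-error objective: "log" minimises
    sum((log pred - log meas)^2) via its closed form (the mean residual);
    "linear" minimises sum((pred BCF - meas BCF)^2) by bounded 1-D search.
    """
    if space not in OBJECTIVE_SPACES:
        raise SoilDataError(f"space must be one of {OBJECTIVE_SPACES}")
    records = list(species_records)
    if len(records) < 2:
        raise SoilDataError("need at least 2 records to refit an intercept")
    species = {r.species for r in records}
    if len(species) != 1:
        raise SoilDataError(f"records span multiple species: {sorted(species)}")
    terms = _soil_terms(model, records, soils)
    log_meas = np.array([r.log_bcf for r in records])
    if not (np.isfinite(terms).all() and np.isfinite(log_meas).all()):
        raise SoilDataError("non-finite residuals; check soils and records")

    residuals = log_meas - terms
    k_log = float(np.mean(residuals))
    if space == "log":
        objective = float(np.sum((residuals - k_log) ** 2))
        k = k_log
    else:
        meas = 10.0 ** log_meas

        def sse(k_try: float) -> float:
            return float(np.sum((10.0 ** (terms + k_try) - meas) ** 2))

        # The linear optimum lies near the log-space one; bracket widely.
        result = minimize_scalar(sse, bounds=(k_log - 3.0, k_log + 3.0), method="bounded")
        k = float(result.x)
        objective = float(result.fun)
    return SpeciesIntercept(
        species=records[0].species, k=k, objective=objective, space=space, n=len(records)
    )


def evaluate_fold_agreement(
    model: TransferModel,
    records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
    k_override: float | None = None,
    fold: float = 2.0,
) -> FoldAgreement:
    """Predicted-vs-measured fold deviations and coverage at a threshold.

    ``k_override`` substitutes a cultivar-specific intrinsic sensitivity for
    the model's own intercept (the cross-species extrapolation assumption).
    A 2-fold threshold is the conventional agreement band for soil-plant
    transfer predictions.
    """
    if fold < 1.0:
        raise SoilDataError("fold threshold must be >= 1")
    records = list(records)
    terms = _soil_terms(model, records, soils)
    k = model.k if k_override is None else k_override
    pairs = []
    deviations = []
    for term, record in zip(terms, records):
        predicted = 10.0 ** (term + k)
        measured = record.bcf
        if measured <= 0:
            raise SoilDataError("measured BCF must be > 0")
        deviation = max(predicted / measured, measured / predicted)
        pairs.append((predicted, measured))
        deviations.append(deviation)
    coverage = float(np.mean([d <= fold for d in deviations])) if deviations else math.nan
    return FoldAgreement(
        pairs=tuple(pairs),
        fold_deviations=tuple(deviations),
        threshold=fold,
        coverage=coverage,
    )
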
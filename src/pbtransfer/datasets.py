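"""Bundled reference data for the corn-grain Pb transfer analysis.

These small tables transcribe the published values the pipeline is built
around: the 17-soil Chinese reference panel used to develop the transfer
models, the two published transfer models (one per exogenous-Pb dose
level), the intrinsic-sensitivity intercepts reported for six non-model
corn cultivars, and two independent literature soils with measured
grain-Pb BCFs used for out-of-sample validation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .soil_data import SoilProfile
from .transfer_model import TransferModel

__all__ = [
    "reference_soil_panel",
    "low_pb_model",
    "high_pb_model",
    "nonmodel_species_intercepts",
    "LiteratureObservation",
    "literature_validation_records",
    "MODEL_SPECIES",
]

#: The cultivar the transfer models were developed on.
MODEL_SPECIES = "Zhengdan 958"

# soil_id, location, pH, OM g/kg, CEC cmol/kg, TN g/kg, TP, TK g/kg, bg Pb mg/kg
_PANEL = [
    ("S1", "Hunan", 4.90, 15.52, 10.85, 1.14, 0.47, 15.26, 23.12),
    ("S2", "Chongqing", 5.74, 17.48, 21.34, 1.00, 0.55, 22.61, 29.72),
    ("S3", "Liaoning", 5.74, 25.84, 12.19, 1.00, 0.73, 23.94, 27.94),
    ("S4", "Yunnan", 5.92, 34.26, 11.10, 2.01, 0.81, 4.77, 24.58),
    ("S5", "Jiangxi", 6.01, 11.69, 8.70, 0.51, 0.52, 9.96, 33.48),
    ("S6", "Anhui", 6.25, 20.04, 19.08, 0.99, 0.35, 15.41, 29.34),
    ("S7", "Heilongjiang", 6.27, 35.69, 28.59, 1.74, 0.48, 24.70, 33.99),
    ("S8", "Jilin", 6.82, 32.85, 31.11, 1.75, 0.35, 24.58, 31.01),
    ("S9", "Jiangsu", 6.93, 47.69, 26.20, 2.44, 0.69, 21.03, 36.81),
    ("S10", "Shaanxi", 7.90, 16.49, 22.37, 1.36, 0.98, 24.37, 37.30),
    ("S11", "Hebei", 7.98, 8.57, 8.12, 0.68, 0.53, 24.22, 31.96),
    ("S12", "Henan", 8.07, 17.79, 16.01, 1.07, 0.75, 19.86, 35.89),
    ("S13", "Xinjiang", 8.12, 19.43, 25.25, 1.32, 0.78, 25.49, 31.73),
    ("S14", "Shanxi", 8.24, 23.17, 16.80, 1.13, 0.95, 23.70, 37.97),
    ("S15", "Tianjin", 8.29, 22.02, 24.67, 1.42, 0.92, 24.63, 34.18),
    ("S16", "Gansu", 8.37, 19.27, 11.23, 1.05, 0.74, 23.62, 35.22),
    ("S17", "Shandong", 8.65, 11.84, 13.09, 0.93, 0.97, 21.37, 34.55),
]


def reference_soil_panel() -> list[SoilProfile]:
    """The 17 reference soils (pH 4.90-8.65, OM 8.57-47.69 g/kg,
    CEC 8.12-31.11 cmol/kg) spanning typical Chinese agricultural soils."""
    return [
        SoilProfile(
            soil_id=sid, location=loc, ph=ph, om=om, cec=cec,
            tn=tn, tp=tp, tk=tk, background_pb=bg,
        )
        for sid, loc, ph, om, cec, tn, tp, tk, bg in _PANEL
    ]


def low_pb_model() -> TransferModel:
    """Published low-dose transfer model:
    log10 BCF = -0.098 pH - 0.150 log10 OM - 1.894."""
    return TransferModel(
        a=-0.098, b=-0.150, k=-1.894,
        selected=("pH", "logOM"),
        level_label="low",
    )


def high_pb_model() -> TransferModel:
    """Published high-dose transfer model:
    log10 BCF = -0.108 pH - 0.178 log10 OM - 1.806."""
    return TransferModel(
        a=-0.108, b=-0.178, k=-1.806,
        selected=("pH", "logOM"),
        level_label="high",
    )


def nonmodel_species_intercepts() -> dict[str, dict[str, float]]:
    """Reported intrinsic-sensitivity intercepts k for six non-model corn
    cultivars, per transfer model, as published."""
    return {
        "low": {
            "Jingketian 183": -1.823,
            "Chuandan 30": -1.881,
            "Liaodan 565": -1.924,
            "Tunyu 88": -2.295,
            "Zhongdan 808": -2.288,
            "Nongda 84": -2.152,
        },
        "high": {
            "Jingketian 183": -1.681,
            "Chuandan 30": -1.785,
            "Liaodan 565": -1.846,
            "Tunyu 88": -1.857,
            "Zhongdan 808": -1.794,
            "Nongda 84": -1.717,
        },
    }


@dataclass(frozen=True)
class LiteratureObservation:
    """An independently published (soil, measured BCF) pair for validation."""

    soil: SoilProfile
    species: str
    measured_bcf: float
    soil_pb: float  # total soil Pb, mg/kg


def literature_validation_records() -> list[LiteratureObservation]:
    """Two published field observations of Zhengdan 958 grain-Pb BCF on
    soils outside the reference panel (the second reports no CEC)."""
    return [
        LiteratureObservation(
            soil=SoilProfile(soil_id="Lit1", ph=6.3, om=17.6, cec=22.6),
            species=MODEL_SPECIES,
            measured_bcf=0.0020,
            soil_pb=30.62,
        ),
        LiteratureObservation(
            soil=SoilProfile(soil_id="Lit2", ph=5.9, om=38.6, cec=None),
            species=MODEL_SPECIES,
            measured_bcf=0.0024,
            soil_pb=30.72,
        ),
    ]
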
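"""Synthetic soil panels and BCF records with the study's statistical structure.

The generator emulates a spiked-pot transfer experiment: soil properties
drawn uniformly over the reference panel's ranges, log10 BCF generated from
a known transfer model plus cultivar-specific intercept offsets and
additive Gaussian noise on the log scale (multiplicative, log-normal noise
on the BCF itself), and concentration records back-solved at the dose the
soil's pH class receives. Because the truth model is known, every pipeline
stage can be checked for exact recovery in the noiseless limit and for
calibrated recovery under noise.

A single integer seed governs all draws; per-stage substreams are derived
deterministically from it, so panels and records are reproducible and
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bcf_core import BCFRecord, compute_bcf
from .datasets import MODEL_SPECIES, low_pb_model, reference_soil_panel
from .soil_data import ConcentrationRecord, SoilDataError, SoilProfile, assign_dose
from .transfer_model import TransferModel, predict_log_bcf

__all__ = [
    "SyntheticConfig",
    "default_species_offsets",
    "gen_soils",
    "gen_bcf_records",
    "simulate",
    "SimulatedBundle",
]

#: Property ranges of the 17-soil reference panel.
PH_RANGE = (4.90, 8.65)
OM_RANGE = (8.57, 47.69)
CEC_RANGE = (8.12, 31.11)
BACKGROUND_PB_RANGE = (23.12, 37.97)

#: Residual scale (log10 units) consistent with the transfer models'
#: reported explanatory power over these property ranges.
DEFAULT_NOISE_SD = 0.1


def default_species_offsets() -> dict[str, float]:
    """Intercept offsets (log10 units) of six non-model cultivars relative
    to the model cultivar's intrinsic sensitivity, at the published
    magnitudes (range about -0.40 to +0.07)."""
    return {
        "Jingketian 183": 0.071,
        "Chuandan 30": 0.013,
        "Liaodan 565": -0.030,
        "Tunyu 88": -0.401,
        "Zhongdan 808": -0.394,
        "Nongda 84": -0.258,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated bundle.

    ``truth`` is the generating transfer model; ``species_offsets`` maps
    cultivar name to its intercept shift (the model cultivar is always
    emitted with offset 0). ``noise_sd`` is the sd of additive noise on
    log10 BCF.
    """

    n_soils: int = 17
    seed: int = 0
    ph_range: tuple[float, float] = PH_RANGE
    om_range: tuple[float, float] = OM_RANGE
    cec_range: tuple[float, float] = CEC_RANGE
    background_pb_range: tuple[float, float] = BACKGROUND_PB_RANGE
    truth: TransferModel = field(default_factory=low_pb_model)
    species_offsets: Mapping[str, float] = field(default_factory=default_species_offsets)
    noise_sd: float = DEFAULT_NOISE_SD
    levels: tuple[str, ...] = ("low", "high")
    use_reference_panel: bool = False

    def __post_init__(self) -> None:
        if self.n_soils < 1:
            raise SoilDataError("n_soils must be >= 1")
        if self.noise_sd < 0:
            raise SoilDataError("noise_sd must be >= 0")
        for name, rng in (
            ("ph_range", self.ph_range),
            ("om_range", self.om_range),
            ("cec_range", self.cec_range),
            ("background_pb_range", self.background_pb_range),
        ):
            if not rng[0] < rng[1]:
                raise SoilDataError(f"{name} must satisfy lo < hi, got {rng}")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_soils(config: SyntheticConfig) -> list[SoilProfile]:
    """Draw a soil panel with properties uniform over the configured ranges.

    Uniform independent sampling avoids the collinearity of resampling real
    panel rows; set ``use_reference_panel`` to get the literal 17-soil
    reference panel instead.
    """
    if config.use_reference_panel:
        return reference_soil_panel()
    (rng,) = _substreams(config.seed, 1)
    soils = []
    width = len(str(config.n_soils))
    for i in range(config.n_soils):
        soils.append(
            SoilProfile(
                soil_id=f"SYN{i + 1:0{width}d}",
                ph=float(rng.uniform(*config.ph_range)),
                om=float(rng.uniform(*config.om_range)),
                cec=float(rng.uniform(*config.cec_range)),
                background_pb=float(rng.uniform(*config.background_pb_range)),
            )
        )
    return soils


def gen_bcf_records(
    soils: Sequence[SoilProfile],
    truth: TransferModel,
    species_offsets: Mapping[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    levels: Sequence[str] = ("low", "high"),
) -> tuple[list[BCFRecord], list[ConcentrationRecord]]:
    """Generate BCF records (and consistent concentration records).

    log10 BCF = truth prediction + species offset + N(0, noise_sd); the
    soil Pb is background plus the dose assigned to the soil's pH class,
    and c_grain is back-solved as bcf * c_soil so that recomputing the BCF
    from the concentrations reproduces the generated value.
    """
    if noise_sd < 0:
        raise SoilDataError("noise_sd must be >= 0")
    offsets = {MODEL_SPECIES: 0.0}
    offsets.update(species_offsets or {})
    (rng,) = _substreams(seed, 1)
    bcf_records: list[BCFRecord] = []
    conc_records: list[ConcentrationRecord] = []
    for level in levels:
        for species in offsets:
            for soil in soils:
                log_bcf = predict_log_bcf(truth, soil) + offsets[species]
                if noise_sd > 0:
                    log_bcf += rng.normal(0.0, noise_sd)
                bcf = 10.0 ** log_bcf
                background = soil.background_pb if soil.background_pb is not None else 30.0
                c_soil = background + assign_dose(soil.ph, level)
                conc = ConcentrationRecord(
                    soil_id=soil.soil_id,
                    species=species,
                    level=level,
                    c_grain=bcf * c_soil,
                    c_soil=c_soil,
                )
                conc_records.append(conc)
                bcf_records.append(compute_bcf(conc))
    return bcf_records, conc_records


@dataclass(frozen=True)
class SimulatedBundle:
    """One generated study: soils, records, and the truth that made them."""

    config: SyntheticConfig
    soils: list[SoilProfile]
    bcf_records: list[BCFRecord]
    concentration_records: list[ConcentrationRecord]


def simulate(config: SyntheticConfig) -> SimulatedBundle:
    """Generate a full bundle from one config (seeded substreams for soils
    and records)."""
    soil_seed, record_seed = np.random.SeedSequence(config.seed).spawn(2)
    soils = gen_soils(
        SyntheticConfig(
            **{
                **config.__dict__,
                "seed": int(soil_seed.generate_state(1)[0] % (2**31)),
            }
        )
    )
    bcf_records, conc_records = gen_bcf_records(
        soils,
        config.truth,
        config.species_offsets,
        config.noise_sd,
        seed=int(record_seed.generate_state(1)[0] % (2**31)),
        levels=config.levels,
    )
    return SimulatedBundle(
        config=config,
        soils=soils,
        bcf_records=bcf_records,
        concentration_records=conc_records,
    )
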
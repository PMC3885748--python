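import pytest

from pbtransfer import datasets
from pbtransfer.synthetic_data import gen_bcf_records


@pytest.fixture(scope="session")
def panel():
    """The 17-soil reference panel."""
    return datasets.reference_soil_panel()


@pytest.fixture(scope="session")
def model1():
    """Published low-dose transfer model (pH and logOM slopes)."""
    return datasets.low_pb_model()


@pytest.fixture(scope="session")
def model2():
    """Published high-dose transfer model."""
    return datasets.high_pb_model()


@pytest.fixture()
def noiseless_bcf(panel, model1):
    """BCF records lying exactly on the low-dose model over the panel."""
    records, _ = gen_bcf_records(
        panel, model1, species_offsets={}, noise_sd=0.0, seed=0, levels=("low",)
    )
    return records
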
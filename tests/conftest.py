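"""Shared fixtures: hand-made records and the default synthetic dataset."""

import pytest

from aromapred.io_seq import Dataset, ProteinRecord
from aromapred.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def toy_dataset() -> Dataset:
    return Dataset(records=[
        ProteinRecord(id="a", description="", sequence="MKLVWE"),
        ProteinRecord(id="b", description="test protein", sequence="GGACDEFG"),
        ProteinRecord(id="c", description="Cytochrome P450 19A1", sequence="ACDEFGHIKL"),
    ])


@pytest.fixture(scope="session")
def synth_small():
    """20+20 short sequences: cheap, class-separable."""
    ds, truth = generate_dataset(
        SyntheticConfig(n_pos=20, n_neg=20, length_range=(80, 160), seed=7)
    )
    return ds, truth


@pytest.fixture(scope="session")
def synth_default():
    """The default study conditions: 100+100, lengths 150-500, seed 42."""
    ds, truth = generate_dataset(SyntheticConfig(seed=42))
    return ds, truth
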
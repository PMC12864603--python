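import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

from aopfusion.data import DatasetManifest, PeptideRecord
from aopfusion.simulate import SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_manifest() -> DatasetManifest:
    """Six hand-picked peptides, balanced labels, mixed lengths."""
    records = [
        PeptideRecord("a1", "HHWYC", label=1),
        PeptideRecord("a2", "WYHHCCW", label=1),
        PeptideRecord("a3", "YCWH", label=1),
        PeptideRecord("b1", "GALVI", label=0),
        PeptideRecord("b2", "TSNQDE", label=0),
        PeptideRecord("b3", "KRMP", label=0),
    ]
    return DatasetManifest(records, name="tiny")


@pytest.fixture
def small_synthetic() -> DatasetManifest:
    return generate_dataset(SyntheticSpec(n_pos=30, n_neg=30, seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(1234))
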
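import numpy as np
import pytest

from aptagen import GeneratorModel
from aptagen.synthetic_data import SyntheticSpec, sample_training_set


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained model (zero output projection -> uniform output)."""
    return GeneratorModel(layers=2, hidden_size=16, seed=1)


@pytest.fixture(scope="session")
def motif_spec():
    return SyntheticSpec(n_sequences=400, motif="TTTCCA", plant_rate=1.0, seed=5)


@pytest.fixture(scope="session")
def motif_training_set(motif_spec):
    return sample_training_set(motif_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
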
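import numpy as np
import pytest

from cagenet.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def synth_split():
    """The 80-clip (8 classes x 10) desk-scale synthetic dataset."""
    return generate_dataset(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def tiny_split():
    """A minimal synthetic dataset for fast pipeline tests."""
    return generate_dataset(SyntheticSpec(clips_per_class=3, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
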
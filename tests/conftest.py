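import numpy as np
import pytest

from mscnet.synthetic_fundus import SynthConfig, generate_sample


@pytest.fixture(scope="session")
def synth_sample():
    """One deterministic 128x128 synthetic sample with full annotations."""
    return generate_sample(SynthConfig(height=128, width=128, n_trees=4,
                                       root_caliber=4, seed=11))


@pytest.fixture(scope="session")
def synth_sample_256():
    return generate_sample(SynthConfig(height=256, width=256, n_trees=4, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
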
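import numpy as np
import pytest

from mmanet import NetConfig, PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def slim_config():
    """64-px, 1/8-width dual-branch configuration used for fast experiments."""
    return NetConfig(input_side=64, num_classes=3, width_multiplier=0.125)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(side=64)


@pytest.fixture(scope="session")
def small_dataset(phantom_spec):
    """8 slices from 2 cases — the memorization fixture."""
    return generate_dataset(phantom_spec, n_cases=2, slices_per_case=4, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
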
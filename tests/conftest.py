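import numpy as np
import pytest

from fdacnn import MaskSpec, PhantomSpec, generate_dataset, make_mask


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(image_size=64, n_ellipses=5, noise_sd=0.01, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """Ten 64x64 phantoms with paired k-space and split labels."""
    return generate_dataset(10, small_spec)


@pytest.fixture(scope="session")
def mcp_mask_64():
    return make_mask(MaskSpec(kind="mcp", sampling_rate=0.2, image_size=64, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
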
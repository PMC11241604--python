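import numpy as np
import pytest

from lungscreen.phantom import NoiseModel, PhantomSpec, generate_phantom
from lungscreen.preprocess import preprocess_image


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom with its ground truth."""
    spec = PhantomSpec(seed=9, noise=NoiseModel.none())
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom at the generator's standard noise level."""
    spec = PhantomSpec(seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def processed_phantom(noisy_phantom):
    """Preprocessing chain output for the standard noisy phantom."""
    image, truth = noisy_phantom
    return preprocess_image(image), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
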
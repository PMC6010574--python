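import numpy as np
import pytest

from toothmap import GrayImage8, PhantomSpec, generate_phantom


def random_image(rng: np.random.Generator, shape=(64, 64), **kwargs) -> GrayImage8:
    return GrayImage8(rng.integers(0, 256, size=shape, dtype=np.uint8).astype(np.uint8), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_spec():
    """Phantom conditions with the acquisition nuisances switched off, so
    measurements can be compared to ground truth exactly."""
    return PhantomSpec(
        background_level=0.0,
        background_noise_sd=0.0,
        leakage_green_to_red=0.0,
        leakage_red_to_green=0.0,
        seed=7,
    )


@pytest.fixture
def clean_phantom(clean_spec):
    return generate_phantom(clean_spec)


@pytest.fixture
def default_phantom():
    """Study conditions: background 25, noise SD 3, nonzero leakage."""
    return generate_phantom(PhantomSpec(seed=11))
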
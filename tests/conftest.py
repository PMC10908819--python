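import numpy as np
import pytest

from iispine import PhantomConfig, generate_phantom

# Small, fast phantom used across the unit tests: 3 vertebrae on a coarse
# anisotropic grid (4 x 1.5 x 1.5 mm), nothing truncated.
SMALL_CONFIG = PhantomConfig(
    n_vertebrae=3,
    grid_shape=(12, 48, 32),
    spacing=(4.0, 1.5, 1.5),
    vertebra_size=10.0,
    disc_thickness=3.0,
    canal_radius=3.0,
    curvature=2.0,
    noise_sd=0.02,
    seed=7,
)


@pytest.fixture(scope="session")
def small_phantom():
    """(image, mask, metadata) of a 3-vertebra phantom, fully visible."""
    return generate_phantom(SMALL_CONFIG)


@pytest.fixture(scope="session")
def truncated_phantom():
    """Phantom whose top vertebra is half cut by the field of view."""
    from dataclasses import replace

    return generate_phantom(replace(SMALL_CONFIG, partial_top_fraction=0.5, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
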
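import numpy as np
import pytest

from cryopick.synthetic import SyntheticConfig, fixture_suite, generate_micrograph


@pytest.fixture(scope="session")
def tiny_suite():
    """Five seeded 256x256 low-SNR micrographs with 12 planted particles each."""
    return fixture_suite("tiny")


@pytest.fixture(scope="session")
def noiseless_micrograph():
    """One synthetic micrograph with no additive noise, for threshold oracles."""
    cfg = SyntheticConfig(
        image_size=(256, 256),
        n_particles=8,
        particle_radius_px=10.0,
        min_separation_px=50.0,
        n_artifacts=0,
        noise_sigma=0.0,
        seed=7,
    )
    return generate_micrograph(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
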
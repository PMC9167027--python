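import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vertaseg as vs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-only vertebra phantom (no bias, no salt)."""
    return vs.generate_vertebra_phantom(vs.PhantomSpec(noise_sigma=5.0, seed=1))


@pytest.fixture(scope="session")
def bias_phantom():
    """Vertebra phantom with a 30% multiplicative bias field."""
    return vs.generate_vertebra_phantom(
        vs.PhantomSpec(noise_sigma=5.0, bias_amplitude=0.3, seed=1)
    )


@pytest.fixture(scope="session")
def disk_phantom():
    """Clean two-phase disk: bright disk on dark background, light noise."""
    rr, cc = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
    truth = (((rr - 63.5) ** 2 + (cc - 63.5) ** 2) <= 25.0**2).astype(np.uint8)
    rng = np.random.default_rng(1)
    img = np.clip(200.0 * truth + 60.0 * (1 - truth) + rng.normal(0, 5, truth.shape), 0, 255)
    return img, truth


@pytest.fixture(scope="session")
def circle_init():
    return vs.circle_level_set((128, 128))


@pytest.fixture(scope="session")
def checker_init():
    return vs.checkerboard_level_set((128, 128))
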
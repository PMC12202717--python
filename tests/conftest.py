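import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from imsar import PhantomSpec, default_config, make_phantom

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def phys(cfg):
    return cfg.physics


@pytest.fixture(scope="session")
def small_sphere():
    """Noiseless homogeneous sphere phantom (sigma 0.5 S/m) on a 32^3 grid."""
    spec = PhantomSpec(
        kind="sphere",
        shape=(32, 32, 32),
        spacing=(2.3, 2.3, 2.5),
        region_sigma={1: 0.5},
        noise_sd_phase=0.0,
        noise_sd_magnitude=0.0,
        seed=7,
    )
    labels, sigma, epsr = make_phantom(spec)
    return spec, labels, sigma, epsr


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
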
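import numpy as np
import pytest

from abbt import scene_synth as ss
from abbt import geometry as geo
from abbt.cli import calibrate_synthetic


@pytest.fixture(scope="session")
def clean_config() -> ss.SceneConfig:
    """Noise-free, uniformly lit scene: ground truth is exact."""
    return ss.SceneConfig(noise_sd=0.0, illumination_gradient=None, rng_seed=0)


@pytest.fixture(scope="session")
def noisy_config() -> ss.SceneConfig:
    """Standard synthetic study conditions: sRGB noise sd 4, illumination
    gradient 0.85-1.15."""
    return ss.session_config(seed=3)


@pytest.fixture(scope="session")
def geo_config() -> geo.GeometryConfig:
    return geo.GeometryConfig()


@pytest.fixture(scope="session")
def clean_markers(clean_config):
    return calibrate_synthetic(clean_config)


@pytest.fixture(scope="session")
def noisy_markers(noisy_config):
    return calibrate_synthetic(noisy_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
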
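import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gpcrmem import GeneratorConfig, build_system, generate_trajectory, receptor_like_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Small receptor-like system: quick to build, all features present."""
    return receptor_like_config(
        seed=11, n_frames=20, lipids_per_leaflet=16, n_waters=60, noise_sigma=0.01
    )


@pytest.fixture(scope="session")
def small_model(small_config):
    return build_system(small_config)


@pytest.fixture(scope="session")
def small_traj(small_config, small_model):
    traj, _truth = generate_trajectory(small_model, small_config)
    return traj


@pytest.fixture(scope="session")
def quiet_config() -> GeneratorConfig:
    """Noise-free receptor-like system (reference-equality checks)."""
    return receptor_like_config(
        seed=12, n_frames=5, lipids_per_leaflet=16, n_waters=40, noise_sigma=0.0
    )


@pytest.fixture(scope="session")
def quiet_system(quiet_config):
    model = build_system(quiet_config)
    traj, truth = generate_trajectory(model, quiet_config)
    return model, traj, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
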
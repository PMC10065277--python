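import numpy as np
import pytest

from proxhrv.preprocess import resample_proximity
from proxhrv.synthetic import SimulationConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Small, quick session config: low proximity rate, no artifacts."""
    return SimulationConfig(
        n_asd=2, n_cp=2, proximity_rate_hz=100.0, artifact_rate=0.0, seed=7
    )


@pytest.fixture
def noise_free_config(fast_config):
    import dataclasses

    return dataclasses.replace(fast_config, noise_cm=0.0)


@pytest.fixture
def session(fast_config):
    return simulate_session("ASD", fast_config, seed=42)


@pytest.fixture
def noise_free_session(noise_free_config):
    return simulate_session("ASD", noise_free_config, seed=42)


@pytest.fixture
def resampled(session):
    return resample_proximity(session.proximity)
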
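"""Shared fixtures: small deterministic scenes used across test modules."""

import numpy as np
import pytest

from cortexflow.synthetic_data import NoiseModel, SimConfig, StimulusProtocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_cfg():
    """Noiseless 10 s acquisition configuration."""
    return SimConfig(seed=7, duration_s=10.0)


@pytest.fixture
def protocol():
    """The 15 s baseline / 30 s stimulation / 15 s recovery protocol."""
    return StimulusProtocol(baseline_s=15.0, stim_s=30.0, recovery_s=15.0)


@pytest.fixture
def noisy_cfg():
    return SimConfig(seed=11, duration_s=10.0,
                     noise=NoiseModel(gaussian_sd=0.05))
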
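import logging

import pytest

from gaitevents import DetectionConfig, detect_trial, reference_events
from gaitevents.simulate import SyntheticConfig, generate_trial

logging.getLogger("gaitevents").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_config():
    """Ideal trial conditions: no marker noise, velocity minima on the events."""
    return SyntheticConfig(
        marker_noise_std_m=0.0, to_min_lead_ms=0.0, hs_min_lag_ms=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_config):
    return generate_trial(noiseless_config)


@pytest.fixture(scope="session")
def default_trial():
    """Study-condition trial: 2 mm marker noise, asymmetric TO leads 80/35 ms."""
    return generate_trial(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_events(noiseless_trial):
    kinematic = detect_trial(noiseless_trial.markers, sides=noiseless_trial.config.sides)
    reference = reference_events(noiseless_trial.force)
    return kinematic, reference


@pytest.fixture()
def config():
    return DetectionConfig()
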
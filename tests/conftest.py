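import numpy as np
import pytest

from myodict import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Fast 4-class, 3-channel protocol with short trials for unit tests."""
    return SynthConfig(
        n_classes=4,
        n_channels=3,
        n_trials_per_class=4,
        active_duration=2.0,
        rest_duration=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
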
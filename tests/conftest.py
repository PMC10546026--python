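import numpy as np
import pytest

from clet import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def led_run():
    """Small clean LED run with exactly known injected latency."""
    config = SyntheticConfig(mode="led", seed=11, n_white=10, n_black=10,
                             latency_ms=120.0)
    recording, markers, truth = simulate(config)
    return config, recording, markers, truth


@pytest.fixture(scope="session")
def hmd_run():
    """Small clean HMD run with exactly known injected latency."""
    config = SyntheticConfig(mode="hmd", seed=12, n_white=10, n_black=10,
                             latency_ms=80.0)
    recording, markers, truth = simulate(config)
    return config, recording, markers, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
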
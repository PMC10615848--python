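import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_net_result():
    """One short dynamic-field simulation shared by cheap assertions."""
    from gabawave.recipes import fig3c_config
    from gabawave.simulator import run_network

    return run_network(fig3c_config(n=40, duration=3000.0, seed=7))
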
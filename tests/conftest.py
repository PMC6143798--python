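import logging

import pytest

from corticobg import CircuitConfig, RewardConfig, WindowWorld, run_episode
from corticobg.loop import _make_net

# decision timeouts during deliberately degenerate tests are expected
logging.getLogger("corticobg.circuit").setLevel(logging.ERROR)

CORNERS = ("upper_left", "upper_right", "lower_left", "lower_right")


@pytest.fixture(scope="session")
def circuit_config() -> CircuitConfig:
    return CircuitConfig()


@pytest.fixture(scope="session")
def trained_window(circuit_config):
    """One window-task network trained over three passes of the corners.

    Shared read-only by the analysis tests; returns (net, traces).
    """
    net = _make_net(14, 4, circuit_config, seed=0, variant="full")
    env = WindowWorld(seed=0)
    traces = []
    for _ in range(3):
        for corner in CORNERS:
            env.reset(corner)
            traces.append(run_episode(env, net, RewardConfig.window_defaults()))
    return net, traces
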
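import pytest

from hippotrial import DriveConfig, SimulationConfig, build_network
from hippotrial.pathology import apply_severity


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def moderate_network(network):
    net, path = apply_severity(network, "moderate", rng_seed=11)
    return net, path


@pytest.fixture()
def short_sim():
    """A cheap simulation configuration for engine-level tests."""
    return SimulationConfig(duration=0.5, burn_in=0.2, seed=3,
                            severity="moderate")


@pytest.fixture()
def drive():
    return DriveConfig()
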
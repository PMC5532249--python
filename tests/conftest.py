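import warnings

import pytest

from domcarbon.synth import WorldConfig, make_world

# sklearn GP kernel-bound warnings are expected on small station networks
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    return make_world(WorldConfig(seed=7, n_sites=60, grid_nx=20, grid_ny=20))


@pytest.fixture(scope="session")
def small_world_sites(small_world):
    return small_world.sites
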
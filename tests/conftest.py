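import numpy as np
import pytest

from bilayermech import SyntheticSpec, gen_leaflet_frames, make_groupmap


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_per_leaflet=36, n_frames=10, seed=11)


@pytest.fixture(scope="session")
def small_gmap(small_spec):
    return make_groupmap(small_spec)


@pytest.fixture(scope="session")
def small_frames(small_spec):
    return gen_leaflet_frames(small_spec, n_frames=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
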
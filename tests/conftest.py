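import numpy as np
import pytest

import floradrift as fd

SEED = 7


@pytest.fixture(scope="session")
def landscape():
    return fd.make_landscape(16, 16, 10.0, seed=SEED)


@pytest.fixture(scope="session")
def climate(landscape):
    return fd.make_climate(landscape, seed=SEED)


@pytest.fixture(scope="session")
def cube(landscape, climate):
    cube, truth = fd.simulate_presence(landscape, climate, n_species=12,
                                       seed=SEED)
    return cube


@pytest.fixture(scope="session")
def truth(landscape, climate):
    _, truth = fd.simulate_presence(landscape, climate, n_species=12,
                                    seed=SEED)
    return truth


@pytest.fixture(scope="session")
def zoned(landscape):
    zoner, labels = fd.zone_landscape(landscape, k=6, seed=SEED)
    return zoner, labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
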
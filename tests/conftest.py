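import numpy as np
import pytest

from disconnectome import synthetic as dsyn


@pytest.fixture(scope="session")
def toy():
    """Shared toy world: (parcellation, bundle_set, peak_field, qc)."""
    return dsyn.toy_world(rng_seed=0)


@pytest.fixture(scope="session")
def toy_parcellation(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_bundles(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_field(toy):
    return toy[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
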
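import numpy as np
import pytest

from oostage import PhantomParams, generate_dataset


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(side=96)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """Balanced 10/10/10 phantom set at 96 px, shared across tests."""
    records, manifest = generate_dataset({"MI": 10, "MII": 10, "PI": 10}, small_params, seed=5)
    return records, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
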
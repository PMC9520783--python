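import numpy as np
import pytest

from opmcoreg import PhantomSpec, make_phantom, simulate_scan


@pytest.fixture(scope="session")
def phantom():
    """Default phantom, seed 1, shared read-only across the suite."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_scan(phantom):
    """Noiseless coloured scan of the shared phantom."""
    return simulate_scan(phantom, colored=True, noise_sigma=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
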
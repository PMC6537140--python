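import numpy as np
import pytest

from flimhca import default_template, generate_reference_decay
from flimhca.decay_model import DeltaIRF, GaussianIRF

# Master seed for every Monte-Carlo test; substreams are spawned from it.
MASTER_SEED = 20260930


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def small_template():
    return default_template(frame_shape=(96, 96))


@pytest.fixture(scope="session")
def gauss_irf():
    return GaussianIRF(center_ns=0.5, sigma_ns=0.2)


@pytest.fixture(scope="session")
def delta_ref():
    """Reference decay of a 2.5 ns dye recorded with an instantaneous IRF."""
    return generate_reference_decay(2.5, DeltaIRF())


@pytest.fixture(scope="session")
def gauss_ref(gauss_irf):
    """Reference decay of a 2.5 ns dye with the default Gaussian IRF."""
    return generate_reference_decay(2.5, gauss_irf)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
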
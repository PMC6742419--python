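import numpy as np
import pytest

from nspce.dfba import integrate_dfba
from nspce.fixtures import make_synthetic_network, make_toy_model

#: coarse-but-sufficient integration settings for the synthetic network
#: (responses accurate to ~1e-4 relative, well below surrogate targets)
SYN_IKW = dict(rtol=1e-4, atol=1e-6)


@pytest.fixture(scope="session")
def toy():
    model, space = make_toy_model(1.0)
    return model, space


@pytest.fixture(scope="session")
def synthetic():
    model, space = make_synthetic_network()
    return model, space


@pytest.fixture(scope="session")
def synthetic_nominal_traj(synthetic):
    model, _space = synthetic
    p = model.closed_form["nominal_params"]
    return integrate_dfba(model, p, (0.0, 40.0), **SYN_IKW)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
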
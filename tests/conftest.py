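import numpy as np
import pytest

from fmrefine.likelihood import LikelihoodConfig
from fmrefine.toy import ToyEnsemble, make_toy_dataset


@pytest.fixture(scope="session")
def toy_small():
    """Small structured toy ensemble with noiseless couplings."""
    ens, j_true, _ = make_toy_dataset(n_states=20, n_obs=24, seed=7)
    return ens, j_true


@pytest.fixture(scope="session")
def toy_full():
    """Paper-scale toy ensemble (100 states x 60 observables), noiseless."""
    ens, j_true, _ = make_toy_dataset(seed=1)
    return ens, j_true


@pytest.fixture()
def tiny_ensemble():
    rng = np.random.default_rng(3)
    phi = rng.uniform(-180.0, 180.0, (3, 2))
    return ToyEnsemble(phi=phi, populations=np.full(3, 1 / 3))


@pytest.fixture()
def default_likelihood():
    return LikelihoodConfig()
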
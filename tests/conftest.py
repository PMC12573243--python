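import numpy as np
import pytest

from metanet.first_order_zoo import train_zoo
from metanet.meta_autoencoder import train_interunit, train_unitwise
from metanet.synthetic_data import default_configs, make_synthetic_suite


@pytest.fixture(scope="session")
def tiny_suite():
    """8 datasets (4 vision-like + 4 audio-like), 400 patches each."""
    cfg_a, cfg_b = default_configs(seed=7)
    return make_synthetic_suite(cfg_a, cfg_b, 400)


@pytest.fixture(scope="session")
def tiny_zoo(tiny_suite):
    """32 first-order nets: 4 per dataset, split 3 train / 1 validation."""
    return train_zoo(tiny_suite, n_models=4, n_train=3, base_seed=11)


@pytest.fixture(scope="session")
def tiny_meta(tiny_zoo):
    """Both meta-stages trained briefly on the tiny zoo (enough for contracts)."""
    unitwise = train_unitwise(tiny_zoo, epochs=2, seed=3)
    interunit = train_interunit(tiny_zoo, unitwise, epochs=10, seed=4)
    return unitwise, interunit


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
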
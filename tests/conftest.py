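import numpy as np
import pytest

from heightmort import synthetic


@pytest.fixture(scope="session")
def default_world():
    """One default-condition synthetic survey shared across tests."""
    cfg = synthetic.SimConfig(seed=11)
    inventory, truth = synthetic.generate_inventory(cfg)
    return cfg, inventory, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20160901)
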
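import numpy as np
import pytest

from cernapipe.datagen import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small planted dataset shared across read-only tests."""
    cfg = SimulationConfig(n_mirna=20, n_mrna=80, n_circ=40, rng_seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
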
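import numpy as np
import pytest

from meripkit.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimConfig(n_genes=300, n_samples_per_group=10, n_modules=3,
                    module_size=40, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
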
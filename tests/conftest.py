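import numpy as np
import pytest

from sympnet import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """6 symptoms + 2 clusters, 1 bridge, n=800 — shared across fast tests."""
    spec = synthetic.make_true_network(6, 2, 1, edge_density=0.3, seed=11)
    return synthetic.sample_cohort(spec, n=800, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
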
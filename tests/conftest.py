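import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cusaseq as cq

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog2k():
    """A 2000-gene synthetic catalog (with signature symbols seeded)."""
    return cq.make_gene_catalog(2000, seed=11)


@pytest.fixture(scope="session")
def model2k(catalog2k):
    """Region model with the default 1.0 log2 regional effect."""
    return cq.make_region_model(catalog2k, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """A complete 3000-gene, 4-patient matched study."""
    return cq.simulate_study(n_genes=3000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
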
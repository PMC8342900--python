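"""Shared fixtures: seeded synthetic datasets and master networks."""

import pytest

import cernet as cn
from cernet.fixtures import simulate_master


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulated study: 60 samples, 8 planted circuits."""
    return cn.simulate_dataset(cn.FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def discovered(default_dataset):
    """(circuits, correlations) recovered from the default dataset."""
    ds = default_dataset
    return cn.discover_circuits(ds.expression, ds.catalog, ds.interactions, seed=1)


@pytest.fixture(scope="session")
def master_circuits():
    """A denser random circuit list with 3 planted components."""
    return simulate_master(40, edge_density=0.004, frac_validated=0.3, seed=11, n_blocks=3)


@pytest.fixture(scope="session")
def master_net(master_circuits):
    return cn.build_master(master_circuits)
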
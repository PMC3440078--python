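import logging

import pytest

from adstar import StarPoissonRegression, simulate_dataset
from adstar.io import load_taipei_adjacency, load_taipei_events
from adstar.model import dataset_to_Xy

logging.getLogger("adstar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def taipei_graph():
    return load_taipei_adjacency()


@pytest.fixture(scope="session")
def taipei_events():
    return load_taipei_events()


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated year, 12 districts, default (published-magnitude) truth."""
    return simulate_dataset(seed=42, n_years=1)


@pytest.fixture(scope="session")
def small_Xy(small_dataset):
    return dataset_to_Xy(small_dataset)


@pytest.fixture(scope="session")
def fitted_small(small_dataset, small_Xy):
    """A short-chain fit of the one-year dataset, shared across tests."""
    X, y = small_Xy
    model = StarPoissonRegression(
        adjacency=small_dataset.adjacency,
        iterations=500, burnin=200, thin=3, random_state=7,
    )
    return model.fit(X, y)
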
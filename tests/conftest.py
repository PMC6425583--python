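import warnings

import numpy as np
import pytest

import pagamap as pm
from pagamap.pipeline import run_pipeline


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def y_dataset():
    """One simulated Y-topology dataset shared across read-only tests."""
    return pm.simulate_tree(pm.y_topology(), cells_per_segment=200, seed=0)


@pytest.fixture(scope="session")
def y_result(y_dataset):
    """Default-pipeline result on the shared Y dataset."""
    return run_pipeline(y_dataset, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_neighbor_graph(rng, n=8, p=0.5):
    """Random symmetric unit-weight graph as a NeighborGraph (test helper)."""
    from pagamap.neighbors import graph_from_edges

    edges = [(i, j, 1.0) for i in range(n) for j in range(i + 1, n) if rng.uniform() < p]
    return graph_from_edges(edges, n_cells=n)
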
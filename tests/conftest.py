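import networkx as nx
import numpy as np
import pytest

from tcmspace.formula_network import FormulaCollection
from tcmspace.synthetic_data import StudyConfig, gen_study


def adjacency_to_graph(adj: np.ndarray) -> nx.Graph:
    """Build a labelled herb graph from an adjacency matrix (test helper)."""
    n = adj.shape[0]
    labels = [f"H{i:03d}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                g.add_edge(labels[i], labels[j], count=1)
    return g


@pytest.fixture
def toy_collection():
    return FormulaCollection.from_records([("F1", ["A", "B", "C"]), ("F2", ["B", "C", "D"])])


@pytest.fixture(scope="session")
def small_config():
    """A deliberately small study for fast smoke tests (not the default world)."""
    return StudyConfig(
        n_herbs=20,
        n_formulas=40,
        formula_size_min=3,
        formula_size_max=6,
        n_incompatible_pairs=4,
        compounds_per_herb=3.0,
        p_chemical=15,
        p_metabolism=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return gen_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    return gen_study(StudyConfig(seed=11))
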
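import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint unit-weight triangles: the classic modularity test graph."""
    G = nx.Graph()
    G.add_edges_from([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)], weight=1.0)
    return G


@pytest.fixture
def path_abc() -> nx.Graph:
    G = nx.Graph()
    G.add_edges_from([("a", "b"), ("b", "c")], weight=1.0)
    return G


@pytest.fixture
def small_observations() -> pd.DataFrame:
    """Three subjects, four distinct terms from the packaged vocabulary."""
    rows = [
        ("A", "leg_weakness"), ("A", "arm_weakness"), ("A", "paresthesias"),
        ("A", "leg_weakness"),  # duplicated observation, must dedupe
        ("B", "fatigue"), ("B", "tiredness"),
        ("C", "paresthesias"), ("C", "numbness"), ("C", "pain"),
    ]
    return pd.DataFrame(rows, columns=["subject_id", "term_id"])


@pytest.fixture
def random_features() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    X = rng.uniform(0, 1, size=(12, 6))
    X[X < 0.15] = 0.0
    X[:, 0] += 0.05  # no all-zero rows
    return pd.DataFrame(
        X, index=[f"S{i}" for i in range(12)], columns=[f"f{j}" for j in range(6)]
    )


def random_weighted_graph(n: int, p: float, seed: int) -> nx.Graph:
    rng = np.random.default_rng(seed)
    G = nx.gnp_random_graph(n, p, seed=seed)
    for u, v in G.edges:
        G[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
    if G.number_of_edges() == 0:
        G.add_edge(0, 1 % max(n, 2), weight=1.0)
    return G
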
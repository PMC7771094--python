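import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coppinet.network import CoppiNetwork


def make_coppi(weighted_edges, point="FC_ST1") -> CoppiNetwork:
    """CoPPI from {(u, v): weight} without going through expression data."""
    g = nx.Graph()
    for (u, v), w in weighted_edges.items():
        g.add_edge(u, v, weight=float(w))
    return CoppiNetwork(point=point, graph=g)


def random_coppi(n_nodes, p_edge, rng, point="FC_ST1") -> CoppiNetwork:
    """Erdos-Renyi graph with Uniform(0,1) weights; nodes g000, g001, ..."""
    names = [f"g{i:03d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(names[i], names[j], weight=float(rng.random()))
    return CoppiNetwork(point=point, graph=g)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression():
    """Five genes x five samples with known correlation structure."""
    return pd.DataFrame(
        {
            "s1": [1.0, 2.0, 1.0, 5.0, 0.2],
            "s2": [2.0, 4.0, 2.0, 5.0, 0.3],
            "s3": [3.0, 6.0, 3.0, 5.0, 0.1],
            "s4": [4.0, 8.0, 5.0, 5.0, 0.2],
            "s5": [5.0, 10.0, 4.0, 5.0, 0.4],
        },
        index=pd.Index(["ga", "gb", "gc", "gd", "ge"], name="gene"),
    )
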
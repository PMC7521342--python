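import numpy as np
import pytest

from alkapks import synthetic_data as sd
from alkapks.domain_scan import default_profiles


@pytest.fixture(scope="session")
def profiles():
    """Calibrated domain profiles (threshold calibration is cached)."""
    return default_profiles()


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-truth simulation shared across tests."""
    cfg = sd.SimConfig(n_genes=300, planted_up=30, seed=11)
    cm, truth = sd.simulate_counts(cfg)
    return cfg, cm, truth


def random_additive_matrix(n, rng):
    """Distance matrix of a random edge-weighted binary tree on n leaves
    (leaf path lengths), for NJ recovery oracles."""
    import networkx as nx
    from skbio import DistanceMatrix

    G = nx.Graph()
    G.add_edge("t0", "t1", length=float(rng.uniform(0.1, 1)))
    inner = 0
    for k in range(2, n):
        edges = list(G.edges())
        u, v = edges[rng.integers(0, len(edges))]
        length = G[u][v]["length"]
        G.remove_edge(u, v)
        inner += 1
        mid = f"i{inner}"
        frac = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, length=length * frac)
        G.add_edge(mid, v, length=length * (1 - frac))
        G.add_edge(mid, f"t{k}", length=float(rng.uniform(0.1, 1)))
    leaves = [f"t{i}" for i in range(n)]
    paths = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    d = np.array([[paths[a][b] for b in leaves] for a in leaves])
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(d, leaves)
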
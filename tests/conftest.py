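import itertools

import networkx as nx
import numpy as np
import pytest

import graphsel as gs


def random_weighted_graph(rng, n_nodes=None, density=None) -> nx.Graph:
    """Random undirected graph with uniform(0,1) edge weights and string ids."""
    n = n_nodes if n_nodes is not None else int(rng.integers(6, 15))
    p = density if density is not None else float(rng.uniform(0.3, 0.9))
    ids = [f"n{i:02d}" for i in range(n)]
    g = nx.Graph(mode="co_importance")
    g.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        if rng.random() < p:
            g.add_edge(a, b, weight=float(rng.uniform(0, 1)))
    return g


def brute_force_heaviest(g: nx.Graph, k: int):
    """Enumerate all k-subsets; return (best objective, lexicographically
    smallest co-optimal subset)."""
    best_obj, best_set = -1.0, None
    for subset in itertools.combinations(sorted(g.nodes), k):
        w = g.subgraph(subset).size(weight="weight")
        if w > best_obj + 1e-12:
            best_obj, best_set = w, subset
    return best_obj, best_set


def random_importance_tensor(rng, f=None, s=None, n=None, sparsity=0.3):
    f = f if f is not None else int(rng.integers(1, 6))
    s = s if s is not None else int(rng.integers(1, 7))
    n = n if n is not None else int(rng.integers(2, 31))
    vals = rng.uniform(0, 1, size=(f, s, n))
    vals[rng.random(vals.shape) < sparsity] = 0.0
    ids = [f"f{i:03d}" for i in range(n)]
    return gs.ImportanceTensor([f"sel{j}" for j in range(f)], ids, vals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edge("a", "b")
    g.add_edge("b", "c")
    g.add_edge("c", "d")
    return g


@pytest.fixture
def small_table():
    spec = gs.SyntheticSpec(
        n_samples=120, n_groups=3, group_size=2, n_noise=24, effect_size=1.5,
        within_group_correlation=0.8, seed=7,
    )
    table, truth = gs.generate_dataset(spec)
    return table, truth
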
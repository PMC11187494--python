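import itertools

import numpy as np
import pytest

import graphsel as gs
from graphsel.selectors import ImportanceTensor, SelectionTensor
from conftest import random_importance_tensor


def selection_tensor(values, ids, t=2):
    return SelectionTensor([f"s{i}" for i in range(np.shape(values)[0])], ids, values, t)


class TestCoSelectionMatrix:
    def test_single_co_selection_event(self):
        B = selection_tensor(np.array([[[1, 1, 0]]]), ["A", "B", "C"])
        M = gs.build_co_selection_matrix(B)
        assert M.M[0, 1] == 1 and M.M[0, 0] == 1 and M.M[0, 2] == 0

    def test_sums_over_selectors(self):
        B = selection_tensor(np.array([[[1, 1]], [[1, 1]]]), ["A", "B"])
        M = gs.build_co_selection_matrix(B)
        assert M.M[0, 1] == 2

    def test_matches_triple_loop_oracle(self, rng):
        vals = (rng.random((3, 4, 8)) < 0.4).astype(int)
        B = selection_tensor(vals, [f"f{i}" for i in range(8)], t=8)
        M = gs.build_co_selection_matrix(B).M
        for i in range(8):
            for j in range(8):
                expect = sum(
                    int(vals[f, s, i] and vals[f, s, j])
                    for f in range(3)
                    for s in range(4)
                )
                assert M[i, j] == expect

    def test_invariants_on_random_tensors(self, rng):
        for _ in range(200):
            tensor = random_importance_tensor(rng, n=int(rng.integers(2, 13)))
            t = min(int(rng.integers(1, 5)), tensor.n_features)
            B = gs.binarize(tensor, t=t)
            M = gs.build_co_selection_matrix(B).M
            F, S = B.n_selectors, B.n_folds
            assert np.array_equal(M, M.T)
            diag = np.diag(M)
            assert M.max() <= F * S
            for i, j in itertools.combinations(range(M.shape[0]), 2):
                assert M[i, j] <= min(diag[i], diag[j])


class TestCoImportanceGraph:
    def test_min_of_two_values(self):
        tensor = ImportanceTensor(["s"], ["i", "j"], np.array([[[0.3, 0.5]]]))
        g = gs.build_co_importance_graph(tensor)
        assert g["i"]["j"]["weight"] == pytest.approx(0.3)

    def test_zero_importance_feature_is_isolated(self):
        tensor = ImportanceTensor(
            ["s"], ["i", "j", "z"], np.array([[[0.3, 0.5, 0.0]]])
        )
        g = gs.build_co_importance_graph(tensor)
        assert "z" not in g

    def test_worked_two_by_two_example(self):
        # slices (f,s): i gets (.8,.1),(.4,.6); j gets (.5,.9),(.3,.2)
        vals = np.zeros((2, 2, 2))
        vals[:, :, 0] = [[0.8, 0.1], [0.4, 0.6]]
        vals[:, :, 1] = [[0.5, 0.9], [0.3, 0.2]]
        g = gs.build_co_importance_graph(ImportanceTensor(["f1", "f2"], ["i", "j"], vals))
        assert g["i"]["j"]["weight"] == pytest.approx(1.1)

    def test_rejects_out_of_range_tensor(self):
        tensor = ImportanceTensor(["s"], ["i", "j"], np.array([[[0.3, 1.0]]]))
        tensor.values[0, 0, 1] = 1.5  # corrupt after construction
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            gs.build_co_importance_graph(tensor)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(100):
            tensor = random_importance_tensor(rng)
            g = gs.build_co_importance_graph(tensor)
            V = tensor.values
            F, S, N = V.shape
            for i, j in itertools.combinations(range(N), 2):
                expect = sum(
                    min(V[f, s, i], V[f, s, j]) for f in range(F) for s in range(S)
                )
                fi, fj = tensor.feature_ids[i], tensor.feature_ids[j]
                got = g[fi][fj]["weight"] if g.has_edge(fi, fj) else 0.0
                assert got == pytest.approx(expect, abs=1e-9)

    def test_capacity_bound(self, rng):
        for _ in range(25):
            tensor = random_importance_tensor(rng)
            g = gs.build_co_importance_graph(tensor)
            totals = dict(zip(tensor.feature_ids, tensor.total_importance()))
            for u, v, d in g.edges(data=True):
                assert d["weight"] <= min(totals[u], totals[v]) + 1e-9

    def test_positive_homogeneity(self, rng):
        tensor = random_importance_tensor(rng, f=3, s=3, n=12)
        c = 0.37
        scaled = ImportanceTensor(
            tensor.selector_ids, tensor.feature_ids, tensor.values * c
        )
        g1 = gs.build_co_importance_graph(tensor)
        g2 = gs.build_co_importance_graph(scaled)
        assert set(g1.edges) == set(g2.edges)
        for u, v in g1.edges:
            assert g2[u][v]["weight"] == pytest.approx(c * g1[u][v]["weight"])

    def test_counts_equal_binary_co_importance(self, rng):
        for _ in range(20):
            tensor = random_importance_tensor(rng, n=10)
            B = gs.binarize(tensor, t=3)
            from_counts = gs.co_graph_from_counts(gs.build_co_selection_matrix(B))
            as_float = ImportanceTensor(
                B.selector_ids, B.feature_ids, B.values.astype(float)
            )
            from_importance = gs.build_co_importance_graph(as_float)
            assert set(from_counts.edges) == set(from_importance.edges)
            for u, v in from_counts.edges:
                assert from_counts[u][v]["weight"] == pytest.approx(
                    from_importance[u][v]["weight"]
                )


class TestCountsGraph:
    def test_single_positive_entry(self):
        M = np.zeros((3, 3), dtype=int)
        M[0, 0] = M[1, 1] = 4
        M[0, 1] = M[1, 0] = 3
        g = gs.co_graph_from_counts(gs.CoSelectionMatrix(["A", "B", "C"], M))
        assert list(g.edges(data="weight")) == [("A", "B", 3.0)]

    def test_zero_off_diagonal_gives_no_edges(self):
        M = np.diag([2, 1, 5])
        g = gs.co_graph_from_counts(gs.CoSelectionMatrix(["A", "B", "C"], M))
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 3

    def test_five_by_five_fixture_matches_entries(self, rng):
        ids = list("abcde")
        upper = rng.integers(0, 4, size=(5, 5))
        M = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag([9] * 5)
        g = gs.co_graph_from_counts(gs.CoSelectionMatrix(ids, M))
        for i, j in itertools.combinations(range(5), 2):
            if M[i, j] > 0:
                assert g[ids[i]][ids[j]]["weight"] == M[i, j]
            else:
                assert not g.has_edge(ids[i], ids[j])


class TestPruneGraph:
    def _graph(self, weights):
        import networkx as nx

        g = nx.Graph(mode="co_importance")
        for (u, v), w in weights.items():
            g.add_edge(u, v, weight=w)
        return g

    def test_keeps_top_strength_nodes(self):
        g = self._graph({("a", "b"): 4.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        # strengths: a=5, b=5, c=2
        pruned = gs.prune_graph(g, max_nodes=2)
        assert set(pruned.nodes) == {"a", "b"}

    def test_identity_when_large_enough(self):
        g = self._graph({("a", "b"): 1.0})
        assert gs.prune_graph(g, max_nodes=5) is g

    def test_matches_strength_sort_oracle(self, rng):
        from conftest import random_weighted_graph

        g = random_weighted_graph(rng, n_nodes=50, density=0.2)
        pruned = gs.prune_graph(g, max_nodes=10)
        strength = gs.node_strength(g)
        expect = set(sorted(g.nodes, key=lambda v: (-strength[v], v))[:10])
        assert set(pruned.nodes) == expect

    def test_rejects_budget_below_k(self):
        g = self._graph({("a", "b"): 1.0})
        with pytest.raises(ValueError, match="max_nodes"):
            gs.prune_graph(g, max_nodes=3, k=5)
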
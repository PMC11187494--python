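import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graphsel as gs
from graphsel.selectors import ImportanceTensor, run_selector


class TestRunSelector:
    def test_correlation_magnitude_matches_hand_value(self):
        # |Pearson r| of x=(0,1,2,3) against a two-class label is 0.8944
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        score = run_selector("abs_correlation", X, y)
        assert score[0] == pytest.approx(0.8944, abs=1e-4)

    @pytest.mark.parametrize("selector", ["anova_f", "mrmr", "mutual_info"])
    def test_informative_feature_outscores_noise(self, selector, rng):
        y = np.array(["pos"] * 40 + ["neg"] * 40)
        a = np.where(y == "pos", 1.0, -1.0) + rng.normal(0, 0.01, 80)
        b = rng.normal(0, 1, 80)
        score = run_selector(selector, np.column_stack([a, b]), y, random_state=0)
        assert score[0] > score[1]

    @pytest.mark.parametrize(
        "selector", ["anova_f", "l1_logistic", "decision_tree", "mrmr", "variance"]
    )
    def test_constant_feature_scores_zero(self, selector, rng):
        y = np.array(["pos"] * 20 + ["neg"] * 20)
        X = np.column_stack([rng.normal(size=40), np.full(40, 3.14)])
        score = run_selector(selector, X, y, random_state=0)
        assert score[1] == 0.0

    def test_all_constant_matrix_warns_and_zeroes(self):
        y = np.array(["a", "a", "b", "b"])
        X = np.ones((4, 3))
        with pytest.warns(UserWarning, match="constant"):
            score = run_selector("anova_f", X, y)
        assert np.all(score == 0)

    def test_unknown_selector_raises(self):
        with pytest.raises(ValueError, match="unknown selector"):
            run_selector("nope", np.zeros((4, 2)), np.array(["a", "a", "b", "b"]))

    def test_requires_two_samples_per_class(self):
        with pytest.raises(ValueError, match="2 training samples"):
            run_selector(
                "anova_f", np.random.rand(3, 2), np.array(["a", "a", "b"])
            )


class TestNormalizeImportance:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ((2.0, 4.0, 0.0), (0.5, 1.0, 0.0)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
            ((7.0,), (1.0,)),
        ],
    )
    def test_examples(self, raw, expected):
        np.testing.assert_allclose(
            gs.normalize_importance(np.array(raw)), expected
        )

    @pytest.mark.parametrize("bad", [[-1.0, 2.0], [np.nan, 1.0], [np.inf]])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            gs.normalize_importance(np.array(bad))

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=20)
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_max_is_one_unless_all_zero(self, raw):
        out = gs.normalize_importance(np.array(raw))
        if np.any(np.array(raw) > 0):
            assert out.max() == pytest.approx(1.0)
        else:
            assert np.all(out == 0)
        assert out.min() >= 0


class TestBinarize:
    def _tensor(self, slice_values, ids):
        vals = np.asarray(slice_values, dtype=float)[None, None, :]
        return ImportanceTensor(["s"], ids, vals)

    def test_top_t_by_value(self):
        B = gs.binarize(self._tensor([0.9, 0.2, 0.5], ["a", "b", "c"]), t=2)
        np.testing.assert_array_equal(B.values[0, 0], [1, 0, 1])

    def test_lexicographic_tie_break(self):
        B = gs.binarize(self._tensor([0.5, 0.5], ["b", "a"]), t=1)
        # the tied feature with the lexicographically smaller id wins
        np.testing.assert_array_equal(B.values[0, 0], [0, 1])

    def test_zero_importance_never_selected(self):
        B = gs.binarize(self._tensor([0.4, 0.0, 0.0], ["a", "b", "c"]), t=2)
        np.testing.assert_array_equal(B.values[0, 0], [1, 0, 0])

    def test_budget_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            B = gs.binarize(self._tensor([0.4, 0.2], ["a", "b"]), t=5)
        assert B.values.sum() == 2

    def test_selection_count_within_budget(self, rng):
        tensor = ImportanceTensor(
            ["s1", "s2"],
            [f"f{i}" for i in range(10)],
            rng.uniform(0, 1, size=(2, 3, 10)),
        )
        B = gs.binarize(tensor, t=4)
        per_slice = B.values.sum(axis=2)
        assert per_slice.max() <= 4
        assert np.all((B.values == 1) <= (tensor.values > 0))


class TestBuildImportanceTensor:
    def test_shape_and_range(self, small_table):
        table, _ = small_table
        folds = gs.make_cv_folds(table.labels, seed=0, n_folds=2)
        tensor = gs.build_importance_tensor(
            table, folds, roster=["anova_f"], random_state=0
        )
        assert tensor.values.shape == (1, 2, table.n_features)
        assert tensor.values.min() >= 0 and tensor.values.max() <= 1

    def test_slice_max_is_one_unless_zero(self, small_table):
        table, _ = small_table
        folds = gs.make_cv_folds(table.labels, seed=0, n_folds=3)
        tensor = gs.build_importance_tensor(
            table, folds, roster=["anova_f", "l1_logistic"], random_state=0
        )
        for f in range(tensor.n_selectors):
            for s in range(tensor.n_folds):
                mx = tensor.values[f, s].max()
                assert mx == pytest.approx(1.0) or mx == 0.0

    def test_determinism_and_duplicate_roster_slices_equal(self, small_table):
        table, _ = small_table
        folds = gs.make_cv_folds(table.labels, seed=1, n_folds=2)
        roster = ["decision_tree", "decision_tree"]
        t1 = gs.build_importance_tensor(table, folds, roster=roster, random_state=3)
        t2 = gs.build_importance_tensor(table, folds, roster=roster, random_state=3)
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(t1.values[0], t1.values[1])

    def test_feature_order_equivariance(self, small_table, rng):
        table, _ = small_table
        folds = gs.make_cv_folds(table.labels, seed=0, n_folds=2)
        perm = rng.permutation(table.n_features)
        permuted = gs.FeatureTable(
            table.sample_ids,
            [table.feature_ids[i] for i in perm],
            table.values[:, perm],
            table.labels,
        )
        base = gs.build_importance_tensor(
            table, folds, roster=["anova_f", "mrmr"], random_state=0
        )
        shuf = gs.build_importance_tensor(
            permuted, folds, roster=["anova_f", "mrmr"], random_state=0
        )
        np.testing.assert_allclose(shuf.values[:, :, np.argsort(perm)], base.values)

    def test_validation_rows_never_touch_fitting(self, small_table):
        table, _ = small_table
        half = table.n_samples // 2
        folds = [(np.arange(half), np.arange(half, table.n_samples))]
        t1 = gs.build_importance_tensor(table, folds, roster=["anova_f"], random_state=0)
        noisy = gs.FeatureTable(
            table.sample_ids, table.feature_ids, table.values.copy(), table.labels
        )
        noisy.values[half:] += 100.0  # perturb validation rows only
        t2 = gs.build_importance_tensor(noisy, folds, roster=["anova_f"], random_state=0)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_empty_roster_rejected(self, small_table):
        table, _ = small_table
        folds = gs.make_cv_folds(table.labels, seed=0, n_folds=2)
        with pytest.raises(ValueError, match="roster"):
            gs.build_importance_tensor(table, folds, roster=[])


def test_tensor_persistence_roundtrip(tmp_path, rng):
    tensor = ImportanceTensor(
        ["s1", "s2"], ["a", "b", "c"], rng.uniform(0, 1, size=(2, 2, 3))
    )
    gs.selectors.save_tensor(tensor, str(tmp_path / "imp.npz"))
    back = gs.selectors.load_tensor(str(tmp_path / "imp.npz"))
    np.testing.assert_array_equal(back.values, tensor.values)
    assert back.feature_ids == tensor.feature_ids
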
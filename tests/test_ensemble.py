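import numpy as np
import pytest

from plasmasig import (
    BaggedEnsemble,
    TreeNode,
    fit_ensemble,
    fit_tree,
    gini_impurity,
    predict,
    select_trees,
    split_train_validation,
)

from _oracles import brute_force_best_split


class TestSplit:
    def test_study_sized_split_matches_published_validation_counts(self):
        labels = np.array(["LAC"] * 144 + ["benign"] * 68)
        split = split_train_validation(labels, fraction=0.8, seed=3)
        val = labels[split.val_idx]
        assert int((val == "LAC").sum()) == 29
        assert int((val == "benign").sum()) == 14

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            split_train_validation(["a", "a", "b", "b"], fraction=1.0)
        with pytest.raises(ValueError):
            split_train_validation(["a", "a", "b", "b"], fraction=0.0)

    def test_same_seed_identical_different_seed_not(self):
        labels = ["a"] * 30 + ["b"] * 20
        s1 = split_train_validation(labels, seed=5)
        s2 = split_train_validation(labels, seed=5)
        s3 = split_train_validation(labels, seed=6)
        np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
        assert not np.array_equal(s1.train_idx, s3.train_idx)

    def test_disjoint_and_exhaustive(self):
        labels = ["a"] * 17 + ["b"] * 9
        s = split_train_validation(labels, fraction=0.75, seed=0)
        both = np.concatenate([s.train_idx, s.val_idx])
        assert sorted(both) == list(range(26))


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected", [((5, 5), 0.5), ((10, 0), 0.0), ((3, 1), 0.375)]
    )
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestFitTree:
    def test_separable_1d_single_split(self, rng):
        x = np.concatenate([rng.uniform(-2, -0.5, 10), rng.uniform(0.5, 2, 10)])
        y = np.array([0] * 10 + [1] * 10)
        tree = fit_tree(x[:, None], y, feature_subsample=1, min_leaf=1, rng=rng)
        assert not tree.is_leaf
        assert -0.5 < tree.threshold < 0.5
        assert tree.left.is_leaf and tree.right.is_leaf
        assert tree.left.prediction == 0 and tree.right.prediction == 1

    def test_pure_labels_give_single_leaf(self, rng):
        tree = fit_tree(rng.normal(size=(8, 3)), np.zeros(8, dtype=int), rng=rng)
        assert tree.is_leaf and tree.prediction == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_root_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
        tree = fit_tree(X, y, feature_subsample=2, min_leaf=3, rng=rng)
        oracle = brute_force_best_split(X, y, min_leaf=3)
        assert oracle is not None and not tree.is_leaf
        assert tree.feature == oracle[1]
        assert tree.threshold == pytest.approx(oracle[2])
        assert tree.impurity_decrease * n == pytest.approx(oracle[0])

    def test_min_leaf_respected(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        tree = fit_tree(X, y, min_leaf=5, rng=rng)
        assert all(leaf.n_train >= 5 for leaf in tree.leaves())

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_tree(np.zeros((4, 2)), np.zeros(5, dtype=int), rng=rng)


class TestFitEnsemble:
    def _data(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        y = np.where(X[:, 0] + rng.normal(scale=0.8, size=n) > 0, "pos", "neg")
        if len(set(y)) == 1:
            y[0] = "pos" if y[0] == "neg" else "neg"
        return X, y

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_ensemble(np.zeros((4, 2)), ["a"] * 4, n_trees=2)

    def test_oob_fraction_near_e_inverse(self):
        n = 343
        X = np.random.default_rng(1).normal(size=(n, 3))
        y = np.array(["a", "b"] * (n // 2) + ["a"])
        ens = fit_ensemble(X, y, n_trees=100, seed=7, min_leaf=50)
        oob_fracs = [
            1 - len(np.unique(b)) / n for b in ens.bootstrap_indices
        ]
        # closed form: (1 − 1/n)^n → e⁻¹ of the sample is out-of-bag
        assert abs(np.mean(oob_fracs) - (1 - 1 / n) ** n) < 0.03
        assert abs(np.mean(oob_fracs) - np.exp(-1)) < 0.03

    def test_reproducible_per_seed(self):
        X, y = self._data()
        e1 = fit_ensemble(X, y, n_trees=20, seed=11, positive_class="pos")
        e2 = fit_ensemble(X, y, n_trees=20, seed=11, positive_class="pos")
        _, s1 = predict(e1, X)
        _, s2 = predict(e2, X)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(e1.tree_weights, e2.tree_weights)

    def test_weights_are_one_minus_oob_error(self):
        X, y = self._data(3)
        ens = fit_ensemble(X, y, n_trees=30, seed=2, positive_class="pos")
        finite = ~np.isnan(ens.oob_error_per_tree)
        np.testing.assert_allclose(
            ens.tree_weights[finite], np.clip(1 - ens.oob_error_per_tree[finite], 0, None)
        )

    def test_training_accuracy_interpolates(self):
        X, y = self._data(5, n=60)
        ens = fit_ensemble(X, y, n_trees=300, min_leaf=1, seed=4, positive_class="pos")
        labels, _ = predict(ens, X)
        assert np.mean(labels == y) >= 0.97

    def test_single_tree_ensemble_equals_its_tree(self):
        X, y = self._data(8)
        ens = fit_ensemble(X, y, n_trees=1, seed=9, positive_class="pos")
        labels, score = predict(ens, X)
        tree_votes = ens.trees[0].predict(X)
        np.testing.assert_array_equal(score, tree_votes.astype(float))


class TestSelectTrees:
    def _ensemble(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 0] > 0, "pos", "neg")
        return fit_ensemble(X, y, n_trees=40, seed=seed, positive_class="pos")

    def test_k_equal_n_selects_all(self):
        ens = self._ensemble()
        assert select_trees(ens, ens.n_trees).selected.all()

    def test_k_one_selects_max_weight(self):
        ens = self._ensemble(1)
        sel = select_trees(ens, 1)
        chosen = int(np.flatnonzero(sel.selected)[0])
        assert ens.tree_weights[chosen] == ens.tree_weights.max()

    def test_selected_mean_weight_dominates(self):
        for seed in range(5):
            ens = self._ensemble(seed + 10)
            sel = select_trees(ens, 20)
            w = sel.tree_weights
            assert w[sel.selected].mean() >= w[~sel.selected].mean()

    def test_k_out_of_range(self):
        ens = self._ensemble(2)
        with pytest.raises(ValueError):
            select_trees(ens, 0)
        with pytest.raises(ValueError):
            select_trees(ens, ens.n_trees + 1)


class TestPredict:
    def _manual_ensemble(self, votes, weights):
        trees = [
            TreeNode(n_train=2, counts=(1, 1), prediction=v) for v in votes
        ]
        n = len(trees)
        return BaggedEnsemble(
            trees=trees,
            bootstrap_indices=[np.arange(2)] * n,
            oob_error_per_tree=np.zeros(n),
            tree_weights=np.asarray(weights, dtype=float),
            selected=np.ones(n, dtype=bool),
            classes=("neg", "pos"),
            protein_ids=("P1",),
            seed=0,
        )

    def test_unanimous_positive_scores_one(self):
        ens = self._manual_ensemble([1, 1, 1], [0.5, 0.9, 0.7])
        labels, score = predict(ens, np.zeros((4, 1)))
        assert np.all(score == 1.0) and np.all(labels == "pos")

    def test_exact_tie_goes_negative(self):
        ens = self._manual_ensemble([1, 0], [0.6, 0.6])
        labels, score = predict(ens, np.zeros((1, 1)))
        assert score[0] == pytest.approx(0.5)
        assert labels[0] == "neg"

    def test_column_mismatch_rejected(self):
        ens = self._manual_ensemble([1], [1.0])
        with pytest.raises(ValueError):
            predict(ens, np.zeros((2, 3)))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path, rng):
        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 1] > 0, "pos", "neg")
        ens = fit_ensemble(X, y, n_trees=15, seed=3, positive_class="pos")
        ens = select_trees(ens, 7)
        path = tmp_path / "ens.json"
        ens.to_json(path)
        back = BaggedEnsemble.from_json(path)
        l1, s1 = predict(ens, X)
        l2, s2 = predict(back, X)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(s1, s2)
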
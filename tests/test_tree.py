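"""CART split selection, prediction and ROC-AUC against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from skinrems.errors import InputError
from skinrems.synthetic import simulate_tree_cohort
from skinrems.tree import (
    DecisionTree,
    Leaf,
    Split,
    TreeParams,
    build_tree,
    gini,
    predict,
    predict_table,
    roc_auc,
)


def brute_force_best_decrease(X: pd.DataFrame, y: np.ndarray, min_leaf: int) -> float:
    """Exhaustive search over every (feature, midpoint) split; independent oracle."""
    classes = np.unique(y)
    parent = gini(np.array([(y == c).sum() for c in classes], dtype=float))
    n = len(y)
    best = -np.inf
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        for a, b in itertools.pairwise(np.unique(v)):
            thr = (a + b) / 2
            left = v <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            gl = gini(np.array([(y[left] == c).sum() for c in classes], dtype=float))
            gr = gini(np.array([(y[~left] == c).sum() for c in classes], dtype=float))
            best = max(best, parent - (nl * gl + nr * gr) / n)
    return best


class TestBuildTree:
    def test_separable_midpoint_single_split(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]})
        y = [0, 0, 0, 1, 1, 1]
        tree = build_tree(X, y, TreeParams(min_leaf=1))
        assert tree.splits() == [("f", 5.0)]
        assert isinstance(tree.root.left, Leaf) and isinstance(tree.root.right, Leaf)
        assert tree.root.left.proportions[0] == 1.0
        assert tree.root.right.proportions[1] == 1.0
        preds = predict_table(tree, X)
        assert (preds["label"].to_numpy() == y).all()  # pure leaves -> 100% training accuracy

    def test_root_split_matches_brute_force_oracle(self, rng):
        """Chosen split's impurity decrease equals the exhaustive optimum."""
        for seed in range(15):
            r = np.random.default_rng(seed)
            n = int(r.integers(20, 120))
            k = int(r.integers(1, 5))
            X = pd.DataFrame(
                r.normal(size=(n, k)), columns=[f"f{j}" for j in range(k)]
            )
            y = r.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            params = TreeParams(min_leaf=5, max_depth=1, min_impurity_decrease=0.0)
            tree = build_tree(X, y, params)
            oracle = brute_force_best_decrease(X, y, params.min_leaf)
            if isinstance(tree.root, Leaf):
                assert oracle <= 0.0 or oracle == -np.inf
                continue
            v = X[tree.root.feature].to_numpy()
            left = v <= tree.root.threshold
            counts = lambda m: np.array([(y[m] == c).sum() for c in (0, 1)], dtype=float)
            achieved = gini(counts(np.ones(n, bool))) - (
                left.sum() * gini(counts(left)) + (~left).sum() * gini(counts(~left))
            ) / n
            assert achieved == pytest.approx(oracle, abs=1e-12)

    def test_two_level_structure_recovery(self):
        X, y, truth = simulate_tree_cohort(seed=42)
        tree = build_tree(X, y, TreeParams(min_leaf=5, max_depth=2), pos_label=1)
        root_feature, root_threshold = truth["root"]
        assert tree.root.feature == root_feature
        gap = np.diff(np.sort(X[root_feature].to_numpy()))
        max_gap = gap.max()
        assert abs(tree.root.threshold - root_threshold) <= max_gap
        assert truth["child"][0] in tree.split_features()

    def test_single_class_gives_single_leaf(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        tree = build_tree(X, [1] * 6)
        assert isinstance(tree.root, Leaf)
        assert predict(tree, {"f": 100.0}) == (1, 1.0)

    def test_constant_features_give_single_leaf(self):
        X = pd.DataFrame({"f": np.ones(20)})
        y = [0] * 10 + [1] * 10
        tree = build_tree(X, y)
        assert isinstance(tree.root, Leaf)

    def test_weighted_child_impurity_never_exceeds_parent(self, rng):
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = pd.DataFrame({"a": r.normal(size=60), "b": r.normal(size=60)})
            y = r.integers(0, 2, size=60)
            if len(np.unique(y)) < 2:
                continue
            tree = build_tree(X, y, TreeParams(min_leaf=5, max_depth=3, min_impurity_decrease=0.0))

            def check(node, idx):
                if isinstance(node, Leaf):
                    return
                counts = lambda m: np.array([(y[m] == c).sum() for c in (0, 1)], dtype=float)
                v = X.loc[idx, node.feature].to_numpy()
                mask = np.zeros(len(y), bool)
                mask[idx] = True
                left = mask & (X[node.feature].to_numpy() <= node.threshold)
                right = mask & ~left
                parent_imp = gini(counts(mask))
                child = (left.sum() * gini(counts(left)) + right.sum() * gini(counts(right))) / mask.sum()
                assert child <= parent_imp + 1e-12
                check(node.left, np.flatnonzero(left))
                check(node.right, np.flatnonzero(right))

            check(tree.root, np.arange(len(y)))


class TestPredict:
    def fitted(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]})
        return build_tree(X, [0, 0, 0, 1, 1, 1], TreeParams(min_leaf=1), pos_label=0)

    def test_boundary_value_routes_left(self):
        tree = self.fitted()
        label, score = predict(tree, {"f": 5.0})
        assert label == 0  # value equal to threshold goes to the '<=' branch
        assert score == 1.0

    def test_missing_feature_is_hard_error(self):
        with pytest.raises(InputError):
            predict(self.fitted(), {"g": 1.0})


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], pos_label=1)
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        r = roc_auc([0.5] * 10, [0, 1] * 5, pos_label=1)
        assert r.auc == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        """Trapezoidal AUC equals mean over (pos, neg) pairs with 1/2 for ties."""
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = int(r.integers(10, 60))
            scores = np.round(r.normal(size=n), 1)  # rounding forces ties
            labels = r.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            oracle = np.mean(
                [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
            )
            assert roc_auc(scores, labels, pos_label=1).auc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        a = roc_auc(scores, labels, pos_label=1).auc
        b = roc_auc(np.exp(3 * scores) + 7, labels, pos_label=1).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = np.round(rng.normal(size=200), 1)
        labels = rng.integers(0, 2, size=200)
        assert roc_auc(scores, labels, pos_label=1).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        r = roc_auc(scores, labels, pos_label=1)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)

    def test_single_class_errors(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.2], [1, 1])
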
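"""Classification trees (C&RT) with cut-off extraction and ROC evaluation.

Greedy binary recursive partitioning with the Gini impurity criterion.
Split candidates are midpoints of consecutive sorted unique feature values;
the selected split maximises the impurity decrease, with ties broken
deterministically by (lexicographically smallest feature name, then
smallest threshold). Records with a value equal to a threshold are routed
to the "<=" (left) branch, matching the cut-off phrasing "less than or
equal to". No surrogate splits: a missing feature at prediction time is a
hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class TreeParams:
    """Growth limits guarding against overfitting."""

    min_leaf: int = 5
    max_depth: int = 3
    min_impurity_decrease: float = 1e-4


@dataclass
class Leaf:
    label: object
    proportions: Dict[object, float]
    n: int


@dataclass
class Split:
    feature: str
    threshold: float
    left: Union["Split", Leaf]  # values <= threshold
    right: Union["Split", Leaf]  # values > threshold


@dataclass
class DecisionTree:
    root: Union[Split, Leaf]
    params: TreeParams
    classes: Tuple
    pos_label: object
    feature_names: List[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        def count(node):
            if isinstance(node, Leaf):
                return 1
            return count(node.left) + count(node.right)

        return count(self.root)

    @property
    def depth(self) -> int:
        def d(node):
            if isinstance(node, Leaf):
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def split_features(self) -> List[str]:
        """Feature names used at internal nodes, pre-order, with repeats."""
        out = []

        def walk(node):
            if isinstance(node, Split):
                out.append(node.feature)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def splits(self) -> List[Tuple[str, float]]:
        out = []

        def walk(node):
            if isinstance(node, Split):
                out.append((node.feature, node.threshold))
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out


def gini(counts: np.ndarray) -> float:
    """Gini impurity 1 - sum p_k^2 of a class-count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split_for_feature(
    values: np.ndarray, y_codes: np.ndarray, n_classes: int, min_leaf: int
) -> Optional[Tuple[float, float]]:
    """(impurity decrease, threshold) of the best midpoint split, or None."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    y = y_codes[order]
    n = len(v)
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    parent_imp = gini(parent_counts)

    # cumulative class counts after each prefix
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    cum = np.cumsum(onehot, axis=0)

    best = None
    for i in range(n - 1):
        if v[i + 1] <= v[i]:
            continue
        nl = i + 1
        nr = n - nl
        if nl < min_leaf or nr < min_leaf:
            continue
        left_counts = cum[i]
        right_counts = parent_counts - left_counts
        child_imp = (nl * gini(left_counts) + nr * gini(right_counts)) / n
        decrease = parent_imp - child_imp
        if best is None or decrease > best[0] + 1e-15:
            best = (decrease, float((v[i] + v[i + 1]) / 2.0))
    return best


def _grow(
    X: pd.DataFrame,
    y_codes: np.ndarray,
    classes: Sequence,
    params: TreeParams,
    depth: int,
) -> Union[Split, Leaf]:
    n_classes = len(classes)
    counts = np.bincount(y_codes, minlength=n_classes).astype(float)

    def leaf() -> Leaf:
        # majority label; ties broken toward the first class for determinism
        label = classes[int(np.argmax(counts))]
        props = {c: float(counts[i] / counts.sum()) for i, c in enumerate(classes)}
        return Leaf(label=label, proportions=props, n=int(counts.sum()))

    if (
        depth >= params.max_depth
        or counts.sum() < 2 * params.min_leaf
        or gini(counts) == 0.0
        or X.shape[1] == 0
    ):
        return leaf()

    best = None  # (decrease, feature, threshold)
    for feature in sorted(X.columns):
        values = X[feature].to_numpy(dtype=float)
        cand = _best_split_for_feature(values, y_codes, n_classes, params.min_leaf)
        if cand is None:
            continue
        decrease, threshold = cand
        if best is None or decrease > best[0] + 1e-15:
            best = (decrease, feature, threshold)
    if best is None or best[0] < params.min_impurity_decrease:
        return leaf()

    _, feature, threshold = best
    mask = X[feature].to_numpy(dtype=float) <= threshold
    return Split(
        feature=feature,
        threshold=threshold,
        left=_grow(X.loc[mask], y_codes[mask], classes, params, depth + 1),
        right=_grow(X.loc[~mask], y_codes[~mask], classes, params, depth + 1),
    )


def build_tree(
    features: pd.DataFrame,
    labels: Sequence,
    params: Optional[TreeParams] = None,
    pos_label=None,
) -> DecisionTree:
    """Fit a binary C&RT classifier.

    ``pos_label`` names the class whose leaf proportion becomes the
    prediction score (defaults to the lexically larger of the two labels).
    Single-class or all-constant input yields a single-leaf tree.
    """
    params = params or TreeParams()
    y = pd.Series(list(labels))
    if len(y) != len(features):
        raise InputError("features and labels length mismatch")
    classes = tuple(sorted(y.unique(), key=str))
    if len(classes) > 2:
        raise InputError(f"binary trees only; got classes {classes}")
    if pos_label is None:
        pos_label = classes[-1]
    elif pos_label not in classes:
        raise InputError(f"pos_label {pos_label!r} not among classes {classes}")
    code = {c: i for i, c in enumerate(classes)}
    y_codes = y.map(code).to_numpy()
    root = _grow(features.reset_index(drop=True), y_codes, classes, params, depth=0)
    return DecisionTree(
        root=root,
        params=params,
        classes=classes,
        pos_label=pos_label,
        feature_names=sorted(features.columns),
    )


def predict(tree: DecisionTree, record: Mapping[str, float]) -> Tuple[object, float]:
    """Route one record to a leaf: (class label, positive-class score)."""
    node = tree.root
    while isinstance(node, Split):
        if node.feature not in record:
            raise InputError(f"record missing feature {node.feature!r}")
        node = node.left if record[node.feature] <= node.threshold else node.right
    return node.label, float(node.proportions.get(tree.pos_label, 0.0))


def predict_table(tree: DecisionTree, features: pd.DataFrame) -> pd.DataFrame:
    rows = [predict(tree, rec) for rec in features.to_dict(orient="records")]
    return pd.DataFrame(rows, columns=["label", "score"], index=features.index)


@dataclass
class RocResult:
    """ROC curve points and area, with the raw score/label pairs."""

    scores: np.ndarray
    labels: np.ndarray
    pos_label: object
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores: Sequence[float], labels: Sequence, pos_label=None) -> RocResult:
    """ROC curve and trapezoidal AUC.

    Thresholds sweep the unique scores from high to low; tied scores move
    as a block, so the trapezoidal area credits ties with 1/2 — making the
    AUC equal to the pairwise concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels), key=str)
    if len(classes) != 2:
        raise InputError(f"need both classes present, got {classes}")
    if pos_label is None:
        pos_label = classes[-1]
    pos = labels == pos_label
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)

    order = np.argsort(-scores, kind="mergesort")
    sorted_pos = pos[order].astype(float)
    sorted_scores = scores[order]
    # collapse tied scores into single curve points
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tp = np.cumsum(sorted_pos)[distinct]
    fp = np.cumsum(1.0 - sorted_pos)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(scores=scores, labels=labels, pos_label=pos_label, fpr=fpr, tpr=tpr, auc=auc)
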
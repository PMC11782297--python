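"""From-scratch decision-tree learner driven by Shannon entropy.

Trees are grown greedily: at each node the (feature, threshold) pair
maximizing the information gain IG = H(parent) - sum_c (n_c/n) H(child_c)
is chosen, with H the Shannon entropy in bits, H = -sum_x p(x) log2 p(x).
Candidate thresholds are midpoints between consecutive distinct observed
feature values.  Samples with value <= threshold go left.  Training is
fully deterministic: ties in gain are broken by (lower feature index, lower
threshold), leaf predictions break count ties by the lexicographically
smallest class label.  Tree depth is the only tuned hyperparameter and is
selected on a validation split by macro-averaged per-class accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClassDistribution",
    "DecisionTree",
    "SplitCandidate",
    "TreeNode",
    "best_split",
    "entropy",
    "fit_tree",
    "information_gain",
    "macro_accuracy",
    "predict",
    "select_depth",
]

_GAIN_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ClassDistribution:
    """Class counts at a node."""

    counts: tuple[tuple[str, int], ...]  # sorted by class label

    def __post_init__(self):
        if not self.counts or sum(c for _x, c in self.counts) < 1:
            raise ValueError("empty class distribution")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "ClassDistribution":
        keys = sorted(set(labels))
        return cls(tuple((k, sum(1 for y in labels if y == k)) for k in keys))

    @property
    def total(self) -> int:
        return sum(c for _x, c in self.counts)

    def proportions(self) -> dict[str, float]:
        t = self.total
        return {x: c / t for x, c in self.counts}

    @property
    def argmax(self) -> str:
        # highest count; ties -> lexicographically smallest label
        return sorted(self.counts, key=lambda xc: (-xc[1], xc[0]))[0][0]


def entropy(d: ClassDistribution) -> float:
    """Shannon entropy in bits, with 0*log(0) := 0."""
    total = d.total
    h = 0.0
    for _x, c in d.counts:
        if c > 0:
            p = c / total
            h -= p * np.log2(p)
    return float(h)


def information_gain(
    parent: ClassDistribution, children: Sequence[ClassDistribution]
) -> float:
    """IG of a split: parent entropy minus the weighted child entropies."""
    n = parent.total
    if sum(c.total for c in children) != n:
        raise ValueError("children do not partition the parent samples")
    return entropy(parent) - sum(c.total / n * entropy(c) for c in children)


@dataclass(frozen=True)
class SplitCandidate:
    feature: int  # column index into the feature matrix
    threshold: float  # midpoint between two consecutive observed values
    gain: float


@dataclass
class TreeNode:
    """Internal node (split + children) or leaf (distribution + prediction)."""

    distribution: ClassDistribution
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None  # samples with value <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def prediction(self) -> str:
        return self.distribution.argmax


@dataclass
class DecisionTree:
    root: TreeNode
    max_depth: int
    n_features: int

    def depth(self) -> int:
        def rec(node):
            if node.is_leaf:
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root)

    # -- JSON round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(node: TreeNode) -> dict:
            d = {"counts": list(map(list, node.distribution.counts))}
            if not node.is_leaf:
                d.update(
                    feature=node.split.feature,
                    threshold=node.split.threshold,
                    gain=node.split.gain,
                    left=enc(node.left),
                    right=enc(node.right),
                )
            return d

        return {
            "max_depth": self.max_depth,
            "n_features": self.n_features,
            "root": enc(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        def dec(nd: dict) -> TreeNode:
            dist = ClassDistribution(tuple((x, int(c)) for x, c in nd["counts"]))
            if "feature" in nd:
                return TreeNode(
                    distribution=dist,
                    split=SplitCandidate(
                        int(nd["feature"]), float(nd["threshold"]), float(nd["gain"])
                    ),
                    left=dec(nd["left"]),
                    right=dec(nd["right"]),
                )
            return TreeNode(distribution=dist)

        return cls(
            root=dec(d["root"]),
            max_depth=int(d["max_depth"]),
            n_features=int(d["n_features"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------


def _entropy_from_counts(counts: np.ndarray, axis=-1) -> np.ndarray:
    """Vectorized entropy (bits) of count rows."""
    totals = counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        term = np.where(counts > 0, p * np.log2(p), 0.0)
    return -term.sum(axis=axis)


def best_split(
    X: np.ndarray, y: Sequence[str], min_leaf: int = 1
) -> SplitCandidate | None:
    """Exhaustive search over all features and midpoint thresholds.

    Returns the candidate with maximal information gain, or None if no split
    achieves positive gain (e.g. constant features or a pure node).  Ties
    within 1e-12 bits prefer the lower feature index, then lower threshold.
    Splits leaving fewer than ``min_leaf`` samples on either side are not
    considered.
    """
    X = np.asarray(X, dtype=float)
    n, n_feat = X.shape
    classes = np.unique(np.asarray(y, dtype=object))
    if n < 2 or len(classes) < 2:
        return None
    code = {c: i for i, c in enumerate(classes)}
    codes = np.array([code[v] for v in y])
    parent_counts = np.bincount(codes, minlength=len(classes)).astype(float)
    parent_h = float(_entropy_from_counts(parent_counts))

    best: SplitCandidate | None = None
    for f in range(n_feat):
        col = X[:, f]
        order = np.argsort(col, kind="stable")
        xs = col[order]
        ys = codes[order]
        onehot = np.zeros((n, len(classes)))
        onehot[np.arange(n), ys] = 1.0
        left = np.cumsum(onehot, axis=0)  # counts for split after position i
        left_n = np.arange(1, n + 1, dtype=float)
        right = parent_counts[None, :] - left
        right_n = n - left_n
        # valid boundaries: between distinct values, respecting min_leaf
        valid = np.zeros(n, dtype=bool)
        valid[: n - 1] = xs[:-1] < xs[1:]
        if min_leaf > 1:
            valid &= (left_n >= min_leaf) & (right_n >= min_leaf)
        else:
            valid &= right_n >= 1
        if not valid.any():
            continue
        h_left = _entropy_from_counts(left)
        h_right = _entropy_from_counts(np.where(right < 0, 0, right))
        with np.errstate(invalid="ignore"):
            cond = (left_n * h_left + right_n * h_right) / n
        gains = parent_h - cond
        gains[~valid] = -np.inf
        i = int(np.argmax(gains))  # first index among equal maxima -> lowest threshold
        g = float(gains[i])
        if g <= _GAIN_TIE_TOL:
            continue
        threshold = (xs[i] + xs[i + 1]) / 2.0
        cand = SplitCandidate(f, float(threshold), g)
        if best is None or g > best.gain + _GAIN_TIE_TOL:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------


def fit_tree(
    X: np.ndarray,
    y: Sequence[str],
    max_depth: int,
    min_leaf: int = 5,
) -> DecisionTree:
    """Greedy recursive partitioning up to ``max_depth``.

    Recursion stops at pure nodes, at nodes with fewer than ``2 * min_leaf``
    samples, or when no positive-gain split exists.  A single-class input
    yields a single-leaf tree.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        labels = [y[i] for i in idx]
        dist = ClassDistribution.from_labels(labels)
        if (
            depth >= max_depth
            or len(set(labels)) < 2
            or len(idx) < 2 * min_leaf
        ):
            return TreeNode(distribution=dist)
        cand = best_split(X[idx], labels, min_leaf=min_leaf)
        if cand is None:
            return TreeNode(distribution=dist)
        mask = X[idx, cand.feature] <= cand.threshold
        return TreeNode(
            distribution=dist,
            split=cand,
            left=grow(idx[mask], depth + 1),
            right=grow(idx[~mask], depth + 1),
        )

    root = grow(np.arange(len(y)), 0)
    return DecisionTree(root=root, max_depth=max_depth, n_features=X.shape[1])


def predict(tree: DecisionTree, x: Sequence[float]) -> tuple[str, dict[str, float]]:
    """Route one feature vector to a leaf; values equal to a threshold go left.

    Returns (predicted class, leaf class proportions).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != tree.n_features:
        raise ValueError(
            f"feature vector has {x.shape[0]} entries, tree expects "
            f"{tree.n_features}"
        )
    node = tree.root
    while not node.is_leaf:
        node = node.left if x[node.split.feature] <= node.split.threshold else node.right
    return node.prediction, node.distribution.proportions()


def predict_batch(tree: DecisionTree, X: np.ndarray) -> list[str]:
    return [predict(tree, row)[0] for row in np.asarray(X, dtype=float)]


def macro_accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Macro-averaged per-class accuracy (mean per-class recall)."""
    classes = sorted(set(y_true))
    accs = []
    for c in classes:
        idx = [i for i, y in enumerate(y_true) if y == c]
        accs.append(sum(1 for i in idx if y_pred[i] == c) / len(idx))
    return float(np.mean(accs))


def select_depth(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_val: np.ndarray,
    y_val: Sequence[str],
    depths: Sequence[int] = (1, 2, 3, 4),
    min_leaf: int = 5,
    one_se: bool = True,
) -> DecisionTree:
    """Fit one tree per candidate depth; pick by validation macro accuracy.

    With ``one_se`` (default) the smallest depth whose validation score lies
    within one binomial standard error of the best score is chosen — the
    classic one-standard-error parsimony rule for tree models.  Validation
    accuracies on a few hundred spectra differ by chance on the order of
    that standard error, so treating such differences as ties avoids
    growing depth (and appending rule conditions) on noise; a genuinely
    better deeper tree still wins.  With ``one_se=False`` the plain argmax
    is used, ties breaking toward the smallest depth.
    """
    n_val = len(y_val)
    if n_val == 0:
        raise ValueError("validation set must be nonempty")
    fitted: list[tuple[int, DecisionTree, float]] = []
    for d in sorted(depths):
        tree = fit_tree(X_train, y_train, max_depth=d, min_leaf=min_leaf)
        score = macro_accuracy(y_val, predict_batch(tree, X_val))
        fitted.append((d, tree, score))
    best_score = max(s for _d, _t, s in fitted)
    tol = 0.0
    if one_se:
        tol = float(np.sqrt(max(best_score * (1 - best_score), 0.0) / n_val))
    for _d, tree, score in fitted:
        if score >= best_score - tol - 1e-12:
            return tree
    raise AssertionError("unreachable")  # pragma: no cover
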
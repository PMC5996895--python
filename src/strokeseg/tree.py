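"""Youden-index decision tree with pseudo-count node probabilities.

The tree is grown one node at a time.  At every node, for every feature,
the threshold maximizing Youden's J = sensitivity + specificity - 1 is
found (candidates are midpoints between consecutive distinct sorted
values, scanning both orientations of "predicted positive"); the feature
with the largest J wins and the data splits into a >=-branch and a
<-branch.  Growth continues until leaves are pure, a depth cap is hit, or
no split exists (identical feature vectors with mixed labels become forced
leaves).  Every node stores the preliminary prediction

    p(N) = (n1 + 1) / (n + 2),

which shrinks toward 0.5 for small nodes, so that depth-truncated
predictions p_d(x) remain usable as lesion probabilities.

Growth is fully deterministic: ties between thresholds break toward the
smallest threshold, ties between features toward the lowest feature index.
"""

from __future__ import annotations

import json
import os
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "SplitCandidate",
    "TreeNode",
    "YoudenTreeClassifier",
    "best_youden_split",
    "node_prediction",
    "build_tree",
    "predict_at_depth",
]

FORMAT_VERSION = 1


class SplitCandidate(NamedTuple):
    """A candidate (threshold, quality) pair for one variable.

    ``youden_j`` is the larger of J and -J at the threshold: the >=-side is
    "predicted positive" when ``orientation`` is ``"ge"`` and the <-side
    when it is ``"lt"`` (lesions may be high-valued, as on DWI, or
    low-valued, as on ADC).
    """

    threshold: float
    youden_j: float
    orientation: str


def node_prediction(n1: int, n: int) -> float:
    """Pseudo-count probability (n1+1)/(n+2); 0.5 for an empty node."""
    if not 0 <= n1 <= n:
        raise ValueError(f"need 0 <= n1 <= n, got n1={n1}, n={n}")
    return (n1 + 1) / (n + 2)


def _scan_feature(values: np.ndarray, labels: np.ndarray):
    """Best (|J|, threshold, J_forward) for one feature, or None.

    Vectorized scan over midpoints between consecutive distinct sorted
    values; requires both classes present.  First occurrence of the max on
    the ascending threshold grid implements the smallest-threshold tie rule.
    """
    order = np.argsort(values, kind="stable")
    vs = values[order]
    ys = labels[order]
    cuts = np.nonzero(vs[1:] > vs[:-1])[0]  # split after sorted index i
    if cuts.size == 0:
        return None
    pos = int(ys.sum())
    neg = ys.size - pos
    if pos == 0 or neg == 0:
        return None
    cpos = np.cumsum(ys)[cuts]
    tp_ge = pos - cpos  # positives on the >= side
    fp_ge = neg - (cuts + 1 - cpos)
    # single exact-integer division: equal rational J values compare equal
    j_fwd = (tp_ge * neg - fp_ge * pos) / (pos * neg)
    j_abs = np.abs(j_fwd)
    i = int(np.argmax(j_abs))
    thr = 0.5 * (vs[cuts[i]] + vs[cuts[i] + 1])
    return float(j_abs[i]), float(thr), float(j_fwd[i])


def best_youden_split(values, labels) -> SplitCandidate | None:
    """Best Youden-index split of one variable.

    Returns ``None`` when no split exists (all values identical).  Raises
    ``ValueError`` when only one class is present (J undefined).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class; J is undefined")
    res = _scan_feature(values, labels.astype(np.float64))
    if res is None:
        return None
    j_abs, thr, j_fwd = res
    return SplitCandidate(thr, j_abs, "ge" if j_fwd >= 0 else "lt")


class TreeNode:
    """One node of the tree; a leaf when ``split`` is None."""

    __slots__ = (
        "p",
        "n",
        "n1",
        "depth",
        "variable",
        "threshold",
        "child_ge",
        "child_lt",
        "forced_leaf",
    )

    def __init__(self, depth: int = 0):
        self.depth = depth
        self.p = 0.5
        self.n = 0
        self.n1 = 0
        self.variable: int | None = None
        self.threshold: float | None = None
        self.child_ge: "TreeNode | None" = None
        self.child_lt: "TreeNode | None" = None
        self.forced_leaf = False

    @property
    def is_leaf(self) -> bool:
        return self.child_ge is None

    def to_dict(self) -> dict:
        d = {"p": self.p, "n": self.n, "n1": self.n1, "depth": self.depth}
        if self.forced_leaf:
            d["forced_leaf"] = True
        if not self.is_leaf:
            d["variable"] = self.variable
            d["threshold"] = self.threshold
            d["child_ge"] = self.child_ge.to_dict()
            d["child_lt"] = self.child_lt.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(int(d["depth"]))
        node.p = float(d["p"])
        node.n = int(d["n"])
        node.n1 = int(d["n1"])
        node.forced_leaf = bool(d.get("forced_leaf", False))
        if "variable" in d:
            node.variable = int(d["variable"])
            node.threshold = float(d["threshold"])
            node.child_ge = cls.from_dict(d["child_ge"])
            node.child_lt = cls.from_dict(d["child_lt"])
        return node


def _grow(X: np.ndarray, y: np.ndarray, max_depth: int | None) -> TreeNode:
    n_features = X.shape[1]
    root = TreeNode(0)
    stack = [(root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        ysub = y[idx]
        node.n = int(idx.size)
        node.n1 = int(ysub.sum())
        node.p = node_prediction(node.n1, node.n)
        if node.n1 in (0, node.n):
            continue  # pure leaf
        if max_depth is not None and node.depth >= max_depth:
            continue
        best = None  # (j_abs, feature, threshold); strict > keeps lowest index
        for f in range(n_features):
            res = _scan_feature(X[idx, f], ysub.astype(np.float64))
            if res is not None and (best is None or res[0] > best[0]):
                best = (res[0], f, res[1])
        if best is None:
            node.forced_leaf = True  # duplicate feature vectors, mixed labels
            continue
        _, f, thr = best
        node.variable = f
        node.threshold = thr
        mask = X[idx, f] >= thr
        node.child_ge = TreeNode(node.depth + 1)
        node.child_lt = TreeNode(node.depth + 1)
        stack.append((node.child_ge, idx[mask]))
        stack.append((node.child_lt, idx[~mask]))
    return root


def _height(node: TreeNode) -> int:
    h = 0
    stack = [(node, 0)]
    while stack:
        nd, d = stack.pop()
        h = max(h, d)
        if not nd.is_leaf:
            stack.append((nd.child_ge, d + 1))
            stack.append((nd.child_lt, d + 1))
    return h


def _count_nodes(node: TreeNode) -> int:
    c = 0
    stack = [node]
    while stack:
        nd = stack.pop()
        c += 1
        if not nd.is_leaf:
            stack.extend((nd.child_ge, nd.child_lt))
    return c


class YoudenTreeClassifier(ClassifierMixin, BaseEstimator):
    """Decision tree classifier split on the maximal Youden index.

    Parameters
    ----------
    max_depth : int or None
        Depth cap during growth; None grows until purity (or forced
        leaves).

    Attributes
    ----------
    tree_ : TreeNode
        Root of the grown tree.
    height_ : int
        Maximal leaf depth (the trained depth).
    n_nodes_ : int
        Total node count.
    classes_ : ndarray
        Always ``[0, 1]`` ordering of the two classes seen in ``y``.
    """

    def __init__(self, max_depth: int | None = None):
        self.max_depth = max_depth

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if not np.isin(np.unique(y), (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0.0, 1.0])
        y01 = (y > 0.5).astype(np.float64)
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        self.n_features_in_ = X.shape[1]
        self.tree_ = _grow(X, y01, self.max_depth)
        self.height_ = _height(self.tree_)
        self.n_nodes_ = _count_nodes(self.tree_)
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X)
        p = _predict_depth(self.tree_, X, None)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= 0.5, self.classes_[-1], self.classes_[0])

    def predict_at_depth(self, X, depth: int) -> np.ndarray:
        """p of the node reached after ``depth`` traversal steps (clamped
        to the leaf when the path ends earlier)."""
        if depth < 0:
            raise ValueError("depth must be >= 0")
        X = self._check_X(X)
        return _predict_depth(self.tree_, X, int(depth))

    def predict_all_depths(self, X) -> np.ndarray:
        """Matrix of p_d(x) for every depth d: shape (height_+1, n_samples)."""
        X = self._check_X(X)
        out = np.empty((self.height_ + 1, X.shape[0]), dtype=np.float64)
        _fill_all_depths(self.tree_, X, np.arange(X.shape[0]), out)
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "tree_")
        return {
            "format_version": FORMAT_VERSION,
            "model": "youden_tree",
            "n_features": self.n_features_in_,
            "max_depth": self.max_depth,
            "height": self.height_,
            "root": self.tree_.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "YoudenTreeClassifier":
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported tree format: {d.get('format_version')!r}")
        clf = cls(max_depth=d.get("max_depth"))
        clf.n_features_in_ = int(d["n_features"])
        clf.classes_ = np.array([0.0, 1.0])
        clf.tree_ = TreeNode.from_dict(d["root"])
        clf.height_ = _height(clf.tree_)
        clf.n_nodes_ = _count_nodes(clf.tree_)
        return clf

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "YoudenTreeClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _predict_depth(root: TreeNode, X: np.ndarray, depth: int | None) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=np.float64)
    stack = [(root, np.arange(X.shape[0]), 0)]
    while stack:
        node, idx, d = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf or (depth is not None and d >= depth):
            out[idx] = node.p
            continue
        mask = X[idx, node.variable] >= node.threshold
        stack.append((node.child_ge, idx[mask], d + 1))
        stack.append((node.child_lt, idx[~mask], d + 1))
    return out


def _fill_all_depths(
    root: TreeNode, X: np.ndarray, all_idx: np.ndarray, out: np.ndarray
) -> None:
    stack = [(root, all_idx)]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            out[node.depth :, idx] = node.p  # clamp to the leaf
            continue
        out[node.depth, idx] = node.p
        mask = X[idx, node.variable] >= node.threshold
        stack.append((node.child_ge, idx[mask]))
        stack.append((node.child_lt, idx[~mask]))


# --- thin functional wrappers ----------------------------------------------


def build_tree(table, max_depth: int | None = None) -> YoudenTreeClassifier:
    """Fit a tree from a feature table (DataFrame with the four feature
    columns and a ``label`` column) or an (X, y) pair."""
    from .preprocess import FEATURE_NAMES

    if isinstance(table, tuple):
        X, y = table
    else:
        X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
        y = table["label"].to_numpy()
    return YoudenTreeClassifier(max_depth=max_depth).fit(X, y)


def predict_at_depth(tree: YoudenTreeClassifier, row, depth: int) -> float:
    row = np.atleast_2d(np.asarray(row, dtype=np.float64))
    return float(tree.predict_at_depth(row, depth)[0])
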
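"""Tree depth selection by leave-one-patient-out AUC.

To prune a tree trained on n patients, n auxiliary trees are grown, each
with one patient held out.  The held-out patient's voxels are pushed
through "their" tree to obtain depth-truncated probabilities p_d(x), whose
quality at each depth d is scored with the ROC AUC against the expert
labels.  Each patient contributes the smallest depth attaining their
maximal AUC; the chosen depth is the (lower) median over patients.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import FEATURE_NAMES
from .tree import TreeNode, YoudenTreeClassifier

__all__ = [
    "auc",
    "lower_median",
    "prune_tree",
    "select_depth",
    "DepthSelectionResult",
]


def auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney concordance P(s+ > s-) + 0.5 P(tie).

    Computed from average ranks, so ties contribute one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def lower_median(values) -> int:
    """Median of integers; for an even count, the lower middle value."""
    vs = sorted(int(v) for v in values)
    if not vs:
        raise ValueError("empty sequence")
    return vs[(len(vs) - 1) // 2]


def prune_tree(tree: YoudenTreeClassifier, depth: int) -> YoudenTreeClassifier:
    """Copy of the tree with every node at ``depth`` turned into a leaf.

    Predictions of the pruned tree equal ``predict_at_depth(tree, x, depth)``
    for every input.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    pruned = copy.deepcopy(tree)

    def _cut(node: TreeNode) -> None:
        if node.depth >= depth and not node.is_leaf:
            node.variable = None
            node.threshold = None
            node.child_ge = None
            node.child_lt = None
        elif not node.is_leaf:
            _cut(node.child_ge)
            _cut(node.child_lt)

    _cut(pruned.tree_)
    from .tree import _count_nodes, _height

    pruned.height_ = _height(pruned.tree_)
    pruned.n_nodes_ = _count_nodes(pruned.tree_)
    return pruned


@dataclass
class DepthSelectionResult:
    """Outcome of the leave-one-patient-out depth search."""

    per_patient_best_depth: dict[str, int]
    chosen_depth: int
    per_patient_auc_curves: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chosen_depth": self.chosen_depth,
            "per_patient_best_depth": dict(self.per_patient_best_depth),
            "per_patient_auc_curves": {
                pid: [float(a) for a in curve]
                for pid, curve in self.per_patient_auc_curves.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DepthSelectionResult":
        return cls(
            per_patient_best_depth={
                k: int(v) for k, v in d["per_patient_best_depth"].items()
            },
            chosen_depth=int(d["chosen_depth"]),
            per_patient_auc_curves={
                k: np.asarray(v, dtype=float)
                for k, v in d.get("per_patient_auc_curves", {}).items()
            },
        )

    def auc_curves_frame(self) -> pd.DataFrame:
        rows = []
        for pid, curve in self.per_patient_auc_curves.items():
            for d, a in enumerate(curve):
                rows.append({"patient_id": pid, "depth": d, "auc": float(a)})
        return pd.DataFrame(rows)


def select_depth(
    table: pd.DataFrame,
    *,
    max_depth: int | None = None,
    tree_cache: dict | None = None,
) -> DepthSelectionResult:
    """Choose the pruning depth from a cohort feature table.

    ``table`` holds one row per voxel with ``patient_id``, the four feature
    columns and ``label``.  Requires at least three patients.  Patients
    whose labels are single-class (e.g. empty lesions) are excluded from
    the AUC vote with a warning.  ``tree_cache`` (keyed by the frozenset of
    training patient ids) lets nested cross-validation reuse trees.

    The result is invariant to the ordering of patients in the table.
    """
    pids = sorted(map(str, pd.unique(table["patient_id"])))
    if len(pids) < 3:
        raise ValueError("depth selection requires at least 3 patients")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy()
    pid_arr = table["patient_id"].astype(str).to_numpy()

    best_depths: dict[str, int] = {}
    curves: dict[str, np.ndarray] = {}
    for pid in pids:
        held = pid_arr == pid
        y_ho = y[held]
        if y_ho.min() == y_ho.max():
            warnings.warn(
                f"patient {pid} has single-class labels; excluded from depth vote",
                stacklevel=2,
            )
            continue
        clf = _fit_cached(X[~held], y[~held], pid_arr[~held], max_depth, tree_cache)
        probs = clf.predict_all_depths(X[held])
        aucs = np.array([auc(probs[d], y_ho) for d in range(probs.shape[0])])
        best_depths[pid] = int(np.argmax(aucs))  # first max -> smallest depth
        curves[pid] = aucs
    if not best_depths:
        raise ValueError("no patient provided both classes; cannot select depth")
    return DepthSelectionResult(
        per_patient_best_depth=best_depths,
        chosen_depth=lower_median(best_depths.values()),
        per_patient_auc_curves=curves,
    )


def _fit_cached(
    X: np.ndarray,
    y: np.ndarray,
    pid_arr: np.ndarray,
    max_depth: int | None,
    tree_cache: dict | None,
) -> YoudenTreeClassifier:
    key = None
    if tree_cache is not None:
        key = (frozenset(np.unique(pid_arr)), max_depth)
        if key in tree_cache:
            return tree_cache[key]
    clf = YoudenTreeClassifier(max_depth=max_depth).fit(X, y)
    if tree_cache is not None:
        tree_cache[key] = clf
    return clf
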
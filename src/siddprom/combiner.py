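"""Decision-tree meta-classifier over the two base classifiers' outputs.

Combines, per instance, the network's score, the window's sumG value and
both classifiers' hard labels into a four-feature vector, and grows a small
binary tree by greedy information gain.  The tree exists to test whether
the two methods are complementary: when their predictions coincide on every
instance it has nothing to add and exactly reproduces either base
classifier's F-score.

Induction is deliberately deterministic: split candidates are the midpoints
of consecutive distinct sorted feature values; ties in gain break toward
the first feature in ``FEATURE_NAMES`` order, then the smaller threshold.
Routing uses ``feature ≤ threshold → left``.  No post-pruning — growth
stops on purity, zero gain, or a child below ``min_leaf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sidd_io import NON_PROMOTER, PROMOTER

FEATURE_NAMES = ("ann_score", "sumg_value", "ann_label", "sumg_label")


def label_to_float(label: str) -> float:
    """Encode hard labels numerically (promoter → 1, non-promoter → 0)."""
    return 1.0 if label == PROMOTER else 0.0


def assemble_features(ann_scores, sumg_values, ann_labels, sumg_labels):
    """Stack per-instance base outputs into an (n, 4) feature matrix."""
    cols = [
        np.asarray(ann_scores, dtype=np.float64),
        np.asarray(sumg_values, dtype=np.float64),
        np.asarray([label_to_float(l) for l in ann_labels]),
        np.asarray([label_to_float(l) for l in sumg_labels]),
    ]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("base-output columns differ in length")
    return np.column_stack(cols)


@dataclass
class TreeNode:
    n_promoter: int
    n_non_promoter: int
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def label(self) -> str:
        # majority vote; ties resolve to non-promoter (conservative)
        return PROMOTER if self.n_promoter > self.n_non_promoter else NON_PROMOTER


@dataclass
class CombinerTree:
    root: TreeNode
    min_leaf: int

    def predict_one(self, features) -> str:
        return predict_combiner(self, features)

    def predict(self, X) -> list[str]:
        X = np.asarray(X, dtype=np.float64)
        return [predict_combiner(self, row) for row in X]

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            counts = f"[{node.n_promoter} promoter / {node.n_non_promoter} non-promoter]"
            if node.is_leaf:
                lines.append(f"{pad}leaf: {node.label} {counts}")
                return
            name = FEATURE_NAMES[node.feature]
            lines.append(f"{pad}{name} <= {node.threshold:.6g} {counts}")
            walk(node.left, indent + 1)
            walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines) + "\n"


def _entropy(n_pos: int, n_neg: int) -> float:
    n = n_pos + n_neg
    if n == 0 or n_pos == 0 or n_neg == 0:
        return 0.0
    p = n_pos / n
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def _best_split(X, y, min_leaf):
    """(feature, threshold, gain) of the best midpoint split, or None."""
    n = y.size
    n_pos = int(y.sum())
    parent = _entropy(n_pos, n - n_pos)
    best = None  # (gain, feature, threshold)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        distinct = np.flatnonzero(np.diff(xs) > 0)
        if distinct.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        for k in distinct:
            n_left = k + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            lp = int(cum_pos[k])
            rp = n_pos - lp
            child = (
                n_left * _entropy(lp, n_left - lp)
                + n_right * _entropy(rp, n_right - rp)
            ) / n
            gain = parent - child
            threshold = 0.5 * (xs[k] + xs[k + 1])
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, threshold)
    if best is None or best[0] <= 1e-12:
        return None
    return best[1], best[2], best[0]


def train_combiner(base_outputs, labels, min_leaf: int = 2) -> CombinerTree:
    """Grow the meta-classifier tree from base outputs and true labels.

    ``base_outputs`` is an (n, 4) matrix in :data:`FEATURE_NAMES` order
    (see :func:`assemble_features`).
    """
    X = np.asarray(base_outputs, dtype=np.float64)
    y = np.asarray([l == PROMOTER for l in labels])
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected an (n, {len(FEATURE_NAMES)}) feature matrix")
    if X.shape[0] != y.size:
        raise ValueError("features and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("training requires both classes")
    if min_leaf < 1:
        raise ValueError("min_leaf must be positive")

    def grow(Xn, yn) -> TreeNode:
        n_pos = int(yn.sum())
        node = TreeNode(n_promoter=n_pos, n_non_promoter=yn.size - n_pos)
        if n_pos == 0 or n_pos == yn.size:
            return node
        split = _best_split(Xn, yn, min_leaf)
        if split is None:
            return node
        feature, threshold, _gain = split
        mask = Xn[:, feature] <= threshold
        node.feature = feature
        node.threshold = threshold
        node.left = grow(Xn[mask], yn[mask])
        node.right = grow(Xn[~mask], yn[~mask])
        return node

    return CombinerTree(root=grow(X, y), min_leaf=min_leaf)


def predict_combiner(tree: CombinerTree, features) -> str:
    """Route one instance's base outputs down the tree; ≤ goes left."""
    row = np.asarray(features, dtype=np.float64).ravel()
    if row.size != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features")
    node = tree.root
    while not node.is_leaf:
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node.label
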
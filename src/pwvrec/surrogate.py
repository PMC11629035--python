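"""Interpretable surrogate decision tree distilling the recommendation policy.

A greedy binary CART classifier implemented from scratch because the
stopping rule is bespoke: a node becomes a leaf when its Gini impurity is
already <= ``gini_stop`` (default 0.20), in addition to the usual depth
cap (default 10) and the no-improving-split condition. Split candidates
are midpoints between consecutive sorted unique feature values; the chosen
split maximizes the count-weighted Gini decrease, with ties broken by
(lower feature index, lower threshold) so the fit is deterministic and
order-independent. Fidelity is the fraction of rows on which the tree
reproduces the ensemble recommendation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SurrogateTreeClassifier",
    "SurrogateTreeNode",
    "gini_impurity",
    "fit_surrogate",
    "surrogate_fidelity",
    "render_tree",
]


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum p_c^2 of a node with the given class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative class count")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty node has no impurity")
    p = counts / n
    return float(1.0 - np.sum(p * p))


@dataclass
class SurrogateTreeNode:
    """One node: split (feature, threshold) or leaf, with class bookkeeping."""

    depth: int
    class_counts: np.ndarray  # aligned with the classifier's classes_
    gini: float
    leaf_label: str
    split_feature: str | None = None
    split_feature_index: int | None = None
    threshold: float | None = None
    left: "SurrogateTreeNode | None" = None  # x[feature] <= threshold
    right: "SurrogateTreeNode | None" = None
    stop_reason: str | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    def to_dict(self) -> dict:
        d = {
            "depth": self.depth,
            "n": self.n,
            "class_counts": [int(c) for c in self.class_counts],
            "gini": self.gini,
            "label": self.leaf_label,
        }
        if self.is_leaf:
            d["stop_reason"] = self.stop_reason
        else:
            d.update(
                {
                    "split_feature": self.split_feature,
                    "threshold": self.threshold,
                    "left": self.left.to_dict(),
                    "right": self.right.to_dict(),
                }
            )
        return d


def _best_split(X: np.ndarray, y_codes: np.ndarray, n_classes: int, min_leaf: int):
    """Best (numerator, denominator, feature index, threshold) at one node.

    Maximizes sum_left c^2/n_l + sum_right c^2/n_r (the monotone equivalent
    of the weighted-Gini decrease), expressed as the exact rational
    A/(n_l*n_r) with A = suml2*n_r + sumr2*n_l, so split comparisons and
    tie-breaks (lower feature index, then lower threshold) never depend on
    floating-point rounding. Returns None when no candidate exists.
    """
    n = len(y_codes)
    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), y_codes] = 1
    total = onehot.sum(axis=0)

    best = None  # (A, D, feature_idx, threshold) maximizing A/D
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="mergesort")
        xs = xj[order]
        cum = np.cumsum(onehot[order], axis=0)  # class counts in left child
        # candidate boundaries: between distinct consecutive values
        pos = np.nonzero(xs[:-1] < xs[1:])[0]
        if min_leaf > 1:
            pos = pos[(pos + 1 >= min_leaf) & (n - pos - 1 >= min_leaf)]
        if len(pos) == 0:
            continue
        left = cum[pos]
        right = total[None, :] - left
        n_l = pos + 1
        n_r = n - n_l
        A = (left * left).sum(axis=1) * n_r + (right * right).sum(axis=1) * n_l
        D = n_l * n_r
        # float pre-scan, then exact integer comparison among near-ties
        score = A / D
        m = score.max()
        cand = np.nonzero(score >= m - 1e-9 * abs(m))[0]
        bi = int(cand[0])
        for i in cand[1:]:
            if int(A[i]) * int(D[bi]) > int(A[bi]) * int(D[i]):
                bi = int(i)
        thr = 0.5 * (xs[pos[bi]] + xs[pos[bi] + 1])
        a_j, d_j = int(A[bi]), int(D[bi])
        if best is None or a_j * best[1] > best[0] * d_j:
            best = (a_j, d_j, j, float(thr))
    return best


class SurrogateTreeClassifier(BaseEstimator, ClassifierMixin):
    """Greedy CART with an impurity-threshold leaf rule.

    Parameters
    ----------
    max_depth : depth cap (default 10).
    gini_stop : a node with Gini impurity <= this value is a leaf
        (default 0.20).
    min_leaf : minimum rows per child (default 1).
    """

    def __init__(self, max_depth: int = 10, gini_stop: float = 0.20, min_leaf: int = 1):
        self.max_depth = max_depth
        self.gini_stop = gini_stop
        self.min_leaf = min_leaf

    def fit(self, X: pd.DataFrame, y) -> "SurrogateTreeClassifier":
        X = pd.DataFrame(X)
        vals = X.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite feature value")
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if len(y) == 0:
            raise ValueError("cannot fit on an empty dataset")
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        code = {c: i for i, c in enumerate(self.classes_)}
        y_codes = np.fromiter((code[v] for v in y), dtype=int, count=len(y))
        self.tree_ = self._grow(vals, y_codes, depth=0)
        return self

    def _grow(self, X: np.ndarray, y_codes: np.ndarray, depth: int) -> SurrogateTreeNode:
        n_classes = len(self.classes_)
        counts = np.bincount(y_codes, minlength=n_classes)
        g = gini_impurity(counts)
        label = str(self.classes_[int(np.argmax(counts))])  # ties: first class
        node = SurrogateTreeNode(depth, counts, g, label)

        if g <= self.gini_stop:
            node.stop_reason = "gini_stop"
            return node
        if depth >= self.max_depth:
            node.stop_reason = "max_depth"
            return node
        best = _best_split(X, y_codes, n_classes, self.min_leaf)
        # strict gain: A/D > P/n, compared exactly in integers
        parent_num = int(np.sum(counts.astype(np.int64) ** 2))
        if best is None or best[0] * len(y_codes) <= parent_num * best[1]:
            node.stop_reason = "no_gain"
            return node

        _, _, j, thr = best
        node.split_feature_index = j
        node.split_feature = str(self.feature_names_in_[j])
        node.threshold = thr
        mask = X[:, j] <= thr
        node.left = self._grow(X[mask], y_codes[mask], depth + 1)
        node.right = self._grow(X[~mask], y_codes[~mask], depth + 1)
        node.stop_reason = None
        return node

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        vals = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        out = np.empty(len(X), dtype=object)
        for i, row in enumerate(vals):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if row[node.split_feature_index] <= node.threshold else node.right
            out[i] = node.leaf_label
        return out

    def score(self, X, y) -> float:
        """Fraction of rows where the tree reproduces the labels (fidelity)."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))

    @property
    def depth_(self) -> int:
        def d(node):
            return node.depth if node.is_leaf else max(d(node.left), d(node.right))

        check_is_fitted(self, "tree_")
        return d(self.tree_)

    # -- export -------------------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "tree_")
        return json.dumps(
            {
                "classes": [str(c) for c in self.classes_],
                "max_depth": self.max_depth,
                "gini_stop": self.gini_stop,
                "tree": self.tree_.to_dict(),
            },
            indent=2,
        )

    def render(self, levels: int = 5) -> str:
        """Indented text rendering truncated to ``levels`` levels.

        Deeper subtrees are summarized as ``(...)`` with their row count and
        majority label; a binary tree rendered to L levels shows at most
        2^L - 1 nodes.
        """
        check_is_fitted(self, "tree_")
        if levels < 1:
            raise ValueError("levels must be >= 1")
        lines: list[str] = []

        def walk(node: SurrogateTreeNode, prefix: str, level: int) -> None:
            counts = ",".join(str(int(c)) for c in node.class_counts)
            head = f"{prefix}n={node.n} gini={node.gini:.3f} [{counts}] -> {node.leaf_label}"
            if node.is_leaf:
                lines.append(head + f" (leaf: {node.stop_reason})")
                return
            if level >= levels:
                lines.append(head + " (...)")
                return
            lines.append(head + f" | split {node.split_feature} <= {node.threshold:.4g}")
            walk(node.left, prefix + "  ", level + 1)
            walk(node.right, prefix + "  ", level + 1)

        walk(self.tree_, "", 1)
        return "\n".join(lines)

    def to_dot(self, levels: int | None = None) -> str:
        """Graph description (DOT) of the tree, optionally truncated."""
        check_is_fitted(self, "tree_")
        lines = ["digraph surrogate {", '  node [shape=box, fontname="Helvetica"];']
        counter = [0]

        def walk(node: SurrogateTreeNode, level: int) -> int:
            my_id = counter[0]
            counter[0] += 1
            counts = ",".join(str(int(c)) for c in node.class_counts)
            if node.is_leaf or (levels is not None and level >= levels):
                label = f"{node.leaf_label}\\nn={node.n}\\ngini={node.gini:.3f}"
                if not node.is_leaf:
                    label += "\\n(truncated)"
                lines.append(f'  n{my_id} [label="{label}"];')
                return my_id
            label = (
                f"{node.split_feature} <= {node.threshold:.4g}\\n"
                f"gini={node.gini:.3f}\\nn={node.n}\\n[{counts}]"
            )
            lines.append(f'  n{my_id} [label="{label}"];')
            lid = walk(node.left, level + 1)
            rid = walk(node.right, level + 1)
            lines.append(f"  n{my_id} -> n{lid} [label=yes];")
            lines.append(f"  n{my_id} -> n{rid} [label=no];")
            return my_id

        walk(self.tree_, 1)
        lines.append("}")
        return "\n".join(lines)


def fit_surrogate(
    X: pd.DataFrame,
    labels,
    max_depth: int = 10,
    gini_stop: float = 0.20,
    min_leaf: int = 1,
) -> SurrogateTreeClassifier:
    """Fit the surrogate tree on recommendation labels."""
    return SurrogateTreeClassifier(max_depth, gini_stop, min_leaf).fit(X, labels)


def surrogate_fidelity(tree: SurrogateTreeClassifier, X: pd.DataFrame, labels) -> float:
    """Agreement fraction between tree predictions and the given labels."""
    return tree.score(X, labels)


def render_tree(tree: SurrogateTreeClassifier, levels: int = 5) -> str:
    """Thin wrapper over :meth:`SurrogateTreeClassifier.render`."""
    return tree.render(levels)
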
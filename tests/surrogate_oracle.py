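"""Brute-force CART oracle shared by the surrogate tests.

Independent, unvectorized exhaustive search over every (feature, midpoint
threshold) candidate with exact rational scores, used to verify the
package's tree builder node-for-node.
"""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pwvrec.surrogate import SurrogateTreeClassifier


def oracle_gini(labels):
    n = len(labels)
    return 1.0 - sum((list(labels).count(c) / n) ** 2 for c in set(labels))


def oracle_best_split(X, y, min_leaf):
    """Exhaustive scan; exact rational scores; ties keep the first
    (lowest feature index, lowest threshold) candidate."""
    n = len(y)
    best = None  # (score, j, thr)
    for j in range(X.shape[1]):
        vals = sorted(set(X[:, j]))
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            left = [y[i] for i in range(n) if X[i, j] <= thr]
            right = [y[i] for i in range(n) if X[i, j] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            score = sum(
                Fraction(list(side).count(c) ** 2, len(side))
                for side in (left, right)
                for c in set(side)
            )
            if best is None or score > best[0]:
                best = (score, j, thr)
    return best


def oracle_tree(X, y, depth, max_depth, gini_stop, min_leaf, classes):
    counts = [list(y).count(c) for c in classes]
    node = {
        "counts": counts,
        "label": classes[int(np.argmax(counts))],
        "gini": oracle_gini(y),
    }
    if node["gini"] <= gini_stop or depth >= max_depth:
        return node
    best = oracle_best_split(X, y, min_leaf)
    parent_score = Fraction(sum(c * c for c in counts), len(y))
    if best is None or best[0] <= parent_score:
        return node
    _, j, thr = best
    mask = X[:, j] <= thr
    node["feature"] = j
    node["threshold"] = thr
    node["left"] = oracle_tree(
        X[mask], [y[i] for i in range(len(y)) if mask[i]],
        depth + 1, max_depth, gini_stop, min_leaf, classes,
    )
    node["right"] = oracle_tree(
        X[~mask], [y[i] for i in range(len(y)) if not mask[i]],
        depth + 1, max_depth, gini_stop, min_leaf, classes,
    )
    return node


def assert_same_tree(node, oracle):
    assert list(node.class_counts) == oracle["counts"]
    assert node.gini == pytest.approx(oracle["gini"], abs=1e-12)
    assert node.leaf_label == oracle["label"]
    if "feature" in oracle:
        assert not node.is_leaf
        assert node.split_feature_index == oracle["feature"]
        assert node.threshold == pytest.approx(oracle["threshold"], abs=1e-12)
        assert_same_tree(node.left, oracle["left"])
        assert_same_tree(node.right, oracle["right"])
    else:
        assert node.is_leaf


def check_oracle_equivalence(n_datasets=10, seed=0, max_depth=10, gini_stop=0.20):
    """Random small fixtures (n<=30, p<=3): tree must match the oracle."""
    rng = np.random.default_rng(seed)
    for _ in range(n_datasets):
        n = int(rng.integers(8, 31))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p)).round(2)  # rounding induces value ties
        classes = ["ACEI", "ARB", "BB", "DIU"][: int(rng.integers(2, 5))]
        y = [classes[i] for i in rng.integers(0, len(classes), n)]
        tree = SurrogateTreeClassifier(max_depth=max_depth, gini_stop=gini_stop).fit(
            pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y
        )
        expected = oracle_tree(X, y, 0, max_depth, gini_stop, 1, sorted(set(y)))
        assert_same_tree(tree.tree_, expected)
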
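"""Surrogate CART: Gini arithmetic, stopping rules, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from surrogate_oracle import assert_same_tree, oracle_tree

from pwvrec.surrogate import (
    SurrogateTreeClassifier,
    fit_surrogate,
    gini_impurity,
    render_tree,
    surrogate_fidelity,
)


class TestGini:
    def test_pure_node(self):
        assert gini_impurity([10, 0, 0, 0, 0, 0]) == 0.0

    def test_two_balanced_classes(self):
        assert gini_impurity([5, 5]) == 0.5

    def test_six_balanced_classes(self):
        assert gini_impurity([1, 1, 1, 1, 1, 1]) == pytest.approx(0.8333, abs=5e-5)

    def test_errors(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0])
        with pytest.raises(ValueError):
            gini_impurity([-1, 2])


class TestStoppingRules:
    def test_single_class_single_leaf(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        tree = fit_surrogate(X, ["ACEI"] * 10)
        assert tree.tree_.is_leaf and tree.tree_.depth == 0
        assert tree.tree_.stop_reason == "gini_stop"

    def test_low_gini_node_not_split(self):
        # 1 of 10 minority: gini = 0.18 <= 0.20 -> leaf even though separable
        X = pd.DataFrame({"a": np.arange(10.0)})
        y = ["ARB"] * 9 + ["BB"]
        tree = fit_surrogate(X, y)
        assert tree.tree_.is_leaf
        assert tree.tree_.gini == pytest.approx(0.18)

    def test_max_depth_respected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        y = np.where(rng.random(200) < 0.5, "ACEI", "ARB")
        tree = fit_surrogate(X, y, max_depth=3, gini_stop=0.0)
        assert tree.depth_ <= 3

    def test_every_leaf_satisfies_a_stopping_condition(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        y = np.asarray(["ACEI", "ARB", "BB", "DIU"])[rng.integers(0, 4, 150)]
        tree = fit_surrogate(X, y, max_depth=6, gini_stop=0.2)

        def walk(node):
            if node.is_leaf:
                assert (
                    node.gini <= 0.2
                    or node.depth == 6
                    or node.stop_reason == "no_gain"
                )
            else:
                assert (node.left.class_counts + node.right.class_counts
                        == node.class_counts).all()
                walk(node.left)
                walk(node.right)

        walk(tree.tree_)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_cart(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p)).round(2)  # ties likely after rounding
        classes = ["ACEI", "ARB", "BB", "DIU"][: int(rng.integers(2, 5))]
        y = [classes[i] for i in rng.integers(0, len(classes), n)]
        tree = SurrogateTreeClassifier(max_depth=10, gini_stop=0.20).fit(
            pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y
        )
        oracle = oracle_tree(X, y, 0, 10, 0.20, 1, sorted(set(y)))
        assert_same_tree(tree.tree_, oracle)

    def test_hand_built_separable_dataset(self):
        X = pd.DataFrame({"a": [0, 1, 2, 3, 10, 11, 12, 13.0]})
        y = ["ACEI"] * 4 + ["ARB"] * 4
        tree = fit_surrogate(X, y)
        assert tree.tree_.threshold == pytest.approx(6.5)
        assert (tree.predict(X) == np.asarray(y, dtype=object)).all()


class TestFidelityAndRendering:
    def test_training_fidelity_one_on_pure_leaves(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = np.where(X["a"] > 0, "ACEI", "ARB")
        tree = fit_surrogate(X, y, gini_stop=0.0)
        assert surrogate_fidelity(tree, X, y) == 1.0

    def test_deeper_tree_at_least_as_faithful(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        y = np.where(
            X["a"] + 0.5 * X["b"] - 0.2 * X["c"] ** 2 > 0, "ACEI",
            np.where(X["b"] > 1, "ARB", "DIU"),
        )
        f3 = surrogate_fidelity(fit_surrogate(X, y, max_depth=3, gini_stop=0.0), X, y)
        f10 = surrogate_fidelity(fit_surrogate(X, y, max_depth=10, gini_stop=0.0), X, y)
        assert f10 >= f3

    def test_permuted_labels_fidelity_near_majority_share(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        y = np.asarray(["ACEI"] * 240 + ["ARB"] * 160, dtype=object)
        y_perm = rng.permutation(y)
        tree = fit_surrogate(X, y_perm, max_depth=2, gini_stop=0.2)
        fid = surrogate_fidelity(tree, X, y_perm)
        assert fid == pytest.approx(0.6, abs=0.1)

    def test_render_single_leaf_and_level_bound(self, rng):
        tree = fit_surrogate(pd.DataFrame({"a": [1.0, 2.0]}), ["ACEI", "ACEI"])
        assert len(render_tree(tree).splitlines()) == 1

        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = np.asarray(["ACEI", "ARB", "BB", "DIU"])[rng.integers(0, 4, 200)]
        deep = fit_surrogate(X, y, max_depth=8, gini_stop=0.0)
        for levels in (1, 2, 3, 5):
            assert len(deep.render(levels).splitlines()) <= 2**levels - 1
        full = deep.render(levels=deep.depth_ + 1)
        assert "(...)" not in full

    def test_dot_export_contains_splits(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["hba1c", "cfpwv"])
        y = np.where(X["hba1c"] > 0, "ACEI", "ARB")
        tree = fit_surrogate(X, y, gini_stop=0.0)
        dot = tree.to_dot()
        assert dot.startswith("digraph") and "hba1c" in dot

    def test_non_finite_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError):
            fit_surrogate(X, ["ACEI", "ARB"])

    def test_missing_column_at_predict(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        tree = fit_surrogate(X, ["ACEI"] * 10 + ["ARB"] * 10)
        with pytest.raises(KeyError):
            tree.predict(pd.DataFrame({"a": [0.0]}))
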
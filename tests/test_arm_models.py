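"""Per-arm forests, importance measures, feature selection, counterfactuals."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from pwvrec.arm_models import (
    ArmImportanceRegressor,
    ImportanceTable,
    fit_arm_model,
    mdi_importance,
    permutation_importance,
    predict_all_arms,
    refit_reduced,
    select_top_features,
)
from pwvrec.preprocess import ArmDataset


def _linear_dataset(rng, n=400, p=6, informative=2, noise=0.1):
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)]
    )
    coefs = np.zeros(p)
    coefs[:informative] = [1.0, 0.5][:informative]
    y = pd.Series(X.to_numpy() @ coefs + noise * rng.normal(size=n), name="y")
    return X, y, coefs


class TestArmForest:
    def test_constant_target_constant_predictor(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]})
        y = [2.5, 2.5, 2.5]
        with pytest.warns(UserWarning):
            est = ArmImportanceRegressor(n_estimators=10).fit(X, y)
        assert (est.predict(pd.DataFrame({"a": [9.0], "b": [9.0]})) == 2.5).all()

    def test_recovers_linear_signal_in_sample(self, rng):
        X, y, _ = _linear_dataset(rng, n=800, noise=0.0)
        ds = ArmDataset("ACEI", X, y)
        forest = fit_arm_model(ds, {"n_estimators": 150}, seed=0)
        from pwvrec.validation import r_squared

        assert r_squared(y, forest.predict(X)) >= 0.9

    def test_seeded_determinism(self, rng):
        X, y, _ = _linear_dataset(rng)
        a = ArmImportanceRegressor(n_estimators=30, n_repeats=2, random_state=5).fit(X, y)
        b = ArmImportanceRegressor(n_estimators=30, n_repeats=2, random_state=5).fit(X, y)
        assert a.selected_features_ == b.selected_features_
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestImportances:
    def test_single_feature_score_is_one(self, rng):
        X = pd.DataFrame({"only": rng.normal(size=100)})
        y = X["only"] * 2.0
        forest = RandomForestRegressor(n_estimators=20, random_state=0).fit(X, y)
        assert mdi_importance(forest, X.columns)["only"] == pytest.approx(1.0)

    def test_mdi_normalized_and_strong_feature_first(self, rng):
        X, y, _ = _linear_dataset(rng, n=600, informative=1, noise=0.05)
        forest = RandomForestRegressor(n_estimators=100, random_state=0).fit(X, y)
        scores = mdi_importance(forest, X.columns)
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert scores.idxmax() == "x0"

    def test_permutation_unused_feature_exactly_zero(self, rng):
        X = pd.DataFrame({"used": rng.normal(size=200), "unused": 1.0})
        y = 3.0 * X["used"]
        forest = RandomForestRegressor(n_estimators=30, random_state=0).fit(X, y)
        scores = permutation_importance(forest, X, y, n_repeats=3, seed=0)
        assert scores["unused"] == 0.0
        assert scores["used"] > 0.0

    def test_permutation_seeded(self, rng):
        X, y, _ = _linear_dataset(rng)
        forest = RandomForestRegressor(n_estimators=30, random_state=0).fit(X, y)
        a = permutation_importance(forest, X, y, n_repeats=3, seed=11)
        b = permutation_importance(forest, X, y, n_repeats=3, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_length_mismatch_rejected(self, rng):
        X, y, _ = _linear_dataset(rng, n=50)
        forest = RandomForestRegressor(n_estimators=5, random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            permutation_importance(forest, X, y[:-1])


class TestSelection:
    def test_matches_brute_force_ranking(self, rng):
        names = [f"f{i}" for i in range(12)]
        mdi = pd.Series(rng.random(12), index=names)
        mdi /= mdi.sum()
        perm = pd.Series(rng.random(12), index=names)
        table = ImportanceTable.from_scores(mdi, perm)

        # independent oracle: exhaustive sort on (mean rank, mdi rank, name)
        mdi_rank = {n: r + 1 for r, n in enumerate(sorted(names, key=lambda n: (-mdi[n], n)))}
        perm_rank = {n: r + 1 for r, n in enumerate(sorted(names, key=lambda n: (-perm[n], n)))}
        oracle = sorted(
            names, key=lambda n: ((mdi_rank[n] + perm_rank[n]) / 2, mdi_rank[n], n)
        )
        assert select_top_features(table, 5) == oracle[:5]

    def test_all_features_returned_when_k_equals_p(self, rng):
        names = [f"f{i}" for i in range(10)]
        s = pd.Series(rng.random(10), index=names)
        table = ImportanceTable.from_scores(s / s.sum(), s)
        assert sorted(select_top_features(table, 10)) == sorted(names)

    def test_ranks_are_permutation(self, rng):
        names = [f"f{i}" for i in range(8)]
        s = pd.Series(rng.random(8), index=names)
        table = ImportanceTable.from_scores(s / s.sum(), s).table
        for col in ("mdi_rank", "perm_rank"):
            assert sorted(table[col]) == list(range(1, 9))


class TestReducedRefit:
    def test_reduced_close_to_full(self, rng):
        X, y, _ = _linear_dataset(rng, n=600, p=8, noise=0.05)
        Xh, yh, _ = _linear_dataset(rng, n=300, p=8, noise=0.05)
        ds = ArmDataset("ARB", X, y)
        from pwvrec.validation import r_squared

        full = fit_arm_model(ds, {"n_estimators": 100}, seed=1)
        bundle = refit_reduced(ds, ["x0", "x1"], {"n_estimators": 100}, seed=1)
        r2_full = r_squared(yh, full.predict(Xh))
        r2_red = r_squared(yh, bundle.predict(Xh))
        assert r2_red >= r2_full - 0.1

    def test_contract_errors(self, rng):
        X, y, _ = _linear_dataset(rng, n=60)
        ds = ArmDataset("BB", X, y)
        with pytest.raises(ValueError):
            refit_reduced(ds, [], seed=0)
        with pytest.raises(KeyError):
            refit_reduced(ds, ["nope"], seed=0)
        bundle = refit_reduced(ds, ["x0"], {"n_estimators": 5}, seed=0)
        with pytest.raises(KeyError, match="BB"):
            bundle.predict(pd.DataFrame({"x9": [1.0]}))


class TestCounterfactualMatrix:
    def test_shape_and_canonical_order(self, rng):
        X, y, _ = _linear_dataset(rng, n=80)
        bundles = {}
        for d in ("ARB", "ACEI", "DIU"):
            ds = ArmDataset(d, X, y)
            bundles[d] = refit_reduced(ds, ["x0", "x1"], {"n_estimators": 5}, seed=0)
        preds = predict_all_arms(bundles, X)
        assert list(preds.columns) == ["ACEI", "ARB", "DIU"]
        assert preds.shape == (80, 3)
        assert np.isfinite(preds.to_numpy()).all()

    def test_constant_models_give_constant_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        y = pd.Series([1.0, 1.0, 1.0, 1.0])
        ds = ArmDataset("ACEI", X, y)
        bundle = refit_reduced(ds, ["a"], {"n_estimators": 5}, seed=0)
        preds = predict_all_arms({"ACEI": bundle}, X)
        assert (preds["ACEI"] == 1.0).all()
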
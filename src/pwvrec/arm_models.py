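"""Per-arm random-forest outcome models with importance-based reduction.

Each drug arm gets its own regression forest predicting standardized PWV
change from the candidate covariates (a T-learner: counterfactual
prediction for a patient means querying every arm's model). After a full
fit, two importance measures are computed -- mean decrease in impurity and
permutation importance -- combined into a consensus rank, and the model is
refit on the top-k (default 10) features only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.utils.validation import check_is_fitted

from .preprocess import ArmDataset
from .schema import DRUG_CLASSES

__all__ = [
    "ArmImportanceRegressor",
    "PerArmRecommender",
    "ImportanceTable",
    "fit_arm_model",
    "mdi_importance",
    "permutation_importance",
    "select_top_features",
    "refit_reduced",
    "predict_all_arms",
]


def mdi_importance(forest: RandomForestRegressor, feature_names) -> pd.Series:
    """Mean-decrease-in-impurity scores, normalized to sum to 1.

    The score is the variance reduction attributed to splits on each
    feature, averaged over trees.
    """
    check_is_fitted(forest)
    scores = np.asarray(forest.feature_importances_, dtype=float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    return pd.Series(scores, index=list(feature_names), name="mdi_score")


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    n_repeats: int = 10,
    seed: int | None = None,
    max_samples: float | int = 1.0,
) -> pd.Series:
    """Mean increase in squared error when a feature is shuffled.

    A feature no tree ever splits on scores exactly 0. ``max_samples``
    subsamples rows to bound the cost on large arms.
    """
    if len(X) != len(np.asarray(y)):
        raise ValueError("X and y length mismatch")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if isinstance(max_samples, (int, np.integer)) and max_samples > len(X):
        max_samples = len(X)
    res = _sk_permutation_importance(
        model,
        X,
        y,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
        max_samples=max_samples,
    )
    return pd.Series(res.importances_mean, index=list(X.columns), name="perm_score")


@dataclass
class ImportanceTable:
    """Both importance measures plus their ranks and consensus rank."""

    table: pd.DataFrame  # columns: mdi_score, perm_score, *_rank, consensus_rank

    @classmethod
    def from_scores(cls, mdi: pd.Series, perm: pd.Series) -> "ImportanceTable":
        if list(mdi.index) != list(perm.index):
            raise ValueError("importance score indices differ")
        df = pd.DataFrame({"mdi_score": mdi, "perm_score": perm})
        df["mdi_rank"] = _ordinal_rank(df["mdi_score"])
        df["perm_rank"] = _ordinal_rank(df["perm_score"])
        df["consensus_rank"] = 0.5 * (df["mdi_rank"] + df["perm_rank"])
        return cls(df)

    def top(self, k: int = 10) -> list[str]:
        """The k best-consensus features (ties: lower MDI rank, then name)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        t = self.table
        order = sorted(
            t.index, key=lambda n: (t.at[n, "consensus_rank"], t.at[n, "mdi_rank"], n)
        )
        return order[: min(k, len(order))]


def _ordinal_rank(scores: pd.Series) -> pd.Series:
    """Rank 1..p, best (largest) score first; ties broken by name."""
    order = sorted(scores.index, key=lambda n: (-scores[n], n))
    return pd.Series({n: i + 1 for i, n in enumerate(order)}, name=scores.name)


def select_top_features(importances: ImportanceTable, k: int = 10) -> list[str]:
    """Thin wrapper over :meth:`ImportanceTable.top`."""
    return importances.top(k)


class ArmImportanceRegressor(BaseEstimator, RegressorMixin):
    """Random forest with embedded top-k feature selection for one arm.

    ``fit`` trains a full forest on all columns of ``X``, ranks features by
    the consensus of MDI and permutation importance (configurable to either
    alone), then refits on the selected top ``k_features`` columns.
    ``predict`` uses the reduced model and requires the selected columns to
    be present.

    Parameters
    ----------
    n_estimators : trees in the full (importance) forest (default 300).
    k_features : number of features kept after reduction (default 10).
    importance : "consensus" | "mdi" | "permutation".
    n_repeats : permutation repetitions (default 10).
    perm_max_samples : row fraction/count for permutation scoring.
    max_features : feature subsampling of the full forest (regression
        convention 1/3).
    n_estimators_reduced / max_features_reduced : overrides for the
        reduced refit (None -> same as the full forest).
    random_state : seed for both forests and the permutation shuffles.
    """

    def __init__(
        self,
        n_estimators: int = 300,
        k_features: int = 10,
        importance: str = "consensus",
        n_repeats: int = 10,
        perm_max_samples: float | int = 1.0,
        max_features: float = 1.0 / 3.0,
        n_estimators_reduced: int | None = None,
        max_features_reduced: float | None = None,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.k_features = k_features
        self.importance = importance
        self.n_repeats = n_repeats
        self.perm_max_samples = perm_max_samples
        self.max_features = max_features
        self.n_estimators_reduced = n_estimators_reduced
        self.max_features_reduced = max_features_reduced
        self.random_state = random_state

    def _make_forest(self, seed_offset: int, reduced: bool = False) -> RandomForestRegressor:
        rs = None if self.random_state is None else self.random_state + seed_offset
        n_est = self.n_estimators
        mf = self.max_features
        if reduced:
            n_est = self.n_estimators_reduced or n_est
            mf = self.max_features_reduced if self.max_features_reduced is not None else mf
        return RandomForestRegressor(
            n_estimators=n_est,
            max_features=mf,
            bootstrap=True,
            random_state=rs,
            n_jobs=1,
        )

    def fit(self, X: pd.DataFrame, y) -> "ArmImportanceRegressor":
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.importance not in ("consensus", "mdi", "permutation"):
            raise ValueError(f"unknown importance mode {self.importance!r}")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        if np.ptp(y) == 0.0:
            warnings.warn(
                "degenerate (constant) target; fitting a constant predictor",
                UserWarning,
            )
            self.constant_ = float(y[0]) if len(y) else 0.0
            self.selected_features_ = list(X.columns[: self.k_features])
            self.importances_ = None
            self.model_ = None
            return self

        self.constant_ = None
        full = self._make_forest(0).fit(X, y)
        mdi = mdi_importance(full, X.columns)
        perm_seed = None if self.random_state is None else self.random_state + 1
        perm = permutation_importance(
            full,
            X,
            y,
            n_repeats=self.n_repeats,
            seed=perm_seed,
            max_samples=self.perm_max_samples,
        )
        self.importances_ = ImportanceTable.from_scores(mdi, perm)
        if self.importance == "mdi":
            ranked = sorted(X.columns, key=lambda n: (-mdi[n], n))
            self.selected_features_ = ranked[: min(self.k_features, len(ranked))]
        elif self.importance == "permutation":
            ranked = sorted(X.columns, key=lambda n: (-perm[n], n))
            self.selected_features_ = ranked[: min(self.k_features, len(ranked))]
        else:
            self.selected_features_ = self.importances_.top(self.k_features)

        self.model_ = self._make_forest(2, reduced=True).fit(
            X[self.selected_features_], y
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "selected_features_")
        X = pd.DataFrame(X)
        if self.constant_ is not None:
            return np.full(len(X), self.constant_)
        missing = [c for c in self.selected_features_ if c not in X.columns]
        if missing:
            raise KeyError(f"missing selected feature column(s): {missing}")
        return self.model_.predict(X[self.selected_features_])


class PerArmRecommender(BaseEstimator):
    """T-learner over the six drug arms plus the argmax recommendation rule.

    ``fit`` accepts either a mapping drug -> :class:`ArmDataset` or
    ``(X, y, arms)`` with a treatment label per row, and trains one
    :class:`ArmImportanceRegressor` per arm on that arm's patients only.
    Counterfactual prediction queries every arm's model on the same rows.
    """

    def __init__(
        self,
        n_estimators: int = 300,
        k_features: int = 10,
        importance: str = "consensus",
        n_repeats: int = 10,
        perm_max_samples: float | int = 1.0,
        max_features: float = 1.0 / 3.0,
        n_estimators_reduced: int | None = None,
        max_features_reduced: float | None = None,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.k_features = k_features
        self.importance = importance
        self.n_repeats = n_repeats
        self.perm_max_samples = perm_max_samples
        self.max_features = max_features
        self.n_estimators_reduced = n_estimators_reduced
        self.max_features_reduced = max_features_reduced
        self.random_state = random_state

    def _arm_seed(self, i: int) -> int | None:
        if self.random_state is None:
            return None
        # spread arm seeds so per-arm forests are independent but reproducible
        return int((self.random_state + 1000003 * (i + 1)) % (2**31 - 1))

    def fit(self, data, y=None, arms=None) -> "PerArmRecommender":
        if isinstance(data, dict):
            datasets = data
        else:
            X = pd.DataFrame(data)
            if y is None or arms is None:
                raise ValueError("fit(X, y, arms) requires y and arms")
            y = pd.Series(np.asarray(y, dtype=float), index=X.index)
            arms = pd.Series(np.asarray(arms, dtype=object), index=X.index)
            datasets = {}
            for d in DRUG_CLASSES:
                mask = arms == d
                if mask.any():
                    datasets[d] = ArmDataset(
                        d,
                        X[mask].reset_index(drop=True),
                        y[mask].reset_index(drop=True),
                    )
        unknown = sorted(set(datasets) - set(DRUG_CLASSES))
        if unknown:
            raise ValueError(f"unknown drug class(es): {unknown}")
        self.models_ = {}
        for i, d in enumerate(DRUG_CLASSES):
            if d not in datasets:
                continue
            ds = datasets[d]
            est = ArmImportanceRegressor(
                n_estimators=self.n_estimators,
                k_features=self.k_features,
                importance=self.importance,
                n_repeats=self.n_repeats,
                perm_max_samples=self.perm_max_samples,
                max_features=self.max_features,
                n_estimators_reduced=self.n_estimators_reduced,
                max_features_reduced=self.max_features_reduced,
                random_state=self._arm_seed(i),
            )
            self.models_[d] = est.fit(ds.X, ds.y)
        self.arms_ = list(self.models_)
        return self

    def predict_all(self, X: pd.DataFrame) -> pd.DataFrame:
        """n x n_arms matrix of predicted standardized PWV change."""
        check_is_fitted(self, "models_")
        X = pd.DataFrame(X)
        out = pd.DataFrame(index=X.index)
        for d in DRUG_CLASSES:
            if d not in self.models_:
                continue
            try:
                out[d] = self.models_[d].predict(X)
            except KeyError as err:
                raise KeyError(f"arm {d}: {err}") from err
        if not np.all(np.isfinite(out.to_numpy())):
            raise ValueError("non-finite counterfactual prediction")
        return out

    def recommend(self, X: pd.DataFrame) -> pd.Series:
        """Arm with the largest predicted reduction per row."""
        preds = self.predict_all(X)
        cols = np.asarray(preds.columns, dtype=object)
        return pd.Series(
            cols[np.argmax(preds.to_numpy(), axis=1)],
            index=preds.index,
            name="recommended_drug",
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted reduction under the recommended arm (row maximum)."""
        return self.predict_all(X).to_numpy().max(axis=1)

    @property
    def selected_features_(self) -> dict[str, list[str]]:
        check_is_fitted(self, "models_")
        return {d: m.selected_features_ for d, m in self.models_.items()}


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimator surface
# ---------------------------------------------------------------------------


def fit_arm_model(
    data: ArmDataset, hyperparams: dict | None = None, seed: int | None = None
) -> RandomForestRegressor:
    """Fit a plain (full-feature) forest for one arm."""
    hp = {"n_estimators": 300, "max_features": 1.0 / 3.0}
    hp.update(hyperparams or {})
    if hp["n_estimators"] < 1:
        raise ValueError("n_trees must be >= 1")
    forest = RandomForestRegressor(
        n_estimators=hp["n_estimators"],
        max_features=hp["max_features"],
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    return forest.fit(data.X, data.y)


def refit_reduced(
    data: ArmDataset,
    features: list[str],
    hyperparams: dict | None = None,
    seed: int | None = None,
) -> "ArmModelBundle":
    """Refit on a reduced feature list and wrap into a bundle."""
    if not features:
        raise ValueError("empty feature list")
    missing = [f for f in features if f not in data.X.columns]
    if missing:
        raise KeyError(f"feature(s) not in arm dataset: {missing}")
    reduced = ArmDataset(data.drug_class, data.X[features], data.y, data.patient_ids)
    model = fit_arm_model(reduced, hyperparams, seed)
    return ArmModelBundle(data.drug_class, model, list(features), len(data.y), seed)


@dataclass
class ArmModelBundle:
    """Fitted reduced ensemble for one arm plus its metadata."""

    drug_class: str
    model: RandomForestRegressor
    selected_features: list[str]
    n_train: int
    seed: int | None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.selected_features if c not in X.columns]
        if missing:
            raise KeyError(
                f"bundle {self.drug_class}: missing column(s) {missing}"
            )
        return self.model.predict(X[self.selected_features])


def predict_all_arms(bundles: dict[str, "ArmModelBundle"], X: pd.DataFrame) -> pd.DataFrame:
    """Counterfactual predictions for every bundle, canonical column order."""
    out = pd.DataFrame(index=pd.DataFrame(X).index)
    for d in DRUG_CLASSES:
        if d in bundles:
            out[d] = bundles[d].predict(pd.DataFrame(X))
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("non-finite counterfactual prediction")
    return out
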
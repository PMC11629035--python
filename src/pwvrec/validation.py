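"""Internal (stratified holdout) and external (cohort-transfer) validation.

Internal validation pools the three source cohorts and holds out 20% of
patients, stratified by drug class so every arm contributes test rows.
External validation reserves the EVIDENT-analogue cohort entirely for
testing and trains on the other two cohorts, optionally SMOTE-augmented to
an ~80/20 train/test balance; synthetic training points never descend from
test-cohort rows. Per-arm performance is reported as R^2 and MSE on the
standardized PWV-change scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score

from .augment import plan_external_counts, smote_augment
from .preprocess import ArmDataset, build_arm_datasets
from .schema import COHORT_COL, COHORTS, DRUG_CLASSES, DRUG_COL

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "holdout_split",
    "external_scheme",
    "r_squared",
    "mse",
    "evaluate_bundles",
]


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (test-set mean)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0.0:
        raise ValueError("r_squared undefined for constant y")
    return float(r2_score(y, yhat))


def mse(y, yhat) -> float:
    """Mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    return float(mean_squared_error(y, yhat))


def holdout_split(
    cohort: pd.DataFrame, train_frac: float = 0.8, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug-class-stratified random holdout split.

    The overall training size is round(train_frac * n); per-arm counts are
    apportioned by largest remainder so each arm appears in both folds
    whenever it has at least two patients. A single-patient arm goes to
    training with a warning.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_train_total = int(round(train_frac * n))

    groups = {
        d: cohort.index[cohort[DRUG_COL] == d].to_numpy()
        for d in cohort[DRUG_COL].unique()
    }
    order = sorted(groups)  # deterministic arm order

    # largest-remainder apportionment of the training quota
    quotas = {d: train_frac * len(groups[d]) for d in order}
    base = {d: int(np.floor(quotas[d])) for d in order}
    remaining = n_train_total - sum(base.values())
    by_rem = sorted(order, key=lambda d: (-(quotas[d] - base[d]), d))
    for d in by_rem[: max(remaining, 0)]:
        base[d] += 1

    train_idx, test_idx = [], []
    for d in order:
        idx = groups[d].copy()
        rng.shuffle(idx)
        k = base[d]
        if len(idx) == 1:
            logger.warning("holdout_split: arm %s has one patient; -> training", d)
            k = 1
        elif len(idx) >= 2:
            k = min(max(k, 1), len(idx) - 1)  # both folds nonempty
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])

    train = cohort.loc[sorted(train_idx)]
    test = cohort.loc[sorted(test_idx)]
    return train, test


def external_scheme(
    cohort: pd.DataFrame,
    augment: bool = True,
    k_neighbors: int = 5,
    seed: int | None = None,
    mode: str = "mean",
):
    """Cohort-transfer split: EVIDENT rows test, EVA+LOD (augmented) train.

    Returns (train_datasets, test_datasets, params, provenance). Test rows
    are untouched by augmentation and are transformed with the training
    medians and standardization parameters.
    """
    present = set(cohort[COHORT_COL].unique())
    missing = [c for c in COHORTS if c not in present]
    if missing:
        raise ValueError(f"cohort label(s) missing: {missing}")

    test_rows = cohort[cohort[COHORT_COL] == "EVIDENT"]
    train_rows = cohort[cohort[COHORT_COL] != "EVIDENT"]

    train_ds, params = build_arm_datasets(train_rows, mode=mode)
    test_ds, _ = build_arm_datasets(
        test_rows,
        standardizer=params["standardizer"],
        medians=params["medians"],
        mode=mode,
    )

    provenance = []
    if augment:
        counts = plan_external_counts(
            {d: ds.n for d, ds in train_ds.items()}, test_n=len(test_rows)
        )
        train_ds, provenance = smote_augment(
            train_ds, counts, k_neighbors=k_neighbors, seed=seed
        )
    return train_ds, test_ds, params, provenance


@dataclass
class ValidationReport:
    """Per-arm R^2/MSE for one validation scheme."""

    scheme: str  # "internal" | "external"
    metrics: pd.DataFrame  # index drug, columns r2, mse, n_test
    seed: int | None = None
    config: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "config": self.config,
            "notes": self.notes,
            "metrics": {
                d: {
                    "r2": None if pd.isna(r.r2) else float(r.r2),
                    "mse": None if pd.isna(r.mse) else float(r.mse),
                    "n_test": int(r.n_test),
                }
                for d, r in self.metrics.iterrows()
            },
        }

    def to_frame(self) -> pd.DataFrame:
        return self.metrics.copy()


def evaluate_bundles(
    bundles: dict,
    test_datasets: dict[str, ArmDataset],
    scheme: str = "internal",
    seed: int | None = None,
    config: dict | None = None,
) -> ValidationReport:
    """Score each arm's model on its own held-out patients.

    ``bundles`` maps drug -> an object with ``predict(X)``. Arms whose test
    set is empty or has a constant/short target get NaN R^2 with a reason.
    """
    rows, notes = {}, {}
    for d in DRUG_CLASSES:
        if d not in bundles:
            continue
        ds = test_datasets.get(d)
        if ds is None or ds.n == 0:
            rows[d] = {"r2": np.nan, "mse": np.nan, "n_test": 0}
            notes[d] = "empty test arm"
            continue
        yhat = bundles[d].predict(ds.X)
        m = mse(ds.y, yhat)
        if ds.n < 2 or np.ptp(ds.y.to_numpy()) == 0.0:
            rows[d] = {"r2": np.nan, "mse": m, "n_test": ds.n}
            notes[d] = "R2 undefined (constant or single-row target)"
        else:
            rows[d] = {"r2": r_squared(ds.y, yhat), "mse": m, "n_test": ds.n}
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    return ValidationReport(scheme, metrics, seed=seed, config=config or {}, notes=notes)
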
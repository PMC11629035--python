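"""SMOTE-style oversampling of the per-arm training datasets.

Classic SMOTE is a classification device; here the drug arm plays the role
of the class label and the interpolation acts on the *joint* (features,
target) vector, so a synthetic patient inherits a target consistent with
its position on the segment between its two parents:

    new = parent + u * (neighbor - parent),   u ~ Uniform[0, 1],

with the neighbor drawn among the k nearest same-arm points (Euclidean
distance on z-scored features). Original rows are preserved unchanged,
binary covariates are re-thresholded at 0.5, and every synthetic sample is
recorded with its parents and interpolation coefficient so convexity and
class purity can be audited exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .preprocess import ArmDataset
from .schema import SCHEMA_BY_NAME

__all__ = ["ArmSMOTE", "smote_augment", "plan_external_counts"]


def _binary_columns(X: pd.DataFrame) -> list[str]:
    cols = []
    for c in X.columns:
        spec = SCHEMA_BY_NAME.get(c)
        if spec is not None:
            if spec.kind == "binary":
                cols.append(c)
        else:
            vals = X[c].dropna().unique()
            if len(vals) and np.isin(vals, (0.0, 1.0)).all():
                cols.append(c)
    return cols


@dataclass
class AugmentedSample:
    """Provenance record for one synthetic row."""

    drug_class: str
    synthetic_id: str
    parent_id: str
    neighbor_id: str
    u: float


class ArmSMOTE:
    """Joint-vector SMOTE over a map of per-arm datasets.

    Parameters
    ----------
    k_neighbors : neighbors considered per seed point (default 5).
    random_state : seed for seed-point choice, neighbor choice and u draws.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(
        self,
        datasets: dict[str, ArmDataset],
        target_counts: dict[str, int],
    ) -> tuple[dict[str, ArmDataset], list[AugmentedSample]]:
        """Grow each arm to ``target_counts[arm]`` rows; return provenance."""
        rng = np.random.default_rng(np.random.SeedSequence(self.random_state))
        out: dict[str, ArmDataset] = {}
        provenance: list[AugmentedSample] = []
        for arm in sorted(datasets):
            ds = datasets[arm]
            target = int(target_counts.get(arm, ds.n))
            if target < ds.n:
                raise ValueError(
                    f"target count {target} below current size {ds.n} for {arm}"
                )
            n_new = target - ds.n
            if n_new == 0:
                out[arm] = ds
                continue
            if ds.n <= self.k_neighbors:
                raise ValueError(
                    f"arm {arm} has {ds.n} <= k_neighbors={self.k_neighbors} "
                    "rows; use a smaller k"
                )
            out[arm], prov = self._augment_arm(ds, n_new, rng)
            provenance.extend(prov)
        return out, provenance

    def _augment_arm(
        self, ds: ArmDataset, n_new: int, rng: np.random.Generator
    ) -> tuple[ArmDataset, list[AugmentedSample]]:
        X = ds.X.to_numpy(dtype=float)
        y = ds.y.to_numpy(dtype=float)
        ids = list(ds.patient_ids) or [f"{ds.drug_class}_{i}" for i in range(ds.n)]

        # distances on z-scored features so no covariate dominates
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(Z)
        _, idx = nn.kneighbors(Z)  # column 0 is the point itself

        joint = np.column_stack([X, y])
        seeds = rng.integers(0, ds.n, size=n_new)
        picks = rng.integers(0, self.k_neighbors, size=n_new)
        us = rng.uniform(0.0, 1.0, size=n_new)

        new_rows = np.empty((n_new, joint.shape[1]))
        prov: list[AugmentedSample] = []
        for j in range(n_new):
            p = int(seeds[j])
            q = int(idx[p, 1 + picks[j]])
            new_rows[j] = joint[p] + us[j] * (joint[q] - joint[p])
            prov.append(
                AugmentedSample(
                    ds.drug_class,
                    f"{ds.drug_class}_syn{j:05d}",
                    ids[p],
                    ids[q],
                    float(us[j]),
                )
            )

        new_X = pd.DataFrame(new_rows[:, :-1], columns=ds.X.columns)
        for c in _binary_columns(ds.X):
            new_X[c] = (new_X[c] >= 0.5).astype(float)
        aug_X = pd.concat([ds.X.reset_index(drop=True), new_X], ignore_index=True)
        aug_y = pd.concat(
            [ds.y.reset_index(drop=True), pd.Series(new_rows[:, -1], name=ds.y.name)],
            ignore_index=True,
        )
        aug_ids = ids + [p.synthetic_id for p in prov]
        return ArmDataset(ds.drug_class, aug_X, aug_y, aug_ids), prov


def smote_augment(
    datasets: dict[str, ArmDataset],
    target_counts: dict[str, int],
    k_neighbors: int = 5,
    seed: int | None = None,
) -> tuple[dict[str, ArmDataset], list[AugmentedSample]]:
    """Functional wrapper over :class:`ArmSMOTE`."""
    return ArmSMOTE(k_neighbors=k_neighbors, random_state=seed).fit_resample(
        datasets, target_counts
    )


def plan_external_counts(
    train_counts: dict[str, int], test_n: int
) -> dict[str, int]:
    """Augmentation targets giving an ~80/20 train/test balance.

    Total training size is grown to about four times the external test
    size, distributed across arms proportionally to their current sizes;
    no arm shrinks.
    """
    if test_n <= 0:
        raise ValueError("test_n must be positive")
    total_now = sum(train_counts.values())
    total_target = 4 * test_n
    if total_now >= total_target:
        return dict(train_counts)
    return {
        d: max(n, int(round(total_target * n / total_now)))
        for d, n in train_counts.items()
    }
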
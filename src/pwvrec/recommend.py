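"""Argmax recommendation rule and its summary statistics.

The recommender picks, per patient, the drug whose arm model predicts the
largest standardized PWV reduction. Ties go to the first maximal column in
canonical drug order. Summaries mirror the usual reporting: the per-drug
match rate (how often the system re-recommends the drug the patient was
actually taking) and the distribution of recommendations over drugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import DRUG_CLASSES

__all__ = ["RecommendationSet", "recommend", "match_rate", "recommendation_distribution"]


@dataclass
class RecommendationSet:
    """Per-patient counterfactual predictions, recommendation and match flag."""

    table: pd.DataFrame  # per-drug prediction columns + recommended/actual/match

    @property
    def recommended(self) -> pd.Series:
        return self.table["recommended_drug"]

    @property
    def actual(self) -> pd.Series:
        return self.table["actual_drug"]

    @property
    def match(self) -> pd.Series:
        return self.table["match"]

    def __len__(self) -> int:
        return len(self.table)


def recommend(predictions: pd.DataFrame, actual_drugs=None) -> RecommendationSet:
    """Apply the argmax rule to an n x arms prediction matrix.

    ``predictions`` must have canonical drug-order columns; any non-finite
    entry is an error naming the offending row.
    """
    cols = [c for c in DRUG_CLASSES if c in predictions.columns]
    if list(predictions.columns) != cols:
        predictions = predictions[cols]
    vals = predictions.to_numpy(dtype=float)
    bad = ~np.isfinite(vals).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite prediction for row(s) {list(predictions.index[bad])}"
        )
    arm_arr = np.asarray(cols, dtype=object)
    rec = arm_arr[np.argmax(vals, axis=1)]  # first maximal column wins ties

    table = predictions.copy()
    table["recommended_drug"] = rec
    table["predicted_best_reduction"] = vals.max(axis=1)
    if actual_drugs is not None:
        actual = np.asarray(actual_drugs, dtype=object)
        if len(actual) != len(table):
            raise ValueError("actual_drugs length mismatch")
        table["actual_drug"] = actual
        table["match"] = table["recommended_drug"] == table["actual_drug"]
    return RecommendationSet(table)


def match_rate(recs: RecommendationSet) -> dict:
    """Per-drug and overall fraction of patients whose actual drug was
    re-recommended. Arms absent from the actual assignments get ``None``."""
    if "actual_drug" not in recs.table.columns:
        raise ValueError("recommendation set has no actual drugs")
    t = recs.table
    per_drug = {}
    for d in DRUG_CLASSES:
        on_d = t["actual_drug"] == d
        n = int(on_d.sum())
        per_drug[d] = None if n == 0 else int((on_d & t["match"]).sum()) / n
    overall = int(t["match"].sum()) / len(t)
    return {"per_drug": per_drug, "overall": overall}


def recommendation_distribution(recs: RecommendationSet) -> pd.DataFrame:
    """Counts and shares of patients recommended each drug (shares sum to 1)."""
    if len(recs) == 0:
        raise ValueError("empty recommendation set")
    counts = recs.recommended.value_counts()
    out = pd.DataFrame(
        {
            "count": [int(counts.get(d, 0)) for d in DRUG_CLASSES],
            "share": [counts.get(d, 0) / len(recs) for d in DRUG_CLASSES],
        },
        index=list(DRUG_CLASSES),
    )
    return out
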
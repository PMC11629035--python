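"""Data preparation: eligibility filtering, median imputation, PWV
standardization and construction of the six per-arm outcome datasets.

The outcome target for arm ``d`` is the standardized PWV change of the
patients who took ``d``:

    target = mean over modalities of  z(baseline) - z(followup),

where ``z`` uses the *baseline* training-set mean/SD of each modality (so
baseline and follow-up sit on one scale and the change score is a plain
difference). Positive targets mean PWV reduction, the direction the
recommender maximizes. Targets are never imputed: patients lacking a
follow-up PWV are dropped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    BA_BASELINE,
    BA_FOLLOWUP,
    CF_BASELINE,
    CF_FOLLOWUP,
    DRUG_CLASSES,
    DRUG_COL,
    FEATURE_NAMES,
    ID_COL,
    OTHER_DRUG,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ArmDataset",
    "PWVStandardizer",
    "MedianImputer",
    "filter_eligible",
    "impute_median",
    "standardize_pwv",
    "build_arm_datasets",
]

PWV_MODES = ("mean", "cf", "ba")


def filter_eligible(
    cohort: pd.DataFrame, min_group_size: int = 10
) -> pd.DataFrame:
    """Drop the pooled rare-drug class and any arm below ``min_group_size``.

    The threshold is exclusive (a group of exactly ``min_group_size`` is
    retained); row order is preserved.
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    counts = cohort[DRUG_COL].value_counts()
    keep = [
        d
        for d in counts.index
        if d != OTHER_DRUG and counts[d] >= min_group_size
    ]
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("filter_eligible: dropping arms %s", dropped)
    out = cohort[cohort[DRUG_COL].isin(keep)]
    if out.empty:
        raise ValueError("no drug class meets the minimum group size")
    return out.copy()


class MedianImputer:
    """Per-column median imputation with train -> test reuse.

    Medians are computed over observed values only (midpoint convention for
    even counts, as in :meth:`pandas.Series.median`); binary covariates use
    the same rule. ``transform`` is idempotent.
    """

    def __init__(self) -> None:
        self.medians_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "MedianImputer":
        all_missing = [c for c in X.columns if X[c].notna().sum() == 0]
        if all_missing:
            raise ValueError(
                f"cannot compute median for fully-missing column(s): {all_missing}"
            )
        self.medians_ = X.median(axis=0, skipna=True)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("MedianImputer is not fitted")
        return X.fillna(self.medians_.reindex(X.columns))

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def impute_median(
    X: pd.DataFrame, medians: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing cells with column medians; return (completed, medians).

    When ``medians`` is supplied (train -> test reuse) it is applied as-is.
    """
    if medians is None:
        imp = MedianImputer().fit(X)
        medians = imp.medians_
        return imp.transform(X), medians
    return X.fillna(medians.reindex(X.columns)), medians


@dataclass
class PWVStandardizer:
    """Baseline-anchored z-scaling of the two PWV modalities.

    Fitting estimates mean/SD (population SD, ddof=0) of the *baseline*
    cfPWV and baPWV on the training rows; both baseline and follow-up
    values are then standardized with the same parameters.
    """

    mean_cf: float = float("nan")
    sd_cf: float = float("nan")
    mean_ba: float = float("nan")
    sd_ba: float = float("nan")

    def fit(self, cohort: pd.DataFrame) -> "PWVStandardizer":
        for attr_m, attr_s, col in (
            ("mean_cf", "sd_cf", CF_BASELINE),
            ("mean_ba", "sd_ba", BA_BASELINE),
        ):
            vals = cohort[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            sd = float(np.std(vals))
            if sd <= 0:
                raise ValueError(f"zero variance in {col}; cannot standardize")
            setattr(self, attr_m, float(np.mean(vals)))
            setattr(self, attr_s, sd)
        return self

    @property
    def is_fitted(self) -> bool:
        return np.isfinite(self.sd_cf) and np.isfinite(self.sd_ba)

    def z(self, values, modality: str) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError("PWVStandardizer is not fitted")
        if modality == "cf":
            return (np.asarray(values, dtype=float) - self.mean_cf) / self.sd_cf
        if modality == "ba":
            return (np.asarray(values, dtype=float) - self.mean_ba) / self.sd_ba
        raise ValueError(f"unknown modality {modality!r}")

    def change_score(self, cohort: pd.DataFrame, mode: str = "mean") -> pd.Series:
        """Standardized PWV change (positive = reduction) per patient."""
        if mode not in PWV_MODES:
            raise ValueError(f"mode must be one of {PWV_MODES}")
        d_cf = self.z(cohort[CF_BASELINE], "cf") - self.z(cohort[CF_FOLLOWUP], "cf")
        d_ba = self.z(cohort[BA_BASELINE], "ba") - self.z(cohort[BA_FOLLOWUP], "ba")
        if mode == "cf":
            out = d_cf
        elif mode == "ba":
            out = d_ba
        else:
            out = 0.5 * (d_cf + d_ba)
        return pd.Series(out, index=cohort.index, name="delta_pwv_z")

    def to_dict(self) -> dict:
        return {
            "mean_cf": self.mean_cf,
            "sd_cf": self.sd_cf,
            "mean_ba": self.mean_ba,
            "sd_ba": self.sd_ba,
        }


def standardize_pwv(
    cohort: pd.DataFrame, params: PWVStandardizer | None = None
) -> tuple[pd.DataFrame, PWVStandardizer]:
    """Standardize the four PWV columns; returns (z-values frame, params)."""
    if params is None:
        params = PWVStandardizer().fit(cohort)
    out = pd.DataFrame(index=cohort.index)
    out["cfpwv_baseline_z"] = params.z(cohort[CF_BASELINE], "cf")
    out["cfpwv_followup_z"] = params.z(cohort[CF_FOLLOWUP], "cf")
    out["bapwv_baseline_z"] = params.z(cohort[BA_BASELINE], "ba")
    out["bapwv_followup_z"] = params.z(cohort[BA_FOLLOWUP], "ba")
    return out, params


@dataclass
class ArmDataset:
    """Complete-case, imputed design matrix and target for one drug arm."""

    drug_class: str
    X: pd.DataFrame
    y: pd.Series
    patient_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("ArmDataset feature matrix contains missing values")
        if not np.all(np.isfinite(self.y.to_numpy(dtype=float))):
            raise ValueError("ArmDataset target contains non-finite values")
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def build_arm_datasets(
    cohort: pd.DataFrame,
    standardizer: PWVStandardizer | None = None,
    medians: pd.Series | None = None,
    mode: str = "mean",
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[dict[str, ArmDataset], dict]:
    """Split an eligible cohort into per-arm modelling datasets.

    Returns (datasets keyed by drug class in canonical order, params) where
    ``params`` records the fitted standardizer, imputation medians, the
    target mode and the ids of patients excluded for missing outcome PWV.
    """
    unknown = sorted(set(cohort[DRUG_COL]) - set(DRUG_CLASSES))
    if unknown:
        raise ValueError(f"unknown drug class(es) {unknown}; filter first")

    outcome_cols = [CF_BASELINE, BA_BASELINE, CF_FOLLOWUP, BA_FOLLOWUP]
    complete = cohort[outcome_cols].notna().all(axis=1)
    excluded = cohort.loc[~complete, ID_COL].tolist()
    if excluded:
        logger.warning(
            "build_arm_datasets: excluding %d patient(s) with missing outcome PWV",
            len(excluded),
        )
    kept = cohort[complete]

    if standardizer is None:
        standardizer = PWVStandardizer().fit(kept)
    target = standardizer.change_score(kept, mode=mode)

    feats = kept[list(feature_names)]
    feats, medians = impute_median(feats, medians)

    datasets: dict[str, ArmDataset] = {}
    for d in DRUG_CLASSES:
        mask = (kept[DRUG_COL] == d).to_numpy()
        if not mask.any():
            continue
        datasets[d] = ArmDataset(
            drug_class=d,
            X=feats[mask].reset_index(drop=True),
            y=target[mask].reset_index(drop=True),
            patient_ids=kept.loc[mask, ID_COL].tolist(),
        )
    params = {
        "standardizer": standardizer,
        "medians": medians,
        "mode": mode,
        "excluded_patient_ids": excluded,
    }
    return datasets, params
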
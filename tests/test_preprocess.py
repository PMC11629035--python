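"""Preparation steps: filtering, imputation, standardization, arm datasets."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from pwvrec.preprocess import (
    MedianImputer,
    PWVStandardizer,
    build_arm_datasets,
    filter_eligible,
    impute_median,
    standardize_pwv,
)
from pwvrec.schema import (
    BA_BASELINE,
    BA_FOLLOWUP,
    CF_BASELINE,
    CF_FOLLOWUP,
    DRUG_CLASSES,
    DRUG_COL,
    ID_COL,
)


def _toy_cohort(drugs):
    n = len(drugs)
    return pd.DataFrame(
        {
            ID_COL: [f"P{i}" for i in range(n)],
            DRUG_COL: drugs,
            CF_BASELINE: np.linspace(8, 12, n),
            BA_BASELINE: np.linspace(12, 16, n),
            CF_FOLLOWUP: np.linspace(7, 11, n),
            BA_FOLLOWUP: np.linspace(11, 15, n),
        }
    )


class TestFilterEligible:
    def test_small_and_other_groups_dropped(self):
        cohort = _toy_cohort(["ACEI"] * 12 + ["OTHER"] * 3)
        out = filter_eligible(cohort)
        assert len(out) == 12
        assert set(out[DRUG_COL]) == {"ACEI"}

    def test_exactly_threshold_retained(self):
        cohort = _toy_cohort(["ACEI"] * 10 + ["ARB"] * 9)
        out = filter_eligible(cohort)
        assert set(out[DRUG_COL]) == {"ACEI"}
        assert len(out) == 10

    def test_other_dropped_even_when_large(self):
        cohort = _toy_cohort(["OTHER"] * 30 + ["ARB"] * 10)
        out = filter_eligible(cohort)
        assert set(out[DRUG_COL]) == {"ARB"}

    def test_order_preserved_and_empty_error(self):
        cohort = _toy_cohort(["ACEI", "ARB"] * 10)
        out = filter_eligible(cohort)
        assert list(out[ID_COL]) == list(cohort[ID_COL])
        with pytest.raises(ValueError):
            filter_eligible(_toy_cohort(["ACEI"] * 3))


class TestMedianImputation:
    def test_hand_median(self):
        X = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0]})
        out, med = impute_median(X)
        assert med["a"] == 2.0
        assert list(out["a"]) == [1.0, 2.0, 2.0, 4.0]

    def test_no_missing_identity_and_idempotence(self):
        X = pd.DataFrame({"a": [1.0, 3.0], "b": [0.0, 1.0]})
        out, med = impute_median(X)
        pdt.assert_frame_equal(out, X)
        again, _ = impute_median(out, med)
        pdt.assert_frame_equal(again, out)

    def test_train_test_reuse_bit_identical(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X[X > 1.2] = np.nan
        imp = MedianImputer().fit(X)
        pdt.assert_frame_equal(imp.transform(X), imp.transform(X.copy()))

    def test_median_order_invariant(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=31)})
        X.loc[rng.choice(31, 5, replace=False), "a"] = np.nan
        _, med1 = impute_median(X)
        _, med2 = impute_median(X.sample(frac=1, random_state=3).reset_index(drop=True))
        assert med1["a"] == med2["a"]

    def test_fully_missing_column_named_in_error(self):
        X = pd.DataFrame({"ok": [1.0, 2.0], "gone": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="gone"):
            impute_median(X)


class TestStandardization:
    def test_hand_z_scores(self):
        cohort = _toy_cohort(["ACEI"] * 3)
        cohort[CF_BASELINE] = [8.0, 10.0, 12.0]
        cohort[BA_BASELINE] = [8.0, 10.0, 12.0]
        params = PWVStandardizer().fit(cohort)
        np.testing.assert_allclose(
            params.z([8.0, 10.0, 12.0], "cf"),
            [-1.224745, 0.0, 1.224745],
            atol=1e-6,
        )
        assert params.z([params.mean_ba], "ba")[0] == 0.0

    def test_refit_on_standardized_recovers_unit_scale(self):
        cohort = _toy_cohort(["ACEI"] * 8)
        params = PWVStandardizer().fit(cohort)
        zvals, _ = standardize_pwv(cohort, params)
        restd = cohort.copy()
        restd[CF_BASELINE] = zvals["cfpwv_baseline_z"]
        restd[BA_BASELINE] = zvals["bapwv_baseline_z"]
        refit = PWVStandardizer().fit(restd)
        assert refit.mean_cf == pytest.approx(0.0, abs=1e-12)
        assert refit.sd_cf == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        cohort = _toy_cohort(["ACEI"] * 4)
        cohort[CF_BASELINE] = 9.0
        with pytest.raises(ValueError):
            PWVStandardizer().fit(cohort)


class TestArmDatasets:
    def test_partition_covers_eligible_patients(self, small_cohort):
        from pwvrec.preprocess import filter_eligible

        cohort, _ = small_cohort
        eligible = filter_eligible(cohort)
        datasets, _ = build_arm_datasets(eligible)
        ids = [pid for ds in datasets.values() for pid in ds.patient_ids]
        assert sorted(ids) == sorted(eligible[ID_COL])
        for d, ds in datasets.items():
            assert (eligible.set_index(ID_COL).loc[ds.patient_ids, DRUG_COL] == d).all()

    def test_target_sign_convention(self):
        # baseline z=1, follow-up z=0.2 in both modalities -> target 0.8
        cohort = _toy_cohort(["ACEI"] * 21)
        params = PWVStandardizer().fit(cohort)
        row = cohort.iloc[:1].copy()
        row[CF_BASELINE] = params.mean_cf + 1.0 * params.sd_cf
        row[CF_FOLLOWUP] = params.mean_cf + 0.2 * params.sd_cf
        row[BA_BASELINE] = params.mean_ba + 1.0 * params.sd_ba
        row[BA_FOLLOWUP] = params.mean_ba + 0.2 * params.sd_ba
        assert params.change_score(row).iloc[0] == pytest.approx(0.8)

    def test_missing_outcome_dropped_not_imputed(self, small_cohort):
        from pwvrec.preprocess import filter_eligible

        cohort, _ = small_cohort
        eligible = filter_eligible(cohort).copy()
        drop_ids = eligible[ID_COL].iloc[[0, 5, 9]].tolist()
        eligible.loc[eligible[ID_COL].isin(drop_ids), CF_FOLLOWUP] = np.nan
        datasets, params = build_arm_datasets(eligible)
        assert sorted(params["excluded_patient_ids"]) == sorted(drop_ids)
        kept = [pid for ds in datasets.values() for pid in ds.patient_ids]
        assert set(drop_ids).isdisjoint(kept)

    def test_unknown_drug_rejected(self):
        cohort = _toy_cohort(["ACEI"] * 10 + ["MYSTERY"] * 10)
        with pytest.raises(ValueError):
            build_arm_datasets(cohort)
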
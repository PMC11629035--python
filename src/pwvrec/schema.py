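"""Feature schema and naming conventions for the hypertensive cohort.

The cohort table has one row per patient: identifiers (patient, source
study, assigned drug class), 64 candidate covariates spanning demographics,
lifestyle, concomitant medication, anthropometry, hemodynamics and blood
biochemistry, and the outcome block (baseline and >=1-year follow-up
carotid-femoral and brachial-ankle pulse wave velocity, in m/s).

The two baseline PWV measurements play a double role: they are outcome
anchors and at the same time legitimate predictors of treatment response,
so they appear both in the covariate schema and in the PWV column block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

# ---------------------------------------------------------------------------
# Column naming
# ---------------------------------------------------------------------------

ID_COL = "patient_id"
COHORT_COL = "cohort_id"
DRUG_COL = "drug_class"
CF_BASELINE = "cfpwv_baseline"
BA_BASELINE = "bapwv_baseline"
CF_FOLLOWUP = "cfpwv_followup"
BA_FOLLOWUP = "bapwv_followup"
FOLLOWUP_YEARS = "followup_years"

#: Canonical drug-class order; argmax ties are broken by this order.
DRUG_CLASSES = ("ACEI", "ARB", "BB", "DIU", "DIU_ACEI", "DIU_ARB")
#: Pooled label for antihypertensive classes too rare to model.
OTHER_DRUG = "OTHER"

COHORTS = ("EVA", "LOD", "EVIDENT")

PWV_COLS = (CF_BASELINE, BA_BASELINE, CF_FOLLOWUP, BA_FOLLOWUP)


@dataclass(frozen=True)
class FeatureSpec:
    """One covariate: name, kind, units and marginal moments.

    ``mean``/``sd`` anchor the synthetic generator; ``lo``/``hi`` bound the
    admissible range (truncation limits for continuous draws). For binary
    covariates ``mean`` is the prevalence and ``sd`` is implied.
    """

    name: str
    kind: str  # "continuous" | "binary" | "count"
    units: str
    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "count"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.sd < 0:
            raise ValueError(f"negative sd for {self.name}")
        if self.kind != "binary" and not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean outside [lo, hi] for {self.name}")


def _c(name, units, mean, sd, lo, hi):
    return FeatureSpec(name, "continuous", units, mean, sd, lo, hi)


def _b(name, prevalence):
    return FeatureSpec(name, "binary", "0/1", prevalence, float("nan"), 0.0, 1.0)


def _k(name, units, mean, sd, lo, hi):
    return FeatureSpec(name, "count", units, mean, sd, lo, hi)


# 64 candidate covariates with marginal moments of the pooled study sample.
FEATURE_SCHEMA: tuple[FeatureSpec, ...] = (
    # demographics
    _c("age", "years", 61.8, 10.0, 30.0, 90.0),
    _b("sex_female", 0.495),
    # lifestyle
    _b("smoker_current", 0.134),
    _b("smoker_former", 0.366),
    _k("cigarettes_per_day", "n/day", 5.75, 10.8, 0.0, 60.0),
    _c("alcohol_g_week", "g/week", 55.5, 111.2, 0.0, 800.0),
    _k("medas_score", "units", 7.4, 2.0, 0.0, 14.0),
    # concomitant medication
    _b("antidiabetics", 0.278),
    _b("lipid_lowering", 0.474),
    _b("antiaggregants", 0.222),
    _b("anticoagulants", 0.021),
    _b("nsaids", 0.005),
    # anthropometry
    _c("height_cm", "cm", 162.5, 10.3, 130.0, 200.0),
    _c("weight_kg", "kg", 80.5, 15.3, 40.0, 140.0),
    _c("waist_cm", "cm", 102.6, 10.4, 60.0, 150.0),
    # hemodynamics / vascular
    _c("sbp", "mmHg", 131.2, 16.4, 80.0, 220.0),
    _c("dbp", "mmHg", 81.0, 11.4, 40.0, 130.0),
    _c("heart_rate", "bpm", 69.7, 11.6, 40.0, 120.0),
    _c("abi", "units", 1.1, 0.1, 0.5, 1.6),
    _c(CF_BASELINE, "m/s", 9.5, 2.6, 4.0, 30.0),
    _c(BA_BASELINE, "m/s", 14.2, 2.3, 5.0, 30.0),
    _c("cavi", "m/s", 8.3, 1.3, 4.0, 14.0),
    _c("aix75", "%", 30.8, 10.8, 0.0, 70.0),
    _c("imt_mm", "mm", 0.7, 0.1, 0.3, 1.5),
    _b("imt_plaque", 0.277),
    _c("cornell_index", "mm", 15.1, 5.6, 0.0, 40.0),
    _c("lvh_cornell", "ms*mV", 1600.0, 610.6, 200.0, 4500.0),
    # hematology
    _c("red_blood_cells", "1e6/mm3", 4.8, 0.4, 3.0, 7.0),
    _c("hemoglobin", "g/dL", 14.5, 1.3, 9.0, 20.0),
    _c("hematocrit", "%", 43.3, 3.6, 30.0, 60.0),
    _c("mchc", "g/dL", 29.7, 2.2, 22.0, 38.0),
    _c("chbcm", "pg", 33.3, 0.9, 28.0, 38.0),
    _c("mcv", "fl", 89.2, 5.7, 65.0, 110.0),
    _c("anisocytosis", "%", 12.8, 1.2, 9.0, 20.0),
    _c("leukocytes", "1e6/mm3", 6.8, 1.9, 2.0, 15.0),
    _c("neutrophils", "1e6/mm3", 3.8, 1.3, 1.0, 12.0),
    _c("lymphocytes", "1e6/mm3", 2.2, 0.7, 0.5, 6.0),
    _c("monocytes", "1e6/mm3", 0.5, 0.1, 0.1, 1.5),
    _c("eosinophils", "1e6/mm3", 0.2, 0.1, 0.0, 1.5),
    _c("basophils", "1e6/mm3", 0.1, 0.1, 0.0, 0.8),
    _c("platelets", "1e9/L", 231.4, 59.5, 50.0, 500.0),
    _c("rdw", "%", 12.7, 0.9, 10.0, 20.0),
    _c("mpv", "fl", 9.4, 1.8, 5.0, 15.0),
    # glycemia
    _c("fpg", "mg/dL", 101.7, 27.2, 50.0, 300.0),
    _c("hba1c", "%", 5.9, 0.8, 4.0, 14.0),
    _c("insulin", "mIU/L", 12.4, 7.6, 1.0, 60.0),
    # lipids
    _c("total_cholesterol", "mg/dL", 191.3, 32.5, 80.0, 350.0),
    _c("cldl", "mg/dL", 95.9, 38.1, 20.0, 250.0),
    _c("chdl", "mg/dL", 69.5, 34.3, 15.0, 250.0),
    _c("triglycerides", "mg/dL", 131.0, 61.5, 30.0, 500.0),
    # renal
    _c("uric_acid", "mg/dL", 5.7, 1.4, 1.0, 12.0),
    _c("serum_creatinine", "mg/dL", 0.8, 0.1, 0.3, 2.0),
    _c("creatinine_clearance", "ug/min", 117.0, 66.6, 5.0, 400.0),
    _c("microalbuminuria", "mg/day", 19.1, 48.7, 0.0, 500.0),
    _c("albumin_creatinine_ratio", "ratio", 17.3, 39.0, 0.0, 400.0),
    _c("egfr", "mL/min/1.73m2", 85.2, 14.1, 15.0, 130.0),
    # hepatic
    _c("ast_got", "U/L", 23.6, 12.8, 5.0, 150.0),
    _c("alt_sgpt", "U/L", 26.6, 18.5, 5.0, 200.0),
    _c("ggt", "U/L", 32.9, 37.4, 5.0, 400.0),
    # inflammation / endocrine / vitamins
    _c("fibrinogen", "mg/dL", 344.0, 78.3, 150.0, 700.0),
    _c("crp", "mg/dL", 0.3, 0.4, 0.0, 5.0),
    _c("tsh", "mU/L", 2.4, 1.3, 0.1, 10.0),
    _c("t4", "ug/dL", 1.1, 0.1, 0.5, 2.0),
    _c("vitamin_d", "ug/dL", 23.4, 9.7, 4.0, 80.0),
)

_names = [f.name for f in FEATURE_SCHEMA]
if len(_names) != len(set(_names)):  # pragma: no cover - schema sanity
    raise RuntimeError("duplicate feature names in schema")

FEATURE_NAMES: tuple[str, ...] = tuple(_names)

#: Covariate columns that may be masked by the missingness mechanism.
#: Baseline PWV columns are PWV fields and are never masked.
MASKABLE_FEATURES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n not in (CF_BASELINE, BA_BASELINE)
)

SCHEMA_BY_NAME: dict[str, FeatureSpec] = {f.name: f for f in FEATURE_SCHEMA}

#: Observed arm sizes in the pooled sample of 194 patients.
ARM_COUNTS = {"ACEI": 44, "ARB": 47, "BB": 17, "DIU": 14, "DIU_ACEI": 28, "DIU_ARB": 44}
#: Source-study sizes in the pooled sample (EVA / LOD / EVIDENT).
COHORT_COUNTS = {"EVA": 56, "LOD": 57, "EVIDENT": 81}

ASSIGNMENT_PROBS = {d: c / 194.0 for d, c in ARM_COUNTS.items()}
COHORT_PROBS = {c: v / 194.0 for c, v in COHORT_COUNTS.items()}

COHORT_COLUMNS = (
    (ID_COL, COHORT_COL, DRUG_COL)
    + FEATURE_NAMES
    + (CF_FOLLOWUP, BA_FOLLOWUP, FOLLOWUP_YEARS)
)


def validate_feature_names(names: Iterable[str]) -> None:
    """Raise ``KeyError`` if any name is not in the covariate schema."""
    unknown = [n for n in names if n not in SCHEMA_BY_NAME]
    if unknown:
        raise KeyError(f"unknown covariate(s): {unknown}")
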
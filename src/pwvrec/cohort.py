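"""Synthetic cohort generator with known ground-truth treatment effects.

The generator emulates the statistical structure the downstream analysis
assumes: 64 covariates drawn independently as truncated Gaussians /
Bernoullis at the pooled-sample marginal moments, a six-arm drug
assignment at the observed arm proportions, and per-arm heterogeneous
PWV-change functions. Each arm's true effect is a linear index over a
small set of effect-modifier covariates (standardized against the schema
moments), so the best drug differs across patients and the oracle policy
is known exactly. On the raw m/s scale

    followup = baseline - g_d(x) - eps,   eps ~ N(0, noise_sd),

independently for the carotid-femoral and brachial-ankle modalities, so a
positive effect means PWV reduction (benefit). Drawing covariates
independently is a deliberate simplification: it does not reproduce the
correlation structure of real cohort data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema import (
    ASSIGNMENT_PROBS,
    BA_BASELINE,
    BA_FOLLOWUP,
    CF_BASELINE,
    CF_FOLLOWUP,
    COHORT_COL,
    COHORT_PROBS,
    COHORTS,
    DRUG_CLASSES,
    DRUG_COL,
    FEATURE_NAMES,
    FEATURE_SCHEMA,
    FOLLOWUP_YEARS,
    ID_COL,
    MASKABLE_FEATURES,
    OTHER_DRUG,
    SCHEMA_BY_NAME,
    FeatureSpec,
    validate_feature_names,
)

__all__ = [
    "EffectFunction",
    "SyntheticTruth",
    "default_truth",
    "generate_cohort",
    "compute_bapwv",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class EffectFunction:
    """Linear treatment-effect index g_d(x) = intercept + sum c_j z_j.

    ``z_j`` is the covariate standardized by its schema mean/SD, so the
    coefficients are in m/s of PWV reduction per SD of the modifier.
    """

    modifiers: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float = 0.5

    def __post_init__(self) -> None:
        if len(self.modifiers) != len(self.coefficients):
            raise ValueError("modifiers and coefficients must align")
        validate_feature_names(self.modifiers)

    def __call__(self, features: pd.DataFrame) -> np.ndarray:
        g = np.full(len(features), self.intercept, dtype=float)
        for name, coef in zip(self.modifiers, self.coefficients):
            spec = SCHEMA_BY_NAME[name]
            sd = spec.sd if spec.kind != "binary" else float(
                np.sqrt(spec.mean * (1.0 - spec.mean))
            )
            z = (features[name].to_numpy(dtype=float) - _marginal_mean(spec)) / sd
            g += coef * z
        return g

    @property
    def scale(self) -> float:
        """SD of the index for independent unit-variance modifiers."""
        return float(np.sqrt(np.sum(np.square(self.coefficients))))


def _marginal_mean(spec: FeatureSpec) -> float:
    return spec.mean


# Effect modifiers per arm follow the top of each arm's importance ordering
# in the pooled-cohort analysis (e.g. ACEI response modified by weight and
# HbA1c, ARB by baseline cfPWV and LDL cholesterol).
DEFAULT_MODIFIERS: dict[str, tuple[str, ...]] = {
    "ACEI": ("weight_kg", "hba1c", "alt_sgpt", "creatinine_clearance"),
    "ARB": (CF_BASELINE, "cldl", "ast_got", "chbcm"),
    "BB": ("tsh", "dbp", CF_BASELINE, "hba1c"),
    "DIU": ("cavi", "waist_cm", "vitamin_d", "chdl"),
    "DIU_ACEI": ("aix75", "uric_acid", "abi", "lvh_cornell"),
    "DIU_ARB": ("basophils", "mpv", "mcv", "lvh_cornell"),
}

DEFAULT_COEFFICIENTS = (0.6, 0.4, 0.2, 0.1)


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a generated cohort."""

    effects: dict[str, EffectFunction]
    noise_sd: float
    assignment_probs: dict[str, float] = field(
        default_factory=lambda: dict(ASSIGNMENT_PROBS)
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = [d for d in DRUG_CLASSES if d not in self.effects]
        if missing:
            raise ValueError(f"effect function missing for arms {missing}")

    def effect_matrix(self, features: pd.DataFrame) -> pd.DataFrame:
        """True g_d(x) for every patient x arm, canonical column order."""
        return pd.DataFrame(
            {d: self.effects[d](features) for d in DRUG_CLASSES},
            index=features.index,
        )

    def oracle_policy(self, features: pd.DataFrame) -> pd.Series:
        """Arm maximizing the true reduction; ties -> canonical order."""
        g = self.effect_matrix(features)
        return pd.Series(
            np.asarray(DRUG_CLASSES)[np.argmax(g.to_numpy(), axis=1)],
            index=features.index,
            name="oracle_drug",
        )

    @property
    def effect_spread(self) -> float:
        """Mean per-arm index SD; the natural scale for noise levels."""
        return float(np.mean([self.effects[d].scale for d in DRUG_CLASSES]))

    def to_json(self) -> str:
        payload = {
            "noise_sd": self.noise_sd,
            "assignment_probs": self.assignment_probs,
            "effects": {
                d: {
                    "modifiers": list(e.modifiers),
                    "coefficients": list(e.coefficients),
                    "intercept": e.intercept,
                }
                for d, e in self.effects.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        effects = {
            d: EffectFunction(
                tuple(e["modifiers"]), tuple(e["coefficients"]), e["intercept"]
            )
            for d, e in payload["effects"].items()
        }
        return cls(effects, payload["noise_sd"], payload["assignment_probs"])


def default_truth(
    noise_sd: float | None = None,
    modifiers: dict[str, tuple[str, ...]] | None = None,
    coefficients: tuple[float, ...] = DEFAULT_COEFFICIENTS,
    intercept: float = 0.5,
) -> SyntheticTruth:
    """Default ground truth: 4 modifiers per arm, coefficients (.6,.4,.2,.1).

    ``noise_sd`` defaults to a quarter of the effect spread, the reference
    signal-to-noise condition of the simulation studies.
    """
    modifiers = modifiers or DEFAULT_MODIFIERS
    effects = {
        d: EffectFunction(tuple(m), coefficients[: len(m)], intercept)
        for d, m in modifiers.items()
    }
    truth = SyntheticTruth(effects, noise_sd=0.0)
    if noise_sd is None:
        noise_sd = 0.25 * truth.effect_spread
    truth.noise_sd = float(noise_sd)
    return truth


_TRUNC_LOC_CACHE: dict[tuple[float, float, float, float], float] = {}


def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose truncated-normal mean equals ``mean``.

    Truncation shifts the mean of a clipped Gaussian (strongly so for
    skewed variables like cigarettes/day); solving for the location keeps
    the generated marginal mean on the schema value.
    """
    key = (mean, sd, lo, hi)
    if key not in _TRUNC_LOC_CACHE:
        def gap(loc: float) -> float:
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

        _TRUNC_LOC_CACHE[key] = float(
            optimize.brentq(gap, mean - 12 * sd, mean + 12 * sd, xtol=1e-10)
        )
    return _TRUNC_LOC_CACHE[key]


def _draw_feature(spec: FeatureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "binary":
        return rng.binomial(1, spec.mean, size=n).astype(float)
    loc = _truncnorm_loc(spec.mean, spec.sd, spec.lo, spec.hi)
    a = (spec.lo - loc) / spec.sd
    b = (spec.hi - loc) / spec.sd
    vals = stats.truncnorm.rvs(a, b, loc=loc, scale=spec.sd, size=n, random_state=rng)
    if spec.kind == "count":
        vals = np.clip(np.round(vals), spec.lo, spec.hi)
    return np.asarray(vals, dtype=float)


def generate_cohort(
    n: int,
    seed: int,
    truth: SyntheticTruth | None = None,
    noise_sd: float | None = None,
    other_share: float = 0.0,
    evident_shift_sd: float = 0.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic cohort of ``n`` patients.

    Parameters
    ----------
    n : cohort size; must be large enough that every arm receives at least
        one patient under the multinomial assignment.
    seed : master seed; identical inputs give field-identical cohorts.
    truth : ground-truth configuration; defaults to :func:`default_truth`.
    noise_sd : overrides ``truth.noise_sd`` (m/s) when given.
    other_share : probability mass assigned to the pooled rare-drug class
        ``OTHER`` (taken proportionally from the six modelled arms).
    evident_shift_sd : shift (in SDs) added to every continuous covariate
        of EVIDENT-cohort patients, emulating between-study distribution
        shift for external-validation experiments.

    Returns
    -------
    (cohort DataFrame, SyntheticTruth)
    """
    if n < len(DRUG_CLASSES):
        raise ValueError(f"n={n} cannot populate all {len(DRUG_CLASSES)} arms")
    truth = truth or default_truth()
    if noise_sd is not None:
        truth = SyntheticTruth(truth.effects, float(noise_sd), truth.assignment_probs)
    if not 0.0 <= other_share < 1.0:
        raise ValueError("other_share must be in [0, 1)")

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df[ID_COL] = [f"P{i:06d}" for i in range(n)]

    cohort_p = np.array([COHORT_PROBS[c] for c in COHORTS])
    df[COHORT_COL] = rng.choice(COHORTS, size=n, p=cohort_p / cohort_p.sum())

    arms = list(DRUG_CLASSES)
    probs = np.array([truth.assignment_probs[d] for d in arms], dtype=float)
    probs = probs / probs.sum() * (1.0 - other_share)
    if other_share > 0:
        arms.append(OTHER_DRUG)
        probs = np.append(probs, other_share)
    df[DRUG_COL] = rng.choice(arms, size=n, p=probs)
    empty = [d for d in DRUG_CLASSES if (df[DRUG_COL] == d).sum() == 0]
    if empty:
        raise ValueError(f"n={n} too small: arm(s) {empty} received no patients")

    for spec in FEATURE_SCHEMA:
        df[spec.name] = _draw_feature(spec, n, rng)

    if evident_shift_sd != 0.0:
        mask = (df[COHORT_COL] == "EVIDENT").to_numpy()
        for spec in FEATURE_SCHEMA:
            if spec.kind == "binary":
                continue
            shifted = df.loc[mask, spec.name] + evident_shift_sd * spec.sd
            df.loc[mask, spec.name] = np.clip(shifted, spec.lo, spec.hi)

    g_assigned = np.zeros(n)
    for d in DRUG_CLASSES:
        mask = (df[DRUG_COL] == d).to_numpy()
        if mask.any():
            g_assigned[mask] = truth.effects[d](df.loc[mask])
    if other_share > 0:
        # rare-drug patients get a flat average effect; they are filtered
        # out before modelling anyway
        mask = (df[DRUG_COL] == OTHER_DRUG).to_numpy()
        if mask.any():
            g_assigned[mask] = np.mean(
                [truth.effects[d](df.loc[mask]) for d in DRUG_CLASSES], axis=0
            )

    eps_cf = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else 0.0
    eps_ba = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else 0.0
    df[CF_FOLLOWUP] = df[CF_BASELINE] - g_assigned - eps_cf
    df[BA_FOLLOWUP] = df[BA_BASELINE] - g_assigned - eps_ba
    df[FOLLOWUP_YEARS] = rng.uniform(1.0, 2.0, size=n).round(2)

    return df, truth


def compute_bapwv(height_cm: float, tba_s: float) -> float:
    """Brachial-ankle PWV (m/s) from height and arm-ankle transit time.

    Path length is estimated from height as ``0.5934*height_cm + 14.4724``
    (cm); dividing by the transit time ``tba_s`` (s) gives cm/s, converted
    to m/s.
    """
    if not 100.0 < height_cm < 230.0:
        raise ValueError(f"height_cm={height_cm} outside plausible (100, 230)")
    if tba_s <= 0:
        raise ValueError("tba_s must be positive")
    return (0.5934 * height_cm + 14.4724) / tba_s / 100.0


def inject_missingness(
    cohort: pd.DataFrame, rate: float, seed: int
) -> pd.DataFrame:
    """Set covariate cells missing completely at random with probability ``rate``.

    PWV columns, drug class and identifiers are never masked; the baseline
    PWV covariates count as PWV fields and are likewise exempt.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cols = [c for c in MASKABLE_FEATURES if c in out.columns]
    mask = rng.random((len(out), len(cols))) < rate
    block = out[cols].to_numpy(dtype=float)
    block[mask] = np.nan
    out[cols] = block
    return out


def write_cohort(cohort: pd.DataFrame, truth: SyntheticTruth, prefix: str) -> None:
    """Write ``<prefix>.csv`` and a ``<prefix>.truth.json`` sidecar."""
    cohort.to_csv(f"{prefix}.csv", index=False)
    with open(f"{prefix}.truth.json", "w") as fh:
        fh.write(truth.to_json())


def read_cohort(prefix: str) -> tuple[pd.DataFrame, SyntheticTruth | None]:
    """Read a cohort CSV and, when present, its truth sidecar."""
    cohort = pd.read_csv(f"{prefix}.csv")
    try:
        with open(f"{prefix}.truth.json") as fh:
            truth = SyntheticTruth.from_json(fh.read())
    except FileNotFoundError:
        truth = None
    return cohort, truth
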
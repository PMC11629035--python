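# Methods

## Problem and model

Arterial stiffness, measured as pulse wave velocity (PWV), is an
independent cardiovascular risk factor, and antihypertensive drug classes
differ in how much they reduce it — with effects that plausibly depend on
individual patient characteristics. `pwvrec` implements an individualized
recommendation pipeline for six drug classes (ACEI, ARB, β-blocker,
diuretic, diuretic+ACEI, diuretic+ARB):

1. **Outcome.** For each patient, carotid-femoral and brachial-ankle PWV
   are measured at baseline and at ≥1-year follow-up. Each modality is
   z-scaled with the *baseline* training-set mean/SD (population SD), and
   the target is the standardized change, positive = reduction:

       Δ = ½ [ z(cf_base) − z(cf_follow) ] + ½ [ z(ba_base) − z(ba_follow) ].

   Averaging the two standardized modalities into one target is a design
   choice (both are primary outcomes and sit on the same z-scale after
   baseline-anchored standardization); `pwv_mode="cf"`/`"ba"` selects a
   single modality instead.
2. **Per-arm outcome models (T-learner).** One random-forest regressor per
   drug class, trained only on that class's patients. A full 64-covariate
   forest is fitted first; features are ranked by the consensus (mean of
   ranks) of mean-decrease-in-impurity and permutation importance, the top
   10 are kept, and the forest is refitted on those alone. Counterfactual
   prediction queries all six reduced models on one patient's covariates.
3. **Recommendation.** The argmax rule: recommend the drug with the
   largest predicted standardized PWV reduction; ties go to the first
   maximal column in the canonical order (ACEI, ARB, BB, DIU, DIU_ACEI,
   DIU_ARB). No minimum-benefit threshold is applied by default.
4. **Validation.** *Internal*: a drug-class-stratified 80/20 holdout of
   the pooled cohorts; per-arm R² and MSE on the held-out patients of each
   arm. *External*: the EVIDENT-analogue cohort is reserved entirely for
   testing; the other two cohorts form the training set, enlarged by
   SMOTE-style oversampling to roughly a 4:1 train:test balance.
5. **Surrogate tree.** The recommendation policy is distilled into a CART
   classifier (implemented from scratch) with a bespoke stopping rule:
   a node becomes a leaf when its Gini impurity is ≤ 0.20, at depth 10, or
   when no split strictly reduces weighted impurity. Fidelity is the
   fraction of patients on which the tree reproduces the ensemble's
   recommendation; rendering is truncated to 5 levels by default.

## Synthetic cohort generator

No patient-level data ship with the package; the generator produces
cohorts with the structure the analysis assumes, plus the ground truth
needed to test recovery:

* **Covariates.** 64 features (demographics, lifestyle, medication flags,
  anthropometry, hemodynamics, biochemistry) drawn independently —
  truncated Gaussians for continuous variables (the location parameter is
  solved so the *truncated* mean equals the catalogue mean), Bernoulli
  for binary flags, rounded truncated Gaussians for counts — at the
  pooled-sample marginal moments. Independence is a deliberate
  simplification: real covariates are correlated, so passing tests show
  pipeline correctness under the assumed marginal structure, not
  performance on real data.
* **Assignment.** Multinomial over the six classes at the observed pooled
  proportions (44/47/17/14/28/44 of 194); an optional `other_share` routes
  mass to a pooled rare-drug class exercised by the eligibility filter.
  Cohort labels are drawn at the observed three-study split (≈29/29/42%).
* **Effects.** Each arm's true effect is a linear index over four
  effect-modifier covariates matching the top of that arm's importance
  ordering (e.g. ACEI: weight, HbA1c; ARB: baseline cfPWV, LDL),
  with standardized coefficients (0.6, 0.4, 0.2, 0.1) and a common
  intercept of 0.5 m/s. Equal intercepts make the recommendation problem
  a pure effect-modification problem: no arm dominates on average. On the
  raw scale, follow-up = baseline − g_d(x) − ε per modality with
  independent Gaussian ε.
* **Noise.** The reference noise level is noise_sd = 0.25 × effect
  spread, where the effect spread is the per-arm SD of the linear index
  (√Σc² ≈ 0.755 m/s), i.e. ≈ 0.19 m/s per modality.
* **Missingness.** Covariate cells can be masked MCAR at a configurable
  rate; PWV fields (including the two baseline PWV covariates) and the
  drug assignment are never masked.
* **Ground truth.** The `SyntheticTruth` sidecar carries the effect
  functions, the noise SD, and yields the oracle policy
  argmax_d g_d(x) for any patient, so policy recovery is measurable.

One unresolved point in the source design is which arm's outcome vector a
patient who switched drugs during follow-up should enter; the generator
assigns exactly one drug per patient and does not model switching.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| `n_trees` | 300 | importance forest; studies use 50 (see below) |
| `n_trees_reduced` | = `n_trees` | reduced refit; studies use 300 |
| `max_features` | 1/3 | regression convention for the full forest |
| `max_features_reduced` | = `max_features` | studies use 1.0 (plain bagging on 10 features predicts better at small arm sizes) |
| `k_features` | 10 | features kept per arm |
| `importance` | consensus | mean of MDI and permutation ranks; ties → lower MDI rank, then name |
| `n_repeats` | 10 | permutation repetitions (squared-error loss, training partition) |
| `min_group_size` | 10 | exclusive eligibility threshold (a class of exactly 10 is kept) |
| `train_frac` | 0.8 | internal holdout |
| `k_neighbors` | 5 | SMOTE |
| `max_depth`, `gini_stop` | 10, 0.20 | surrogate tree |

## Numerical and design choices

* **Median imputation** uses the observed-value median (midpoint
  convention); binary covariates use the same rule. Outcome PWV is never
  imputed — patients with missing follow-up are dropped and logged,
  because imputing a target leaks.
* **Holdout split** apportions the training quota over drug classes by
  largest remainder, so |train| = round(0.8·n) while every class with ≥2
  patients appears in both folds; a single-patient class goes to training
  with a warning. Feature selection runs inside the training fold only.
* **SMOTE for regression.** SMOTE is a classification device; here the
  drug class is the class label and interpolation acts on the joint
  (features, target) vector with u ~ Uniform[0,1], so synthetic targets
  stay consistent with the local feature–outcome relationship. Distances
  are Euclidean on z-scored features; binary features are re-thresholded
  at 0.5; every synthetic row records its parents and u, making convexity
  and class purity exhaustively auditable. Interpolating the target
  (rather than copying the seed's) is an interpretation choice.
* **Surrogate splits** use midpoints between consecutive sorted unique
  values; candidate comparison and the strict-gain condition are computed
  in exact integer arithmetic (score A/(n_l·n_r) compared by
  cross-multiplication), so tie-breaking — lower feature index, then
  lower threshold — never depends on floating-point rounding. The tree is
  trained on all 64 covariates (not only the selected union), and
  fidelity is reported both in-sample and on held-out recommendations.
* **Metrics.** R² = 1 − SS_res/SS_tot with the test-set mean; undefined
  (and reported as such, not raised through the report) for empty or
  constant-target test arms. MSE is always defined.
* **Determinism.** All randomness (generation, splits, forests,
  permutation shuffles, SMOTE) derives from one master seed via
  `numpy` seed sequences; two runs with the same seed serialize to
  byte-identical reports.

## Simulation studies

The studies in `pwvrec.experiments` train on a freshly generated cohort
of n = 2000 (assignment at the observed arm proportions, so the smallest
arm has ≈ 145 patients) and score recovery on an independent evaluation
cohort of 1000 patients, over 10 derived seeds:

* *Policy recovery*: oracle-policy agreement at the reference noise
  level.
* *Counterfactual recovery*: per-arm R² between predictions and the true
  g_d mapped to the standardized scale, at noise_sd ∈ {0, 0.5, 1.0} m/s,
  plus the oracle agreement at each level.
* *Feature selection*: a single arm of n = 2000 whose outcome depends on
  10 informative covariates (coefficients 1.0 … 0.1) with 54 pure-noise
  covariates; counts informative features in the selected top 10.
* *Cohort shift*: continuous covariate means of the external-validation
  cohort shifted by 0.5 SD; compares mean internal vs external R² at
  n = 1000.

Study runs use 50 importance trees, 5 permutation repeats scored on at
most 256 subsampled rows, and a 300-tree reduced refit without feature
subsampling — recovery at these sample sizes is insensitive to heavier
settings, and a full four-study battery completes in minutes on one core.
The pipeline defaults remain the heavier settings in the table above.

## Limitations

* Independent covariates and linear effect indices are idealizations; the
  studies certify the pipeline's machinery (selection, per-arm fitting,
  argmax, augmentation, distillation), not clinical performance.
* Random-forest regression shrinks predictions toward each arm's mean at
  small arm sizes, which is the main source of residual policy
  disagreement near effect ties.
* Counterfactual predictions for patients outside an arm are plain model
  extrapolations; there is no propensity correction, no dose modelling,
  and no multi-visit trajectory modelling.
* R² is reported without confidence intervals; the validation schemes
  report point values per arm.
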
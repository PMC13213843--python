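# Methods

This note documents the models and procedures implemented in `anfiskit`, the
assumptions behind them, and the numerical choices that matter when
reproducing or extending the analysis.

## Synthetic cohort model

The simulator (`anfiskit.cohort`) draws child-assessment records from a
two-group mixture keyed on diagnostic status:

- **Group sizes** are fixed counts, not Bernoulli draws: by default 4,311
  typically developing controls and 689 diagnosed children (prevalence
  13.78%). Fixing the counts makes prevalence-dependent statistics exact by
  construction and removes one source of Monte-Carlo noise. A
  `CohortConfig.from_prevalence(n_total, prevalence)` constructor rounds
  `prevalence * n_total` to the nearest integer for users who prefer to
  specify a proportion.
- **Domain scores** (cognitive, behavioral, motor, social interaction) are
  independent truncated normals on [0, 100] within each group, sampled by
  inverse-CDF (`scipy.stats.truncnorm`), never by clipping — clipping would
  put point masses at the boundaries. Defaults (group 0 vs group 1):
  cognitive 60.86 ± 14.51 vs 51.58 ± 17.09, behavioral 55.82 ± 9.38 vs
  49.64 ± 11.21, motor 51.08 ± 7.79 vs 45.08 ± 8.00, social 51.20 ± 11.66 vs
  42.13 ± 11.19. Truncation shifts the configured means by at most ≈0.15
  score units at these parameters; `truncated_normal_mean` exposes the
  analytic truncated mean so tests can bound this bias rather than absorb it
  into loose tolerances.
- **Family history** is group-conditional Bernoulli (45.0% in controls,
  85.6% in cases), which makes it the strongest single correlate of
  diagnosis (phi ≈ 0.28) and puts the overall positive-history rate near
  50.6%.
- **Sex** is group-conditional Bernoulli on female (51.7% / 48.9%),
  giving ≈51.3% female overall; **age** is discrete uniform on {1,…,6}
  (mean 3.5, SD 1.708), matching the target cohort's printed 3.49 ± 1.72.
- **Independence.** Domains are sampled independently within group. The
  moderate negative point-biserial correlations of each domain with
  diagnosis (−0.21 to −0.26) are therefore *emergent* from the group mean
  differences, not imposed; closed-form predictions
  (`expected_point_biserial`, `expected_phi`) are used as test oracles.
- An optional uniform per-cell `missing_rate` on the domain columns
  exercises the missing-data policy; the default is complete data.

Gaussian-per-group margins are the minimal model consistent with the target
means, SDs and correlations; skewness, site effects, longitudinal structure
and any real inter-domain dependence are deliberately not modelled. Passing
tests on this cohort therefore certify the pipeline's statistical machinery,
not clinical performance on real populations — real assessment data will be
harder (heavier tails, instrument floors/ceilings, correlated domains), and
achievable discrimination on the synthetic cohort (AUC ≈ 0.87) is an honest
consequence of its configured group separation.

## Preprocessing

- **Sex encoding**: male → 0, female → 1, case-sensitive by default with an
  opt-in case-folding toggle. The direction is an arbitrary documented
  choice; sex is not among the 11 model features, so it affects only
  bookkeeping.
- **Missing-data policy**: rows whose fraction of missing cells among the
  key columns (the four domains, age, family history; configurable) exceeds
  10% are dropped; surviving missing cells in any numeric column are
  replaced by the column mean computed over kept rows. Note that with six
  key columns a single missing key cell (16.7%) already exceeds the
  threshold, so under the default key set the imputation path only triggers
  for non-key columns or custom key sets/thresholds. The operation is
  idempotent and logs drop/imputation counts.
- **Scaling**: plain min–max to [0, 1], fitted on the training partition
  only; transform-time values outside the fitted range are clamped to the
  boundary. Clamping (rather than extrapolating) keeps the fuzzification
  layer's domain fixed.
- **Stratified split**: per-class test counts are `round(0.20 × class size)`
  with half rounded away from zero; if per-class rounding drifts from the
  overall target the majority class is adjusted by one. With 4,311/689 this
  yields exactly 862 + 138 = 1,000 test records.

## Feature engineering

The 11 model inputs, in fixed order: 4 raw domains, 4 age-adjusted ratios
(score/age; ages start at 1, so the ratio is always defined), 2 cross-domain
ratios with a +1 denominator guard, and the composite risk
`0.3·(100−C) + 0.2·(100−B) + 0.2·(100−M) + 0.3·(100−S)` times a
family-history multiplier (1.0 for negative history; default 1.25 for
positive, configurable — the worked case below pins down the inversion
`100 − x` and multiplier 1 for negative history, but no reference value
constrains the positive multiplier). All engineered quantities are computed
on the raw 0–100 scale first; the full 11-column matrix is then min–max
normalised. Age, sex and raw family history are not direct model inputs:
family history enters only through the composite risk.

The mutual-information screen discretises each feature into 10 equal-width
bins over its observed range and computes MI (natural log) with the
diagnosis from the joint histogram. Features above 0.01 nats are flagged
`retained`; the classifier nonetheless consumes all 11 features by default,
the screen being a diagnostic rather than a hard filter. For a feature
identical to the label the estimator recovers the label entropy
`−p·ln p − (1−p)·ln(1−p)` exactly (≈0.401 nats at p = 0.138).

## ANFIS classifier

Architecture and training defaults are described in the README. Numerical
choices:

- **Underflow floor** ε = 1e−12 applied to each per-feature membership
  before the 11-way product, which is computed as `exp(Σ log μ)`. The floor
  guarantees `normalize_firing` never divides by zero; a floored membership
  receives zero gradient (clamp semantics).
- **Initialisation**: MF centers at 0, 0.5, 1 per feature with width 0.25
  (substantial overlap); rule antecedents from seeded k-means with 8
  clusters on the training features, each centroid coordinate snapped to the
  nearest MF center, duplicate antecedents perturbed to the next MF on the
  highest-variance feature (a seeded random fallback is available);
  consequent coefficients zero with intercepts ~ N(0, 0.1²) so rules are
  not born identical.
- **Optimisation**: Adam (β₁ = 0.9, β₂ = 0.999) on mean binary
  cross-entropy with analytic gradients for all four parameter groups;
  widths are projected onto σ ≥ 0.01 after every step. Gradients are
  verified against central finite differences at relative 1e−4 in the test
  suite (they agree to ≈1e−7).
- **Early stopping** monitors validation loss on a stratified 20% holdout
  of the training data (strict improvement); the best-epoch weights are
  restored. Training is bit-reproducible from (data, config, seed).
- **First-order Sugeno** consequents (linear in the inputs) are used; the
  classic hybrid least-squares/gradient two-pass scheme is out of scope —
  training is end-to-end gradient descent for all layers.
- The decision threshold is fixed at 0.5 with a strict inequality
  (probability exactly 0.5 predicts negative); no class reweighting is
  applied despite the 13.8% prevalence.

## Evaluation

- Confusion metrics follow the standard definitions; a metric whose
  denominator is zero is reported as `None`, never silently 0.
- **AUC** is trapezoidal integration of the ROC over all distinct score
  thresholds, mathematically equal to the Mann–Whitney concordance
  probability with ties counted ½; tests verify this equivalence against an
  exhaustive pairwise oracle and against scikit-learn.
- **Cross-validation** uses seeded stratified k-fold (k = 5); each fold's
  model is trained from scratch. Fold summaries report the sample SD
  (ddof = 1) and a normal-approximation 95% CI, mean ± 1.96·SD/√k. These
  are different quantities: a printed "± 3.4%" that matches a CI half-width
  corresponds to a fold SD of ≈1.8, and both are reported to avoid the
  ambiguity.
- **Perturbation importance** zeroes one normalised feature column at a
  time (i.e. pins it at its observed training minimum) and records the
  accuracy drop. Tier cutoffs: Dominant ≥ 0.005, High ≥ 0.0025,
  Moderate ≥ 0.001, else Low. On models trained on the synthetic cohort the
  absolute contributions are substantially larger than these cutoffs
  (most features land in "Dominant") because the synthetic signal is
  concentrated; the tiering is kept for comparability of the reporting
  format.

## Clinical reporting

Confidence is `|p − 0.5| / 0.5`, stratified Low (≤ 0.5), Medium
(0.5, 0.8], High (> 0.8); the boundary 0.8 belongs to Medium. Per-domain
linguistic labels take the argmax of the three learned memberships of the
normalised raw score; when the top two memberships differ by less than
0.15 the labels are blended in ascending order ("Medium–High") to express
genuine ambiguity — exact ties always blend. Recommendations come from a
fixed six-entry template table keyed on (prediction, tier); a Low-confidence
result always routes to clinical review regardless of direction.

## Problem sizes and determinism

The test suite trains on a reduced cohort (520 + 80) for model-object,
reporting and CLI tests, and on the full default cohort (4,311 + 689) for
the end-to-end learning check; the acceptance script generates one full
cohort and otherwise does closed-form arithmetic. Every stochastic step —
cohort generation, splitting, validation holdout, k-means, batch shuffling,
intercept initialisation — flows from a single integer seed through
`numpy.random.default_rng`.

## Known limitations

- Within-group domain independence and Gaussian margins are idealisations;
  an optional correlation hook is not implemented beyond the identity
  structure (domains are independent by construction).
- The rule base is small (8 rules over 3¹¹ possible antecedents) and its
  quality depends on the k-means initialisation; no rule pruning or growth
  is performed.
- Binary classification only; no multiclass extension, no Mamdani
  inference, no alternative MF families.
- Confidence is a monotone transform of the predicted probability, not a
  calibrated posterior; tiers are reporting conventions, not decision
  thresholds validated against outcomes.
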
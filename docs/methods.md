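# Methods

## The problem and the controlled formulation

`riskstrat` studies risk stratification in heterogeneous public-health survey
data (clinical/laboratory measurements, ordinal self-report scales, binary
condition indicators) as a *representation* problem rather than an outcome
prediction problem.  No external clinical label is used.  Instead the
pipeline induces its own target:

1. every variable is harmonized into a numeric risk signal `s_j`;
2. a continuous risk index is built as a direction-signed linear combination
   of the signals, `score_i = Σ_j w_j d_j s_ij`, with `d_j ∈ {−1, 0, +1}`
   declared per variable in the manifest and equal weights `w_j = 1/p` by
   default;
3. the index is discretized into `K = 3` ordinal classes at its empirical
   tertiles.

Because the classes are a deterministic function of the index, a trivial
classifier that routes a record's index value through the fitted quantile
edges reconstructs the labels perfectly on the partition the edges were
fitted on.  All model metrics must therefore be read as measures of how well
a model family approximates the induced class geometry, not as predictive
performance.  The trivial baseline is reported precisely to make that
explicit.

## Harmonization

* **Validation.**  Exact duplicate rows (after string normalization) are
  removed; per-variable sentinel/refusal codes are masked to missing;
  continuous values outside the manifest's plausibility range are set to
  missing.  Counts of each action are reported.
* **Missingness filter.**  A variable is excluded iff its missing fraction
  strictly exceeds `τ_m` (default 0.3); the boundary value is retained.
* **Imputation, then standardization.**  Continuous variables are imputed
  with the fit-data median and then standardized `z = (x − μ)/σ` with the
  *population* standard deviation (ddof = 0) computed on the completed
  column.  The ordering (impute first, then estimate moments) guarantees a
  complete matrix feeds the standardization and keeps a single code path;
  the convention is recorded in `transform_params`.  A zero-variance column
  is emitted as constant 0 with a flag rather than an error.
* **Encoding.**  Ordinal variables map to consecutive integers preserving
  their order; binary variables map to 0/1 indicators; nominal variables
  (defensive path, not used by the shipped generator) expand to one
  indicator per non-reference level with the most frequent level as
  reference.  Mode imputation resolves ties toward the smallest encoded
  value, which keeps the pipeline seed-free and deterministic.
* **Fit/apply separation.**  `apply_transform` projects new records with the
  stored statistics and never re-estimates anything; unknown categorical
  codes at apply time are treated as missing and mode-imputed.

## The hybrid model

Two base classifiers with complementary inductive biases are fitted on the
signal space: a multinomial logistic regression (L2, `max_iter = 3000`,
regularization strength chosen from `C ∈ {0.01, 0.1, 1, 10}` by 5-fold
cross-validated macro-F1) and a random forest (500 trees, minimum leaf size
3, seeded).  Their class-probability outputs are combined convexly,

    R(x) = w · f_lin(x) + (1 − w) · f_rf(x),  0 ≤ w ≤ 1,

with `w` selected on the grid {0.0, 0.1, …, 1.0} by 5-fold cross-validation
on the training partition.  The validation criterion is mean multiclass
cross-entropy of the combined probabilities; macro-F1 per candidate is
recorded alongside.  Ties go to the candidate with the larger nonlinear
share.  After the search both base models are retrained on the full training
partition.

Implementation note: for each fold the base models are fitted once and all
grid candidates are scored on the fold's probability matrices — identical to
refitting per candidate, since base-model fits do not depend on `w`.  The
logistic `C` is likewise pinned once on the full training partition before
the weight search.

The continuous representation used by correlation and attribution
diagnostics is the expected ordinal class under the combined distribution,
`R(x) = Σ_c c · p_c(x)`.  Argmax ties in class prediction resolve to the
lower class.

Data are split 70/30 with stratification by the induced class; a stratified
5-fold plan on the training partition drives both the weight search and the
stability analysis.  The evaluation partition is never visible to any
fitting step.  The risk index and its classes are computed once on the full
cohort *before* partitioning (the target stays fixed); harmonization
statistics used for modeling are then re-fitted on the training partition
alone and applied to the test partition.

## Attribution and perturbation sensitivity

Per-record contributions use one-at-a-time reference replacement:
`Φ_j(x) = R(x) − R(x with x_j := reference_j)`, where the reference is the
training-set median of the transformed signal (continuous) or mode
(categorical).  The computation is deterministic — no coalition sampling, no
RNG — and is *not* a Shapley scheme: for nonlinear models the `Φ_j` do not
generally sum to `R(x) − R0` (they do in the linear limit, which is what the
test suite asserts).  Dataset-level importance is the mean absolute
contribution per signal normalized to sum to one; normalization is
per-dataset, so magnitudes are not comparable across cohorts.

Directional sensitivity applies a semantically sized push per target —
+1 SD on the standardized scale for continuous signals, switch-on for
binary, +1 level capped at the top level for ordinal — and tabulates mean
|ΔR| plus the fractions of strictly positive, strictly negative and zero
changes (zeros are tracked separately rather than folded into either sign).

## Evaluation and stability

Accuracy, macro precision/recall/F1 (unweighted over classes present in the
truth; a class with no predictions contributes precision 0 with a warning)
and macro one-vs-rest ROC-AUC on predicted probabilities, plus a
row-normalized confusion matrix.  Representation coherence is
Pearson/Spearman correlation between `R(x)` and the risk index
(average-rank ties).  Stability reports the mean and *sample* standard
deviation (ddof = 1) of each metric over the 5 training-partition folds,
and the log distance to the optimum `log10(1 − m)`; a saturated fold
(`1 − m < 10⁻⁶`) is capped at −6 and flagged.  Fold metrics are always
computed on fold-validation parts within the training partition, never on
the test partition.

## The synthetic cohort generator

The generator emulates the structure of public-health survey extracts, not
their marginals.  One latent risk factor `u ~ N(0,1)` drives every signal:
continuous signals are `loading·u + noise` rescaled to plausible clinical
ranges (glucose-like, blood-pressure-like, BMI-like, …); ordinal signals cut
the same latent construction at its quartiles into survey codes 1–4; binary
signals threshold it at the 60th percentile with survey coding 1 = yes /
2 = no.  Defaults: loading magnitude 0.8, noise SD 0.5, MCAR missingness at
rate 0.05 per variable — a moderate signal-to-noise regime in which the
index recovers the latent strongly but not perfectly, as in real survey
composites.  Every fourth signal is negatively loaded so that
direction-handling is always exercised.  Three archetypes mirror typical
dataset compositions: `clinical` (6 continuous / 0 ordinal / 5 binary),
`behavioral` (2/4/3) and `integrated` (2/3/4).

Ground truth (`u`, the planted score, loadings, missingness mask) is
returned for recovery tests.  With `nonlinearity="threshold"` the planted
score adds a gain-1.2 jump when exactly one of two key standardized signals
exceeds 0.4 — a combination of threshold effects that no single hyperplane
can represent, so tertiles of the planted score separate the linear and
nonlinear model families by construction.  (Single monotone step effects
turn out to be largely approximable by a logistic plane; the XOR-of-steps
form makes the gap structural rather than marginal.)
`nonlinearity="interaction"` instead adds gain-1.2 pairwise products of
standardized signals.  In both cases the emitted table is unchanged; only
the planted score's geometry differs.

What passing tests on these cohorts do **not** show: robustness to
informative missingness (the generator is MCAR only), to multi-factor risk
structure (single latent by default), to survey design features (weights,
strata), or to the marginal distributions of any real survey.

## Numerical and design choices

* Quantile edges use linear order-statistic interpolation at `k/K`; a score
  exactly on an edge falls in the *lower* class.  With a tie-free index and
  `n` divisible by `K`, classes are exactly balanced.
* The risk index is unnormalized; any strictly increasing transform of it
  induces identical classes.
* A constant risk index (or heavily tied edges) raises an error suggesting
  inspection of the index construction rather than silently producing
  degenerate classes.
* All randomness flows from one top-level seed, fanned out to the split,
  the fold plan and the forest; reruns with the same configuration are
  bit-stable given fixed library versions.
* The optional binary outcome path `y = I(z_k > τ)` (strict inequality)
  reads raw, untransformed clinical values only and is disabled unless a
  variable and threshold are configured; it never drives training.

## Problem sizes used by the reproduction experiments

The shipped experiments run at desk scale: baseline reconstruction at
n = 3000; latent recovery at n = 5000 with the full model configuration;
the threshold-nonlinearity gap over 20 seeds at n = 2000; the fold-dispersion
contrast over 20 seeds at n = 1500 (integrated) versus n = 500 (clinical),
using the linear base model whose fold variance is the cleaner size probe.
These sizes were chosen so each structural effect is comfortably resolved
while a full run stays in the minutes range on one CPU.

## Known limitations

* The induced classes are a construct of the index; nothing here validates
  clinical risk, and attribution describes the model's internal organization
  only (no causal reading).
* The equal-weight index is the simplest defensible construction; index
  weights are configuration, and conclusions can shift under a different
  index.
* Probabilities are not calibrated; the convex combination preserves
  row-stochasticity but not calibration.
* Nominal multi-level encoding is a defensive path exercised only by unit
  tests, not by the shipped generator.
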
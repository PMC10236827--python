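# Methods

## Problem setting

Per-assay binary classification of compound bioactivity from two feature
spaces: hashed circular fingerprints (binary, radius 2, 2048 bits by
default) and morphological profiles from high-content imaging
(continuous, plate-normalised upstream). Assay hit-call tables are sparse
— a compound is only labelled for the assays in which it was measured —
and imbalanced, with inactives usually the majority.

## Data preparation

**Profile aggregation.** Well-level profiles are reduced to one vector per
compound in two steps. First, the mean feature vector of each plate's
neutral (DMSO-type) control wells is subtracted from every treated well on
that plate, cancelling additive plate effects. Second, when a compound was
measured at several doses, the feature-wise median is taken over the
replicate rows whose dose lies within one standard deviation of the
compound's mean dose. The standard deviation is the sample (n−1) estimate
and the window is inclusive on both ends; these conventions are choices —
population sd or open intervals would be equally defensible — and are
fixed here for determinism. Single-dose compounds pass through unchanged.

**Morphology feature selection** (fitted on the training split only, then
applied to held-out compounds): (1) remove blocklisted feature names
(user-supplied text file; known-noisy features), (2) drop features with
population variance ≤ 0.005, (3) greedily prune correlated pairs: while
any surviving pair has |Pearson r| > 0.9, drop the offending feature with
the largest sum of absolute correlations to all survivors, ties dropping
the later column; (4) drop features whose maximum absolute value exceeds
15. Correlation with a zero-variance feature is defined as 0, never NaN.
The greedy loop terminates because every iteration removes one feature,
and the survivor set provably contains no offending pair (an exhaustive
pair scan verifies this in the tests). Fitting selection on the training
split rather than the full dataset sacrifices a little statistical
efficiency to guarantee that no held-out information leaks into the
feature set.

**Fingerprint bit selection.** Bits whose Bernoulli variance p(1−p)
(population variance on training rows) is ≤ 0.05 are dropped as
near-constant.

**Dataset assembly.** Per assay, compounds must be present in both feature
matrices; assays whose minority class has fewer than `min_minority`
compounds (default 100) are discarded; the majority class — identified by
size, not label — is undersampled without replacement to at most 3× the
minority count. Minority compounds are never removed. The train/test
split is 80/20, stratified on the hit call. All sampling is driven by
per-stage seeds derived from one run seed.

## Calibrated base models

The base learner is a random forest (pluggable behind a
fit/predict-probability contract). Hyperparameters are chosen by
randomized search (20 draws by default from trees {100, 300, 500}, depth
{∞, 10, 20}, minimum leaf {1, 3, 5}, feature subsampling {sqrt, 0.3},
class weighting {none, balanced}) scored by mean stratified-CV AUC; AUC is
used because it is the workflow's headline metric and threshold-free. A
single-candidate space short-circuits the search, which is how the
desk-scale benchmark keeps its runtime down.

**Youden calibration.** The decision threshold maximises J = TPR − FPR
over the unique values of the cross-validated predicted probabilities,
with calls made by p ≥ t. Ties take the smallest threshold (the most
sensitive of the equally good options); the threshold is clamped into
(10⁻⁶, 1−10⁻⁶) so the rescaling below is always well-defined.
Probabilities are then rescaled piecewise-linearly so t ↦ 0.50 with
endpoints fixed; the map is strictly increasing, so rank metrics are
unchanged and thresholding at 0.50 post-rescale reproduces p ≥ t exactly.

## Nested cross-validation stacking

The training split is divided into five stratified outer folds. For each
fold, both base models are tuned, threshold-calibrated (on inner-CV
predictions) and fitted using only the other four folds, then predict the
held-aside fold on the rescaled axis. Each held-aside compound also
receives similarity scores computed only against the actives of the other
four folds: the mean Tanimoto similarity of its 5 most similar actives
(s_struct ∈ [0, 1]) and the median Pearson correlation of its 5 most
positively correlated actives (s_morph ∈ [−1, 1]). With fewer than 5
actives the statistic runs over all of them — small synthetic assays would
otherwise be undefined. Per-fold thresholds are used for that fold's
rescaling, since the optimum genuinely differs between folds. The
concatenated out-of-fold table covers every training compound exactly
once, and no feature recorded for a compound depends on any label in its
own fold (asserted by a sentinel test that corrupts one fold's labels).

Similarity is computed on the selected feature sets, consistent with what
the models consume. Both scores are functions of the value multiset only,
so they are invariant to active-set ordering; the Tanimoto of two empty
fingerprints is defined as 0.

## Fusion schemes

* **Soft-voting ensemble**: mean of the two rescaled probabilities,
  thresholded at 0.50. No parameters.
* **Hierarchical model**: a second-level random forest on the two
  out-of-fold probabilities, estimator count tuned over
  {100, 300, 400, 500} × class weighting by seeded stratified fivefold CV.
* **Similarity-based merger**: logistic regression (L2 penalty, C = 1,
  balanced class weights) on the four features (two probabilities, two
  similarity scores) versus the training hit calls. Features are used raw
  — all live on comparable O(1) scales — so coefficients remain
  interpretable and are exported in the run manifest. Prediction
  evaluates the logistic link from the stored coefficients directly.

Ties at probability 0.50 are called active everywhere, matching the base
learners' p ≥ t rule.

## Evaluation

Precision, sensitivity and specificity are reported for the active class,
F1 for the minority class, plus balanced accuracy, MCC and AUC. AUC uses
the Mann–Whitney rank statistic with midrank tie handling, making it
exactly invariant under strictly monotone probability transforms (so pre-
and post-rescale probabilities give identical AUC). Cross-assay model
comparisons use a two-sided paired t-test, including an assay only if at
least one of the two models achieved balanced accuracy > 0.50 and minority
F1 > 0; zero-variance differences raise rather than returning a
meaningless statistic. The applicability-domain analysis bins held-out
compounds by similarity score into width-0.1 half-open bins ([0, 1] for
structural, [−1, 1] for morphological), the top bin closed so a score of
exactly 1.0 is counted once; empty bins are emitted with n = 0.

## Synthetic benchmark

The generator emulates the statistical structure of the real inputs, not
their chemistry or biology. Compounds are noisy copies of sparse scaffold
prototypes (per-bit on-probability 0.1, per-bit flip probability 0.02 by
default); morphology is Gaussian noise (sd 0.5) plus, for signalled
actives, a fixed signature of unit magnitude on a random sixth of the
features — a compact, organelle-like response rather than a diffuse shift,
which is also what a tree learner can realistically exploit. Defaults:
400 compounds, 256 bits, 60 morphology features, 10 scaffolds, 25%
active.

Signal modes: *structure* (activity = membership of designated scaffolds,
morphology uninformative), *morphology* (labels independent of scaffold,
signature in morphology only), *complementary* (half the actives occupy
exclusive scaffolds with no signature; the other half carry the signature
on background scaffolds). In complementary mode neither single space can
rank more than its own half of the actives, capping each individual model
near 0.75 AUC on average, while fusion can recover both halves — the
desk-scale analogue of the synergy the method is designed for. A
well-level generator with additive plate offsets and dose replicates
exercises the aggregation path; with zero noise the aggregated profile
recovers the latent profile exactly.

What passing these benchmarks does *not* show: real Cell Painting features
are heavy-tailed, correlated in blocks and batch-confounded, real
fingerprints share substructure across scaffolds, and real assay signal is
far weaker and noisier than the generator's. The synthetic results
validate the machinery and its contracts, not expected performance on
experimental data.

## Problem sizes and determinism

The benchmark harness runs 10 seeds per mode with the single-candidate
hyperparameter space (100 trees, balanced class weights); the dominance
comparison fits only the two individual models since that is all it needs.
One integer seed drives every stochastic stage through per-stage derived
seeds (seed × 1 000 003 + CRC32(stage), mod 2³¹−1), so two runs with the
same configuration produce byte-identical prediction files.

## Known limitations

* Single-label-per-assay modelling; no multi-task sharing across assays.
* The logistic merger is linear in its four features; it reweights the
  base models globally rather than gating them per similarity region.
* Probability calibration beyond Youden rescaling (isotonic/Platt) and
  alternative similarity kernels (cosine, Dice) are deliberate non-goals.
* With the default regularized merger (C = 1), replicating training
  rows shifts coefficients slightly (the penalty does not scale with the
  data); exact replication invariance holds only in the unregularized
  limit.
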
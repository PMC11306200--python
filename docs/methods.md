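# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `fairspeech`, in the package's own terms.

## Audited pipelines

**Anxiety regression (Study-1 style).** One row per audio file; features
are the file-averaged F0 (semitones from 27.5 Hz), loudness (openSMILE
units, treated as unitless), local jitter and local shimmer; the outcome is
a continuous self-reported anxiety score (SAE scale, treated as unbounded).
The model is ordinary least squares with intercept, evaluated
leave-one-speaker-out so no speaker contributes to their own predictions.
No feature standardization is applied before OLS (with an intercept the fit
is scale-equivariant) and predictions are not clipped to the observed score
range. Relative error is averaged per file, not per speaker, before group
aggregation. The audit is deterministic: no randomness enters anywhere.

**Depression classification (Study-2 style).** One row per utterance with
88 eGeMAPS-style features; labels live at the participant level (PHQ-8,
binarized at the strict threshold > 9). Utterances inherit their
participant's binary label for training — the only consistent reading when
training on utterances but labelling participants. Decisions are taken per
participant as the maximum positive-class probability over their
utterances, thresholded at 0.5; at a fixed threshold this equals "any
utterance positive", which the tests assert. Cross-validation shuffles
participants with the run seed and cuts contiguous folds of 10 (last fold
smaller); no stratification by default (a stratified option exists). Class
imbalance is left as-is: no re-weighting.

## Statistical primitives

- **Two-way ANOVA** uses Type-II sums of squares for the unbalanced
  2 × 3 design — insensitive to factor order, the conventional default
  when the interaction is not the primary question; Type III is exposed.
  The implementation delegates to statsmodels OLS/anova_lm; tests verify
  it against an independent nested-least-squares oracle to 1e-9.
- **Post-hoc t-tests** are pooled-variance Student tests
  (df = nA + nB − 2), uncorrected by default; a Bonferroni multiplier is
  exposed but off, matching the uncorrected post-hoc reporting convention
  the audit follows. With 21 vs 75 files the printed df is t(94).
- **Two-proportion Z-test** uses the pooled-variance form with a two-sided
  normal p-value; the degenerate pooled proportions 0 and 1 raise instead
  of returning ±inf.
- **Rankings** break ties lexicographically on feature name so results are
  invariant to input column order. Constant features are given the
  least-interesting criterion value (p = 1 / r = 0) with a warning rather
  than an error, since a constant column carries no group evidence.

## Synthetic cohort generators

The generators emulate the statistical structure the audits assume, not
raw audio. Features are conditionally Gaussian given the demographic cell —
the minimal assumption when only per-group means and SDs are specified;
jitter and shimmer are redrawn while negative. The anxiety generator's
default cell sizes, feature moments and outcome moments are the package's
reference cohort (229 files, 30 speakers, six gender × race cells). By
default features and outcome are conditionally independent given the cell;
an "anxiety-coupled" preset adds coupling 0.3 between the score and the
standardized F0/jitter deviations so that regression-recovery tests have
planted signal of a plausible within-group effect size.

The depression generator draws PHQ-8 per gender from Gaussian moments
(7.43 ± 6.12 female, 5.59 ± 4.72 male), rounds to integers, clips to
[0, 27], then moves boundary scores across the >9 threshold until the
binarized counts are exactly 17/44 and 14/63 — the downstream
predicted-positive-rate Z-tests need the base rates as hard counts, and
boundary adjustment perturbs the moments far less than rejection sampling.
Utterance counts per participant follow a shifted Poisson (minimum 5, mean
158, totalling ≈ 16,906 over 107 participants); only the total is a known
quantity, the per-participant distribution is a declared choice. Utterance
features are unit-variance Gaussian noise plus configurable mean shifts:
1.0 SD on 10 features for female speakers and 0.8 SD on 10 partially
overlapping features for depressed speakers by default. The overlap (5 of
10) mirrors, at desk scale, the empirical entanglement of gender- and
depression-informative acoustics that motivates debiasing. What the
generators do **not** model: within-utterance temporal structure, speaker-
specific feature offsets beyond the group mean, non-Gaussian feature
marginals, accent effects, and any realistic eGeMAPS covariance structure.
Passing tests therefore demonstrate that the machinery is correct and
calibrated under these idealized conditions, not that the audit's
conclusions transfer to any particular real corpus.

## Adversarial autoencoder

Architecture reading: "two hidden layers of 256 and 128" is interpreted as
encoder hidden width 256 and decoder hidden width 128, with a configurable
bottleneck defaulting to the input dimensionality; the transformed feature
vector is the reconstruction output, so the post-transform feature-
selection grid can extend to all 88 columns. The combined objective is
reconstruction MSE + λ_d·CE(depression) − λ_g·CE(gender), λ_d = λ_g = 1,
Adam at 1e-4, 50 epochs, minibatch 32, no early stopping.

The gender term is implemented by gradient reversal, and one detail
matters: the adversary head must stay near-optimal, otherwise the encoder
learns to make the representation *anti*-predictive for a stale adversary —
confidently wrong logits still expose the attribute to a freshly trained
probe, and leakage can even increase. The gender head therefore gets its
own optimizer (1e-3, ten times the main rate) and several catch-up steps
per main update, and the reversed gradient is computed against the
refreshed head. With this schedule the residual gender-probe AUC decreases
monotonically in λ_g on planted-effect cohorts, which the tests check.

Transformers and rankings are always fitted on the training fold only and
applied to that fold's held-out rows; fitting on pooled data would leak
test information into the representation.

## Classifier training

The utterance classifier (input → 32 → 32 → 2 softmax, cross-entropy,
Adam 1e-3, ≤ 100 epochs, minibatch 32) early-stops on a held-out 10% of
*training participants* (patience 10, best-epoch weights restored);
holding out utterances of seen speakers would let speaker identity tune
the stopping point. The decision threshold is fixed at 0.5. All training
is seeded and bit-reproducible; per-fold seeds are derived from the run
seed.

## Numerical and degenerate-input choices

- Rank-deficient OLS folds fall back to the minimum-norm solution with a
  warning rather than failing.
- A constant ANOVA response returns F = 0, p = 1 for all effects.
- EO is reported unclamped (it can drop below 0 for metric gaps above 1).
- TPR is reported as missing, with a warning, for a gender with zero
  actual positives; EO is then undefined.
- Standardization leaves zero-variance columns unscaled.

## Problem sizes

Simulation-heavy checks run at desk scale, chosen to keep the full suite
fast while leaving the planted effects comfortably detectable: calibration
and recovery use cohorts of 60 participants × ~40 utterances × 20 features
(null calibration: 20 seeds; ranking recovery: 100 seeds), and the
adversarial leakage property uses 40 participants × ~20 utterances × 15
features with a 64/32-width network over 50 seeds. The reference-statistic
reproductions (Z-tests, EO arithmetic, base rates) are exact and
instantaneous at their published counts.

## Known limitations

- The anxiety ANOVA treats the 229 files from 30 speakers as independent
  observations; within-speaker correlation is not modelled. This
  reproduces the audited design choice deliberately rather than "fixing"
  it.
- Gender is modelled as the two audited categories; the schema admits
  more, but the audit operations require exactly two groups.
- The audit quantifies group-level error parity, not individual fairness,
  and a synthetic pass is a statement about the machinery, not about any
  clinical population.
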
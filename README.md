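# fairspeech

Demographic-bias auditing and debiasing for speech-based mental-health
models, for researchers who build or evaluate machine-learning systems that
estimate anxiety or detect depression from acoustic features and need to
know whether those systems treat demographic groups differently.

Speech carries both clinical state (anxiety, depression) and speaker traits
(gender, race/ethnicity). A model trained on acoustic features can therefore
perform unevenly across groups, or silently encode demography into its
decisions. `fairspeech` audits both failure modes on tabular acoustic
cohorts and implements two mitigation strategies, with synthetic cohort
generators so the full pipeline is testable without restricted clinical
corpora.

## What it computes

**Regression audit (anxiety).** A leave-one-speaker-out linear regression
from four acoustic measures (F0 on a semitone scale, loudness, jitter,
shimmer) to a continuous self-reported anxiety score. Per demographic group
the mean absolute relative error

    RE(g) = mean over rows in g of |ŷ − y| / |y|

and, for each sensitive group *s* against its non-sensitive reference *ns*
(White same-gender, White, or male):

    EO = 1 − |RE(s) − RE(ns)|

EO = 1 means equal accuracy; smaller values quantify the gap.

**Classification audit (depression).** An utterance-level feedforward
classifier (2 × 32 ReLU units, softmax) with participant-level decisions by
max-aggregating utterance probabilities, evaluated with grouped
cross-validation (folds of 10 participants). Per gender: TPR, TNR, balanced
accuracy BA = (TPR + TNR)/2, predicted positive rate PPR, the
equality-of-opportunity measure EO = 1 − |TPR(male) − TPR(female)|, and a
pooled two-proportion Z-test of each gender's PPR against its base
depression rate (PHQ-8 > 9),

    z = (p̂₁ − p̂₂) / √( p̂(1−p̂)(1/n₁ + 1/n₂) ),  p̂ pooled.

**Label/feature bias statistics.** Unbalanced two-way ANOVA
(gender × race/ethnicity, Type-II sums of squares) with post-hoc pooled
t-tests, plus two feature rankings: gender separability (ascending t-test
p-value) and outcome relevance (descending |Pearson r| with PHQ-8).

**Debiasing.** (1) Remove the M most gender-separable features
(M ∈ {5, 10, 15, 20, 30, 60}); (2) transform features with an adversarial
autoencoder (encoder 256 → bottleneck, decoder 128, ReLU) whose training
objective is reconstruction MSE + λ_d·CE(depression head) −
λ_g·CE(gender head), the gender term realised by gradient reversal; then
optionally keep the K features most relevant to depression
(K ∈ {5, 10, 15, 20, 30, 60, 88}). Linear leakage probes quantify residual
gender/depression decodability as cross-validated AUC.

## Worked example

```python
import fairspeech as fs

# gender difference in depression base rates: 14/63 males vs 17/44 females
z = fs.two_proportion_z(14, 63, 17, 44)
print(z.statistic, z.p_value)      # -1.842  0.066  (not significant at 5%)

# regression fairness from a pair of group relative errors
print(fs.equality_of_opportunity_gap(0.093, 0.077))   # 0.984
```

`python examples/adversarial_debiasing.py` trains the adversarial
transformer on a desk-scale synthetic cohort with planted, overlapping
gender and depression effects and prints:

```
gender     probe AUC: 0.937 (original) -> 0.601 (transformed)
depression probe AUC: 0.929 (original) -> 0.856 (transformed)
```

i.e. gender decodability falls toward chance while the depression signal
survives the transformation. The other scripts in `examples/` walk through
the group statistics, the anxiety audit and the full classification audit
grid, each printing the metrics described above.

## Layout

- `src/fairspeech/cohort.py` — cohort schemas, CSV I/O, PHQ-8 binarization
- `src/fairspeech/simulate.py` — synthetic anxiety/depression cohort generators
- `src/fairspeech/stats.py` — ANOVA, t-tests, Z-test, feature rankings
- `src/fairspeech/anxiety.py` — LOSO regression audit (RE, EO)
- `src/fairspeech/debias.py` — feature removal, adversarial autoencoder, probes
- `src/fairspeech/depression.py` — classification audit (BA, EO, PPR, Z-tests)
- `src/fairspeech/nn.py` — seeded numpy feedforward-network core
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
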
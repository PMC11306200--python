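"""Synthetic cohort generators.

The audits in this package were designed around two public speech corpora
(a public-speaking anxiety corpus and a clinical-interview depression
corpus) whose raw audio cannot be redistributed. These generators emulate
the *statistical structure* those audits assume — group-conditional
Gaussian acoustic moments, group-conditional outcome moments, exact
per-gender depression counts — so that every downstream stage is testable
end to end.

Two generators:

* :func:`generate_anxiety_cohort` — 2 (gender) × 3 (race/ethnicity) cells,
  each with a fixed number of audio files and speakers; four acoustic
  measures drawn from per-cell Gaussians; an SAE anxiety score drawn from
  per-cell Gaussians, optionally coupled to standardized feature
  deviations so that regression-recovery tests have signal to find.
* :func:`generate_depression_cohort` — per-participant PHQ-8 scores with
  exact per-gender depressed counts, and utterance-level features with
  configurable planted gender and depression mean shifts (the two planted
  subsets may overlap, emulating the empirical entanglement of gender- and
  depression-informative acoustics).

Both are bit-deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ANXIETY_FEATURES, PHQ8_THRESHOLD, CohortTable, binarize_phq8
from .errors import ValidationError

# -- Study-1 defaults: per-cell sample sizes and moments ----------------------
# Cells keyed (gender, race). Counts: speakers / audio files per cell;
# feature moments (mean, sd) per acoustic measure; SAE moments per cell.

_CELLS = (
    ("female", "african_american"),
    ("female", "hispanic"),
    ("female", "white"),
    ("male", "african_american"),
    ("male", "hispanic"),
    ("male", "white"),
)

DEFAULT_N_SPEAKERS = {
    ("female", "african_american"): 3,
    ("female", "hispanic"): 2,
    ("female", "white"): 9,
    ("male", "african_american"): 3,
    ("male", "hispanic"): 7,
    ("male", "white"): 6,
}

DEFAULT_N_FILES = {
    ("female", "african_american"): 21,
    ("female", "hispanic"): 11,
    ("female", "white"): 75,
    ("male", "african_american"): 30,
    ("male", "hispanic"): 47,
    ("male", "white"): 45,
}

DEFAULT_FEATURE_MOMENTS = {
    ("female", "african_american"): {
        "f0_semitone": (34.968, 1.636), "loudness": (0.645, 0.293),
        "jitter": (1.094, 0.137), "shimmer": (0.025, 0.005)},
    ("female", "hispanic"): {
        "f0_semitone": (35.800, 1.307), "loudness": (0.335, 0.066),
        "jitter": (1.104, 0.106), "shimmer": (0.025, 0.004)},
    ("female", "white"): {
        "f0_semitone": (36.603, 1.837), "loudness": (0.766, 0.283),
        "jitter": (1.080, 0.115), "shimmer": (0.022, 0.004)},
    ("male", "african_american"): {
        "f0_semitone": (23.776, 2.339), "loudness": (0.689, 0.289),
        "jitter": (1.317, 0.141), "shimmer": (0.024, 0.004)},
    ("male", "hispanic"): {
        "f0_semitone": (26.771, 3.217), "loudness": (0.689, 0.240),
        "jitter": (1.242, 0.138), "shimmer": (0.022, 0.005)},
    ("male", "white"): {
        "f0_semitone": (26.188, 1.757), "loudness": (0.726, 0.248),
        "jitter": (1.178, 0.128), "shimmer": (0.020, 0.002)},
}

DEFAULT_SAE_MOMENTS = {
    ("female", "african_american"): (41.62, 6.95),
    ("female", "hispanic"): (54.73, 6.54),
    ("female", "white"): (49.75, 9.98),
    ("male", "african_american"): (44.33, 9.28),
    ("male", "hispanic"): (56.77, 7.79),
    ("male", "white"): (51.84, 6.39),
}


@dataclass
class AnxietyCohortSpec:
    """Configuration for the 2×3 anxiety cohort generator.

    ``coupling`` maps feature name → linear coefficient tying the SAE score
    to that feature's standardized within-cell deviation: after drawing
    ``sae ~ N(mean, sd)`` per cell, each row's score is shifted by
    ``sd * sum_f coupling[f] * z_f`` where ``z_f`` is the row's z-scored
    feature deviation. The default (no coupling) makes features and outcome
    conditionally independent given the demographic cell.
    """

    n_speakers: dict = field(default_factory=lambda: dict(DEFAULT_N_SPEAKERS))
    n_files: dict = field(default_factory=lambda: dict(DEFAULT_N_FILES))
    feature_moments: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FEATURE_MOMENTS.items()})
    sae_moments: dict = field(default_factory=lambda: dict(DEFAULT_SAE_MOMENTS))
    coupling: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for cell in _CELLS:
            if self.n_files[cell] < self.n_speakers[cell] or self.n_speakers[cell] < 1:
                raise ValidationError(f"cell {cell}: need n_files >= n_speakers >= 1")
            for name, (_, sd) in self.feature_moments[cell].items():
                if sd <= 0:
                    raise ValidationError(f"cell {cell}, feature {name}: sd must be > 0")
            if self.sae_moments[cell][1] <= 0:
                raise ValidationError(f"cell {cell}: sae sd must be > 0")


def anxiety_coupled_spec(strength: float = 0.3, seed: int = 0) -> AnxietyCohortSpec:
    """Preset with the SAE score coupled to F0 and jitter deviations.

    Used by regression-recovery tests: with coupling the acoustic measures
    genuinely carry anxiety information, so a cross-validated regressor
    should beat the global-mean baseline.
    """
    return AnxietyCohortSpec(coupling={"f0_semitone": strength, "jitter": strength}, seed=seed)


def generate_anxiety_cohort(spec: AnxietyCohortSpec | None = None, seed: int | None = None) -> CohortTable:
    """Draw an anxiety cohort with exact per-cell file counts.

    Jitter and shimmer are redrawn while negative (truncation at zero); at
    the default moments this essentially never triggers.
    """
    spec = spec or AnxietyCohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    frames = []
    speaker_counter = 0
    for gender, race in _CELLS:
        cell = (gender, race)
        n = spec.n_files[cell]
        n_spk = spec.n_speakers[cell]
        speakers = [f"S{speaker_counter + i:03d}" for i in range(n_spk)]
        speaker_counter += n_spk
        cols: dict[str, np.ndarray] = {}
        z: dict[str, np.ndarray] = {}
        for name in ANXIETY_FEATURES:
            mean, sd = spec.feature_moments[cell][name]
            draws = rng.normal(mean, sd, size=n)
            if name in ("jitter", "shimmer"):
                bad = draws < 0
                while bad.any():
                    draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                    bad = draws < 0
            cols[name] = draws
            z[name] = (draws - mean) / sd
        sae_mean, sae_sd = spec.sae_moments[cell]
        sae = rng.normal(sae_mean, sae_sd, size=n)
        for name, coef in spec.coupling.items():
            sae = sae + sae_sd * coef * z[name]
        frames.append(pd.DataFrame({
            "speaker_id": [speakers[i % n_spk] for i in range(n)],
            "gender": gender,
            "race_ethnicity": race,
            **cols,
            "sae_score": sae,
        }))
    rows = pd.concat(frames, ignore_index=True)
    return CohortTable(rows=rows, schema_tag="anxiety")


# -- Study-2 generator --------------------------------------------------------

@dataclass
class DepressionCohortSpec:
    """Configuration for the utterance-level depression cohort generator.

    Defaults mirror the reference cohort: 44 female / 63 male participants
    with exactly 17 / 14 depressed; PHQ-8 moments 7.43 ± 6.12 (female) and
    5.59 ± 4.72 (male); 88 acoustic features; utterance counts drawn from a
    shifted Poisson with mean 158 (minimum 5) so totals land near 16,906.

    ``gender_effect`` / ``depression_effect`` map feature index → mean shift
    (in units of ``noise_sd``) added when the participant is female /
    depressed respectively. The default planted subsets overlap on half the
    depression-informative features, emulating the entanglement of gender-
    and depression-related acoustics that motivates the debiasing methods.
    """

    n_female: int = 44
    n_male: int = 63
    depressed_female: int = 17
    depressed_male: int = 14
    phq_moments: dict = field(default_factory=lambda: {"female": (7.43, 6.12), "male": (5.59, 4.72)})
    n_features: int = 88
    utterances_per_participant: int = 158
    min_utterances: int = 5
    gender_effect: dict = field(default_factory=lambda: {i: 1.0 for i in range(10)})
    depression_effect: dict = field(default_factory=lambda: {i: 0.8 for i in range(5, 15)})
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.depressed_female > self.n_female or self.depressed_male > self.n_male:
            raise ValidationError("depressed count exceeds group size")
        if min(self.n_female, self.n_male) < 1 or self.n_features < 1:
            raise ValidationError("group sizes and n_features must be positive")
        for idx in list(self.gender_effect) + list(self.depression_effect):
            if not (0 <= idx < self.n_features):
                raise ValidationError(f"effect index {idx} outside feature range")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


def reduced_depression_spec(
    n_female: int = 26,
    n_male: int = 34,
    utterances_per_participant: int = 40,
    n_features: int = 20,
    seed: int = 0,
    **overrides,
) -> DepressionCohortSpec:
    """A desk-scale cohort (default 60 participants × 40 utterances × 20
    features) preserving the full cohort's depressed fractions (≈38.6% of
    females, ≈22.2% of males). Used for simulation-heavy calibration tests."""
    return DepressionCohortSpec(
        n_female=n_female,
        n_male=n_male,
        depressed_female=int(round(n_female * 17 / 44)),
        depressed_male=int(round(n_male * 14 / 63)),
        n_features=n_features,
        utterances_per_participant=utterances_per_participant,
        seed=seed,
        **overrides,
    )


def _adjust_phq_counts(scores: np.ndarray, target_depressed: int) -> np.ndarray:
    """Move boundary scores across the PHQ-8 threshold until the binarized
    depressed count is exact. Scores nearest the threshold move first, so
    the sample moments are disturbed as little as possible."""
    scores = scores.copy()
    depressed = scores > PHQ8_THRESHOLD
    excess = int(depressed.sum()) - target_depressed
    if excess > 0:  # demote the lowest depressed scores to the threshold
        idx = np.where(depressed)[0]
        order = idx[np.argsort(scores[idx], kind="stable")]
        scores[order[:excess]] = PHQ8_THRESHOLD
    elif excess < 0:  # promote the highest healthy scores just past it
        idx = np.where(~depressed)[0]
        order = idx[np.argsort(-scores[idx], kind="stable")]
        scores[order[:-excess]] = PHQ8_THRESHOLD + 1
    return scores


def generate_depression_cohort(spec: DepressionCohortSpec | None = None, seed: int | None = None) -> CohortTable:
    """Draw a depression cohort with exact per-gender depressed counts.

    PHQ-8 scores are sampled from the gender-conditional Gaussians, rounded
    to integers, clipped to [0, 27], then rank-adjusted so the binarized
    counts equal the spec exactly — the predicted-positive-rate Z-tests
    downstream require the base rates as hard counts, not expectations.
    """
    spec = spec or DepressionCohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    participants = []
    for gender, n, k in (("female", spec.n_female, spec.depressed_female),
                         ("male", spec.n_male, spec.depressed_male)):
        mean, sd = spec.phq_moments[gender]
        raw = np.clip(np.rint(rng.normal(mean, sd, size=n)), 0, 27).astype(int)
        adjusted = _adjust_phq_counts(raw, k)
        for i, score in enumerate(adjusted):
            pid = f"P{gender[0].upper()}{i:03d}"
            participants.append((pid, gender, int(score), binarize_phq8(int(score))))
    labels = pd.DataFrame(participants, columns=["participant_id", "gender", "phq8", "depression_class"])

    feat_names = [f"egemaps_{i + 1:03d}" for i in range(spec.n_features)]
    g_shift = np.zeros(spec.n_features)
    for i, s in spec.gender_effect.items():
        g_shift[i] = s * spec.noise_sd
    d_shift = np.zeros(spec.n_features)
    for i, s in spec.depression_effect.items():
        d_shift[i] = s * spec.noise_sd

    blocks = []
    for _, row in labels.iterrows():
        extra = rng.poisson(max(spec.utterances_per_participant - spec.min_utterances, 0))
        n_utt = spec.min_utterances + int(extra)
        mean_vec = np.zeros(spec.n_features)
        if row["gender"] == "female":
            mean_vec = mean_vec + g_shift
        if row["depression_class"] == "depressed":
            mean_vec = mean_vec + d_shift
        X = rng.normal(0.0, spec.noise_sd, size=(n_utt, spec.n_features)) + mean_vec
        block = pd.DataFrame(X, columns=feat_names)
        block.insert(0, "participant_id", row["participant_id"])
        block.insert(1, "gender", row["gender"])
        blocks.append(block)
    rows = pd.concat(blocks, ignore_index=True)
    return CohortTable(rows=rows, schema_tag="depression",
                       labels=labels[["participant_id", "phq8", "depression_class"]].copy())
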
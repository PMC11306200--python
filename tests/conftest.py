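import numpy as np
import pandas as pd
import pytest

import fairspeech as fs


@pytest.fixture(scope="session")
def anxiety_cohort():
    """Default-moment anxiety cohort (229 files, 30 speakers), seed 7."""
    return fs.generate_anxiety_cohort(fs.AnxietyCohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_depression_cohort():
    """Desk-scale depression cohort with planted, partially overlapping
    gender and depression effects (40 participants x ~20 utterances x 15
    features)."""
    spec = fs.reduced_depression_spec(
        n_female=18, n_male=22, utterances_per_participant=20, n_features=15,
        seed=11,
        gender_effect={i: 1.0 for i in range(5)},
        depression_effect={i: 0.8 for i in range(3, 10)},
    )
    return fs.generate_depression_cohort(spec)


@pytest.fixture()
def utterance_meta():
    """Per-utterance metadata (gender, phq8, depression_class) aligner."""

    def _align(cohort):
        return cohort.rows[["participant_id", "gender"]].merge(
            cohort.labels, on="participant_id"
        )

    return _align
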
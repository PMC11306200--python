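"""Cohort data model and CSV I/O.

Two cohort layouts are supported:

* **anxiety** — one row per recorded audio file: speaker id, gender,
  race/ethnicity, four acoustic measures (F0 on a semitone scale, loudness,
  local jitter, local shimmer) and a continuous self-reported anxiety score
  on the State-Anxiety and Enthusiasm (SAE) scale.
* **depression** — one row per utterance: participant id, gender, and a
  block of eGeMAPS-style acoustic features, accompanied by a per-participant
  label table carrying the PHQ-8 score (0–27) and its binarization
  (depressed iff PHQ-8 > 9).

CSV (UTF-8, ``.`` decimal) is the canonical interchange format; feature
tables in this domain are plain numeric tables and nothing richer is needed.
Missing feature values are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

GENDERS = ("female", "male")
RACE_ETHNICITIES = ("african_american", "hispanic", "white")

#: Study-1 acoustic measures, in canonical column order.
ANXIETY_FEATURES = ("f0_semitone", "loudness", "jitter", "shimmer")

ANXIETY_COLUMNS = ("speaker_id", "gender", "race_ethnicity") + ANXIETY_FEATURES + ("sae_score",)

PHQ8_MIN, PHQ8_MAX = 0, 27
#: Participants with PHQ-8 strictly above this score form the depression class.
PHQ8_THRESHOLD = 9


def binarize_phq8(score: int) -> str:
    """Map a PHQ-8 score to ``"depressed"`` or ``"healthy"``.

    The cut-off is strict: scores of exactly 9 are healthy, 10 and above are
    depressed.

    Raises
    ------
    ValidationError
        If ``score`` lies outside the PHQ-8 range [0, 27].
    """
    if not (PHQ8_MIN <= score <= PHQ8_MAX):
        raise ValidationError(f"PHQ-8 score {score!r} outside [{PHQ8_MIN}, {PHQ8_MAX}]")
    return "depressed" if score > PHQ8_THRESHOLD else "healthy"


def average_utterance_features(utterances: pd.DataFrame, by: str, feature_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Average utterance-level features into one row per file/group.

    Parameters
    ----------
    utterances
        One row per utterance; must contain the grouping column ``by``.
    by
        Column identifying the audio file (or any grouping unit).
    feature_columns
        Columns to average; defaults to every numeric column except ``by``.

    Returns
    -------
    pandas.DataFrame indexed by the group key, one row per group, each
    feature the arithmetic mean over the group's utterances.
    """
    if by not in utterances.columns:
        raise SchemaError(f"grouping column {by!r} not in table")
    if len(utterances) == 0:
        raise ValidationError("empty utterance table")
    if feature_columns is None:
        feature_columns = [c for c in utterances.columns if c != by and pd.api.types.is_numeric_dtype(utterances[c])]
    return utterances.groupby(by, sort=False)[list(feature_columns)].mean()


@dataclass
class CohortTable:
    """A feature table plus (for depression cohorts) a participant label table.

    Attributes
    ----------
    rows
        Per-file (anxiety) or per-utterance (depression) records.
    labels
        Per-participant PHQ-8 labels; ``None`` for anxiety cohorts.
    schema_tag
        ``"anxiety"`` or ``"depression"``.
    """

    rows: pd.DataFrame
    schema_tag: str
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.schema_tag not in ("anxiety", "depression"):
            raise ValidationError(f"unknown schema_tag {self.schema_tag!r}")
        if self.schema_tag == "anxiety":
            _validate_anxiety_rows(self.rows)
        else:
            if self.labels is None:
                raise ValidationError("depression cohort requires a label table")
            _validate_depression(self.rows, self.labels)

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_columns(self) -> list[str]:
        if self.schema_tag == "anxiety":
            return list(ANXIETY_FEATURES)
        reserved = {"participant_id", "gender"}
        return [c for c in self.rows.columns if c not in reserved]

    def feature_matrix(self) -> np.ndarray:
        return self.rows[self.feature_columns].to_numpy(dtype=float)

    @property
    def n_participants(self) -> int:
        key = "speaker_id" if self.schema_tag == "anxiety" else "participant_id"
        return self.rows[key].nunique()

    def base_rates(self) -> dict[str, tuple[int, int]]:
        """Per-gender (depressed count, group size) from the label table."""
        if self.labels is None:
            raise ValidationError("base rates require a depression label table")
        merged = self.labels.merge(
            self.rows[["participant_id", "gender"]].drop_duplicates(), on="participant_id"
        )
        out: dict[str, tuple[int, int]] = {}
        for gender, grp in merged.groupby("gender"):
            out[str(gender)] = (int((grp["depression_class"] == "depressed").sum()), len(grp))
        return out


def _validate_anxiety_rows(rows: pd.DataFrame) -> None:
    missing = [c for c in ANXIETY_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"anxiety cohort missing columns: {missing}")
    bad_gender = set(rows["gender"].unique()) - set(GENDERS)
    if bad_gender:
        raise SchemaError(f"unknown gender categories: {sorted(bad_gender)}")
    bad_race = set(rows["race_ethnicity"].unique()) - set(RACE_ETHNICITIES)
    if bad_race:
        raise SchemaError(f"unknown race/ethnicity categories: {sorted(bad_race)}")
    numeric = list(ANXIETY_FEATURES) + ["sae_score"]
    for col in numeric:
        vals = pd.to_numeric(rows[col], errors="coerce")
        if vals.isna().any():
            row = int(rows.index[vals.isna()][0])
            raise SchemaError(f"non-numeric or missing value in column {col!r}, row {row}")
    if (rows["jitter"] < 0).any() or (rows["shimmer"] < 0).any():
        raise SchemaError("jitter and shimmer must be non-negative")


def _validate_depression(rows: pd.DataFrame, labels: pd.DataFrame) -> None:
    for col in ("participant_id", "gender"):
        if col not in rows.columns:
            raise SchemaError(f"depression cohort missing column {col!r}")
    if "participant_id" not in labels.columns or "phq8" not in labels.columns:
        raise SchemaError("label table requires columns participant_id, phq8")
    feature_cols = [c for c in rows.columns if c not in ("participant_id", "gender")]
    if not feature_cols:
        raise SchemaError("depression cohort has no feature columns")
    feats = rows[feature_cols]
    if feats.isna().any().any():
        col = feats.columns[feats.isna().any()][0]
        raise SchemaError(f"missing feature value in column {col!r}")
    unlabeled = set(rows["participant_id"]) - set(labels["participant_id"])
    if unlabeled:
        raise SchemaError(f"participants without label: {sorted(unlabeled)[:5]}")
    if "depression_class" not in labels.columns:
        labels["depression_class"] = [binarize_phq8(int(s)) for s in labels["phq8"]]


def read_cohort(
    path: str | Path,
    schema_tag: str,
    labels_path: str | Path | None = None,
    allow_extra_columns: bool = False,
) -> CohortTable:
    """Read a cohort from CSV.

    For ``schema_tag="depression"``, ``labels_path`` must point to the
    per-participant PHQ-8 label CSV. Unknown columns raise a
    :class:`SchemaError` unless ``allow_extra_columns`` is set.

    On load the function reports (returns) a validated :class:`CohortTable`;
    the depression base rate per gender is available via
    :meth:`CohortTable.base_rates`.
    """
    rows = pd.read_csv(path)
    if schema_tag == "anxiety":
        extra = [c for c in rows.columns if c not in ANXIETY_COLUMNS]
        if extra and not allow_extra_columns:
            raise SchemaError(f"unexpected columns: {extra}")
        return CohortTable(rows=rows, schema_tag="anxiety")
    if schema_tag == "depression":
        if labels_path is None:
            raise ValidationError("depression cohort requires labels_path")
        labels = pd.read_csv(labels_path)
        for s in labels["phq8"]:
            binarize_phq8(int(s))  # range check, raises on bad score
        labels["depression_class"] = [binarize_phq8(int(s)) for s in labels["phq8"]]
        return CohortTable(rows=rows, schema_tag="depression", labels=labels)
    raise ValidationError(f"unknown schema_tag {schema_tag!r}")


def write_cohort(cohort: CohortTable, path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write a cohort (and, for depression cohorts, its labels) to CSV.

    Values round-trip through :func:`read_cohort` exactly (pandas writes
    full float precision by default).
    """
    cohort.rows.to_csv(path, index=False)
    if cohort.schema_tag == "depression":
        if labels_path is None:
            raise ValidationError("labels_path required to write a depression cohort")
        cohort.labels[["participant_id", "phq8"]].to_csv(labels_path, index=False)
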
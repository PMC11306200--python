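"""Speaker-independent anxiety regression and the regression-fairness audit.

Pipeline: leave-one-speaker-out (LOSO) cross-validation of an ordinary
least-squares regression from the four acoustic measures to the SAE anxiety
score; per-group mean absolute relative error (RE); and the regression form
of equality of opportunity,

    EO = 1 − |RE(sensitive) − RE(non-sensitive)|,

computed for three pairing schemes: each (gender, race) cell against the
White cell of the same gender, each race against White, and female against
male. EO = 1 means the model errs equally on both groups; values below 1
quantify the accuracy gap. No clamping is applied, so EO can in principle
go negative for RE gaps above 1.

The audit is fully deterministic: fold order follows speaker order of first
appearance, predictions follow input row order, and OLS has no seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ANXIETY_FEATURES, CohortTable
from .errors import ValidationError
from .stats import AnovaResult, TestResult, pairwise_t, two_way_anova


@dataclass(frozen=True)
class FoldAssignment:
    """Cross-validation folds over units (speakers or participants).

    ``folds`` is a list of (test_units, train_units); test sets partition
    the unit set and no unit appears in its own training set.
    """

    folds: tuple[tuple[tuple, tuple], ...]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


def loso_folds(cohort: CohortTable) -> FoldAssignment:
    """One fold per speaker: that speaker's files test, everyone else trains."""
    speakers = list(dict.fromkeys(cohort.rows["speaker_id"]))
    if len(speakers) < 2:
        raise ValidationError("leave-one-speaker-out needs >= 2 speakers")
    folds = tuple(
        ((spk,), tuple(s for s in speakers if s != spk)) for spk in speakers
    )
    return FoldAssignment(folds)


def fit_predict_anxiety(cohort: CohortTable, folds: FoldAssignment | None = None) -> np.ndarray:
    """Out-of-fold OLS estimates of the SAE score, aligned with row order.

    Per fold an intercept + 4-coefficient least-squares fit on the training
    rows; ``numpy.linalg.lstsq`` yields the minimum-norm solution, so a
    rank-deficient fold degrades gracefully (with a warning).
    """
    if cohort.schema_tag != "anxiety":
        raise ValidationError("fit_predict_anxiety requires an anxiety cohort")
    folds = folds or loso_folds(cohort)
    X = cohort.rows[list(ANXIETY_FEATURES)].to_numpy(dtype=float)
    y = cohort.rows["sae_score"].to_numpy(dtype=float)
    speaker = cohort.rows["speaker_id"].to_numpy()
    design = np.column_stack([np.ones(len(X)), X])

    estimates = np.full(len(y), np.nan)
    for test_units, train_units in folds:
        test_mask = np.isin(speaker, test_units)
        train_mask = np.isin(speaker, train_units)
        coef, _, rank, _ = np.linalg.lstsq(design[train_mask], y[train_mask], rcond=None)
        if rank < design.shape[1]:
            import warnings

            warnings.warn("rank-deficient design in a fold; using minimum-norm fit", stacklevel=2)
        estimates[test_mask] = design[test_mask] @ coef
    if np.isnan(estimates).any():
        raise ValidationError("folds do not cover every row")
    return estimates


def group_relative_error(actual: np.ndarray, estimated: np.ndarray, groups) -> dict:
    """Mean absolute relative error |ŷ − y| / |y| per group label."""
    actual = np.asarray(actual, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    groups = np.asarray(groups)
    if not (len(actual) == len(estimated) == len(groups)):
        raise ValidationError("actual, estimated and groups must align")
    if (actual == 0).any():
        raise ValidationError("relative error undefined for actual == 0")
    re = np.abs(estimated - actual) / np.abs(actual)
    return {g: float(re[groups == g].mean()) for g in dict.fromkeys(groups.tolist())}


def equality_of_opportunity_gap(metric_sensitive: float, metric_nonsensitive: float) -> float:
    """Regression equality of opportunity: 1 − |gap| between group metrics."""
    if not (np.isfinite(metric_sensitive) and np.isfinite(metric_nonsensitive)):
        raise ValidationError("EO requires finite group metrics")
    return 1.0 - abs(metric_sensitive - metric_nonsensitive)


@dataclass
class RegressionAuditReport:
    """Study-1 audit output.

    ``group_stats`` holds mean/sd of actual and estimated anxiety per
    (gender, race) cell; ``re`` maps group key → relative error for all
    three granularities; ``eo`` maps sensitive group key → (EO value,
    non-sensitive reference key); ``anova`` / ``posthoc`` re-run the label
    bias analysis on the model's estimates.
    """

    group_stats: pd.DataFrame
    re: dict
    eo: dict
    anova: dict[str, AnovaResult]
    posthoc: dict[str, dict[str, TestResult]]
    reference: dict = field(default_factory=dict)

    def eo_table(self) -> pd.DataFrame:
        rows = [
            {"group": k, "re": self.re[k], "eo": v, "reference": ref}
            for k, (v, ref) in self.eo.items()
        ]
        return pd.DataFrame(rows)


#: The audit's default non-sensitive reference groups.
DEFAULT_REFERENCE = {"race_ethnicity": "white", "gender": "male"}

_POSTHOC_PAIRS = (
    ("AF-WF", ("female", "african_american"), ("female", "white")),
    ("HF-WF", ("female", "hispanic"), ("female", "white")),
    ("AM-WM", ("male", "african_american"), ("male", "white")),
    ("HM-WM", ("male", "hispanic"), ("male", "white")),
)


def audit_anxiety(cohort: CohortTable, reference: dict | None = None) -> RegressionAuditReport:
    """Run the full Study-1 audit on an anxiety cohort.

    LOSO regression → per-group RE → EO against the reference groups
    (White within gender for intersectional cells, White for race, male for
    gender), plus ANOVA and post-hoc t-tests on both the actual and the
    estimated anxiety.
    """
    reference = {**DEFAULT_REFERENCE, **(reference or {})}
    rows = cohort.rows
    estimates = fit_predict_anxiety(cohort)
    actual = rows["sae_score"].to_numpy(dtype=float)

    # short group codes: AF, HF, WF, AM, HM, WM
    cell = (rows["race_ethnicity"].map({"african_american": "A", "hispanic": "H", "white": "W"})
            + rows["gender"].map({"female": "F", "male": "M"}))

    stats_rows = []
    for (gender, race), grp in rows.assign(est=estimates).groupby(
        ["gender", "race_ethnicity"], observed=True
    ):
        stats_rows.append({
            "gender": gender, "race_ethnicity": race, "n": len(grp),
            "actual_mean": grp["sae_score"].mean(), "actual_sd": grp["sae_score"].std(ddof=1),
            "estimated_mean": grp["est"].mean(), "estimated_sd": grp["est"].std(ddof=1),
        })
    group_stats = pd.DataFrame(stats_rows)

    re: dict[str, float] = {}
    re.update(group_relative_error(actual, estimates, cell))
    re.update(group_relative_error(actual, estimates, rows["race_ethnicity"]))
    re.update(group_relative_error(actual, estimates, rows["gender"]))

    ref_race = reference["race_ethnicity"]
    ref_gender = reference["gender"]
    ref_code = {"african_american": "A", "hispanic": "H", "white": "W"}[ref_race]
    eo: dict[str, tuple[float, str]] = {}
    for code, gcode in (("A", "F"), ("H", "F"), ("A", "M"), ("H", "M")):
        key, ref_key = code + gcode, ref_code + gcode
        if key in re and ref_key in re:
            eo[key] = (equality_of_opportunity_gap(re[key], re[ref_key]), ref_key)
    for race in ("african_american", "hispanic"):
        if race in re and ref_race in re:
            eo[race] = (equality_of_opportunity_gap(re[race], re[ref_race]), ref_race)
    sens_gender = "female" if ref_gender == "male" else "male"
    if sens_gender in re and ref_gender in re:
        eo[sens_gender] = (equality_of_opportunity_gap(re[sens_gender], re[ref_gender]), ref_gender)

    with_est = rows.assign(estimated=estimates)
    anova = {
        "actual": two_way_anova(with_est, "sae_score"),
        "estimated": two_way_anova(with_est, "estimated"),
    }
    posthoc: dict[str, dict[str, TestResult]] = {"actual": {}, "estimated": {}}
    for label, col in (("actual", "sae_score"), ("estimated", "estimated")):
        for name, (g1, r1), (g2, r2) in _POSTHOC_PAIRS:
            a = with_est[(with_est["gender"] == g1) & (with_est["race_ethnicity"] == r1)][col]
            b = with_est[(with_est["gender"] == g2) & (with_est["race_ethnicity"] == r2)][col]
            if len(a) >= 2 and len(b) >= 2:
                posthoc[label][name] = pairwise_t(a.to_numpy(), b.to_numpy())

    return RegressionAuditReport(
        group_stats=group_stats, re=re, eo=eo, anova=anova, posthoc=posthoc,
        reference=reference,
    )
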
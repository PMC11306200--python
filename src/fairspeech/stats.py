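"""Group-difference statistics and feature-ranking procedures.

The audits use four statistical primitives:

* an unbalanced two-way ANOVA (gender × race/ethnicity) on an acoustic
  measure or an outcome score,
* pooled-variance two-sample t-tests for post-hoc pairwise comparisons
  (Student, df = nA + nB − 2),
* the pooled two-proportion Z-test used to compare a model's predicted
  positive rate against a group's base rate, and
* two feature rankings: by gender separability (ascending t-test p-value)
  and by outcome relevance (descending absolute Pearson correlation with
  the PHQ-8 score).

All p-values are two-sided. No multiple-testing correction is applied by
default (pairwise tests accept ``bonferroni_m`` for callers who want one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, two-sided p."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA main effects and interaction."""

    race_ethnicity: TestResult
    gender: TestResult
    interaction: TestResult

    def as_dict(self) -> dict[str, TestResult]:
        return {"race_ethnicity": self.race_ethnicity, "gender": self.gender,
                "interaction": self.interaction}


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by a ranking criterion.

    ``criterion`` is ``"gender_ttest_p"`` (ascending p) or
    ``"outcome_pearson_r"`` (descending |r|); ties break lexicographically
    on the feature name so rankings are reproducible across column
    permutations of the input.
    """

    ordered: tuple[tuple[str, float], ...]
    criterion: str

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.ordered]

    def top(self, k: int) -> list[str]:
        return self.names[:k]


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "gender",
    factor_b: str = "race_ethnicity",
    ss_type: int = 2,
) -> AnovaResult:
    """Unbalanced two-way ANOVA with interaction.

    Type-II sums of squares by default — the conventional choice for an
    unbalanced factorial design, and insensitive to factor order. Type III
    is available via ``ss_type=3``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for f in (factor_a, factor_b):
        levels = data[f].nunique()
        if levels < 2:
            raise ValidationError(f"factor {f!r} has {levels} level(s); need >= 2")
    y = data[response].to_numpy(dtype=float)
    cells = data.groupby([factor_a, factor_b], observed=True)[response].count()
    if (cells < 2).any():
        raise ValidationError("every nonempty cell needs >= 2 observations")

    if np.ptp(y) == 0.0:  # constant response: nothing to explain
        def _null(name: str, df_num: float, df_den: float) -> TestResult:
            return TestResult(0.0, (df_num, df_den), 1.0, f"anova_{name}")
        n_a, n_b = data[factor_a].nunique(), data[factor_b].nunique()
        df_den = len(data) - n_a * n_b
        return AnovaResult(
            race_ethnicity=_null(factor_b, n_b - 1, df_den),
            gender=_null(factor_a, n_a - 1, df_den),
            interaction=_null("interaction", (n_a - 1) * (n_b - 1), df_den),
        )

    frame = data[[response, factor_a, factor_b]].copy()
    frame.columns = ["y", "fa", "fb"]
    model = smf.ols("y ~ C(fa) * C(fb)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    df_resid = float(table.loc["Residual", "df"])

    def _pick(term: str, name: str) -> TestResult:
        row = table.loc[term]
        return TestResult(float(row["F"]), (float(row["df"]), df_resid),
                          float(row["PR(>F)"]), f"anova_{name}")

    return AnovaResult(
        race_ethnicity=_pick("C(fb)", factor_b),
        gender=_pick("C(fa)", factor_a),
        interaction=_pick("C(fa):C(fb)", "interaction"),
    )


def pairwise_t(group_a: np.ndarray, group_b: np.ndarray, bonferroni_m: int = 1) -> TestResult:
    """Pooled-variance (Student) two-sample t-test, df = nA + nB − 2."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    res = sps.ttest_ind(a, b, equal_var=True)
    p = min(1.0, float(res.pvalue) * bonferroni_m)
    return TestResult(float(res.statistic), float(len(a) + len(b) - 2), p, "pooled_t")


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled two-proportion Z-test.

    z = (p̂₁ − p̂₂) / sqrt(p̂(1 − p̂)(1/n₁ + 1/n₂)) with p̂ = (k₁+k₂)/(n₁+n₂);
    two-sided p from the standard normal. Used to compare a model's
    predicted positive rate within a gender against that gender's base
    depression rate.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValidationError(f"invalid proportion counts k={k}, n={n}")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValidationError("pooled proportion is degenerate (0 or 1); z undefined")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float("inf"), float(p), "two_proportion_z")


def _ordered(pairs: list[tuple[str, float]], ascending: bool) -> tuple[tuple[str, float], ...]:
    # sort on (value, name): deterministic under feature-column permutation
    key = (lambda p: (p[1], p[0])) if ascending else (lambda p: (-p[1], p[0]))
    return tuple(sorted(pairs, key=key))


def rank_by_gender_separability(features: pd.DataFrame, gender: pd.Series | np.ndarray) -> FeatureRanking:
    """Rank features by two-sample t-test p-value between genders, ascending.

    The top of the ranking is the most gender-separable feature — the first
    candidate for removal when stripping gender evidence from the input. A
    feature constant in both groups gets p = 1 (with a warning)."""
    gender = np.asarray(gender)
    groups = np.unique(gender)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 gender groups, got {list(groups)}")
    mask = gender == groups[0]
    pairs = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        a, b = x[mask], x[~mask]
        if np.ptp(x) == 0.0:
            warnings.warn(f"feature {name!r} is constant; assigned p = 1", stacklevel=2)
            pairs.append((str(name), 1.0))
            continue
        res = sps.ttest_ind(a, b, equal_var=True)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        pairs.append((str(name), p))
    return FeatureRanking(_ordered(pairs, ascending=True), "gender_ttest_p")


def rank_by_outcome_correlation(features: pd.DataFrame, scores: pd.Series | np.ndarray) -> FeatureRanking:
    """Rank features by |Pearson r| with the outcome score, descending.

    The top of the ranking is the most outcome-relevant feature — the first
    kept when selecting a compact input set. A constant feature gets r = 0
    (with a warning)."""
    y = np.asarray(scores, dtype=float)
    if len(y) < 3:
        raise ValidationError("need >= 3 rows for a correlation ranking")
    if np.ptp(y) == 0.0:
        raise ValidationError("outcome scores are constant; correlation undefined")
    pairs = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(f"feature {name!r} is constant; assigned r = 0", stacklevel=2)
            pairs.append((str(name), 0.0))
            continue
        r = float(sps.pearsonr(x, y).statistic)
        pairs.append((str(name), abs(r)))
    return FeatureRanking(_ordered(pairs, ascending=False), "outcome_pearson_r")
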
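import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import f as fdist

import fairspeech as fs
from fairspeech.errors import ValidationError

# ---------------------------------------------------------------------------
# independent oracles (numpy / closed-form only; no statsmodels, no reuse of
# the implementation path)
# ---------------------------------------------------------------------------


def anova2_oracle(df: pd.DataFrame, resp: str = "y") -> dict:
    """Type-II two-way ANOVA via nested least-squares model comparison."""
    y = df[resp].to_numpy(float)
    A = pd.get_dummies(df["gender"], drop_first=True).to_numpy(float)
    B = pd.get_dummies(df["race_ethnicity"], drop_first=True).to_numpy(float)
    AB = np.concatenate(
        [A[:, [i]] * B[:, [j]] for i in range(A.shape[1]) for j in range(B.shape[1])],
        axis=1,
    )
    one = np.ones((len(y), 1))

    def rss(*blocks):
        X = np.concatenate([one, *blocks], axis=1)
        r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(r @ r)

    a, b, n = A.shape[1] + 1, B.shape[1] + 1, len(y)
    dfr = n - a * b
    mse_full = rss(A, B, AB) / dfr
    out = {}
    for key, dfn, ss in (
        ("gender", a - 1, rss(B) - rss(A, B)),
        ("race_ethnicity", b - 1, rss(A) - rss(A, B)),
        ("interaction", (a - 1) * (b - 1), rss(A, B) - rss(A, B, AB)),
    ):
        F = (ss / dfn) / mse_full
        out[key] = (F, float(dfn), float(dfr), float(fdist.sf(F, dfn, dfr)))
    return out


def pooled_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def ztest_oracle(k1, n1, k2, n2):
    p = (k1 + k2) / (n1 + n2)
    z = (k1 / n1 - k2 / n2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    pval = math.erfc(abs(z) / math.sqrt(2))  # two-sided standard normal
    return z, pval


# ---------------------------------------------------------------------------


class TestTwoWayAnova:
    def test_constant_response_explains_nothing(self, anxiety_cohort):
        df = anxiety_cohort.rows.assign(y=5.0)
        res = fs.two_way_anova(df, "y")
        for tr in res.as_dict().values():
            assert tr.statistic == 0.0 and tr.p_value == 1.0

    def test_design_df_match_2x3_layout(self, anxiety_cohort):
        res = fs.two_way_anova(anxiety_cohort.rows, "sae_score")
        assert res.gender.df == (1.0, 223.0)
        assert res.race_ethnicity.df == (2.0, 223.0)
        assert res.interaction.df == (2.0, 223.0)

    def test_planted_single_factor_effect(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in ("female", "male"):
            for r in ("white", "hispanic"):
                mu = 1.0 if g == "female" else 0.0
                for _ in range(25):
                    rows.append((g, r, mu + rng.normal(scale=1e-3)))
        df = pd.DataFrame(rows, columns=["gender", "race_ethnicity", "y"])
        res = fs.two_way_anova(df, "y")
        assert res.gender.p_value < 1e-20
        assert res.race_ethnicity.statistic < 1.0

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"gender": ["female"] * 8,
                           "race_ethnicity": ["white", "hispanic"] * 4,
                           "y": np.arange(8.0)})
        with pytest.raises(ValidationError):
            fs.two_way_anova(df, "y")

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            rows = []
            for g in ("female", "male"):
                for r in ("african_american", "hispanic", "white"):
                    for _ in range(int(rng.integers(3, 10))):
                        rows.append((g, r, rng.normal()))
            df = pd.DataFrame(rows, columns=["gender", "race_ethnicity", "y"])
            res = fs.two_way_anova(df, "y")
            ora = anova2_oracle(df)
            for key, tr in res.as_dict().items():
                F, dfn, dfr, p = ora["interaction" if key == "interaction" else key]
                assert tr.statistic == pytest.approx(F, abs=1e-9)
                assert tr.p_value == pytest.approx(p, abs=1e-9)
                assert tr.df == (dfn, dfr)


class TestPairwiseT:
    def test_identical_groups_give_zero(self):
        res = fs.pairwise_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_pooled_t(self):
        res = fs.pairwise_t([0, 0, 1, 1], [1, 1, 2, 2])
        assert res.statistic == pytest.approx(-2.449, abs=1e-3)
        assert res.df == 6

    def test_df_is_pooled_not_welch(self, anxiety_cohort):
        # AF (21 files) vs WF (75 files) must print t(94)
        rows = anxiety_cohort.rows
        af = rows[(rows.gender == "female") & (rows.race_ethnicity == "african_american")]
        wf = rows[(rows.gender == "female") & (rows.race_ethnicity == "white")]
        res = fs.pairwise_t(af["f0_semitone"], wf["f0_semitone"])
        assert res.df == 94

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            fs.pairwise_t([1.0], [1, 2, 3])

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 40))
            b = rng.normal(size=rng.integers(2, 40))
            res = fs.pairwise_t(a, b)
            assert res.statistic == pytest.approx(pooled_t_oracle(a, b), abs=1e-9)


class TestTwoProportionZ:
    @pytest.mark.parametrize(
        "k1, n1, k2, n2, expected",
        [
            (14, 63, 17, 44, -1.842),   # predicted vs actual depression rates
            (1, 44, 17, 44, -4.228),
            (1, 63, 14, 63, -3.576),
        ],
    )
    def test_reference_values(self, k1, n1, k2, n2, expected):
        assert fs.two_proportion_z(k1, n1, k2, n2).statistic == pytest.approx(expected, abs=1e-3)

    def test_equal_proportions_give_zero(self):
        res = fs.two_proportion_z(5, 10, 5, 10)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_pooled_proportion_rejected(self):
        with pytest.raises(ValidationError):
            fs.two_proportion_z(0, 10, 0, 20)

    def test_matches_brute_force_and_normal_cdf_oracles(self):
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 100:
            n1, n2 = int(rng.integers(2, 200)), int(rng.integers(2, 200))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            if (k1 + k2) in (0, n1 + n2):
                continue
            z, p = ztest_oracle(k1, n1, k2, n2)
            res = fs.two_proportion_z(k1, n1, k2, n2)
            assert res.statistic == pytest.approx(z, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-9)
            checked += 1

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n2 = int(rng.integers(5, 100)), int(rng.integers(5, 100))
            k1, k2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            z, p = proportions_ztest([k1, k2], [n1, n2])
            res = fs.two_proportion_z(k1, n1, k2, n2)
            assert res.statistic == pytest.approx(z, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)

    @given(
        st.integers(1, 100), st.integers(1, 100),
        st.integers(0, 100), st.integers(0, 100),
    )
    @settings(max_examples=80, derandomize=True)
    def test_antisymmetry(self, n1, n2, k1, k2):
        k1, k2 = min(k1, n1), min(k2, n2)
        if (k1 + k2) in (0, n1 + n2):
            return
        a = fs.two_proportion_z(k1, n1, k2, n2)
        b = fs.two_proportion_z(k2, n2, k1, n1)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


class TestFeatureRankings:
    def _frame(self, rng, n=60, p=6):
        return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])

    def test_gender_indicator_ranked_first(self):
        rng = np.random.default_rng(6)
        X = self._frame(rng)
        gender = np.array(["female", "male"] * 30)
        X["ind"] = (gender == "female") + rng.normal(scale=0.01, size=60)
        ranking = fs.rank_by_gender_separability(X, gender)
        assert ranking.names[0] == "ind"
        assert ranking.criterion == "gender_ttest_p"

    def test_perfect_and_negated_correlation_rank_first(self):
        rng = np.random.default_rng(7)
        X = self._frame(rng)
        y = rng.normal(size=60)
        X["pos"], X["neg"] = y, -y
        ranking = fs.rank_by_outcome_correlation(X, y)
        assert set(ranking.top(2)) == {"pos", "neg"}
        assert ranking.ordered[0][1] == pytest.approx(1.0)

    def test_correlation_values_match_numpy_oracle(self):
        rng = np.random.default_rng(8)
        X = self._frame(rng, n=40)
        y = rng.normal(size=40)
        ranking = fs.rank_by_outcome_correlation(X, y)
        for name, r in ranking.ordered:
            expect = abs(np.corrcoef(X[name], y)[0, 1])
            assert r == pytest.approx(expect, abs=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        X = self._frame(rng)
        gender = np.array(["female"] * 30 + ["male"] * 30)
        a = fs.rank_by_gender_separability(X, gender)
        b = fs.rank_by_gender_separability(X[list(reversed(X.columns))], gender)
        assert a.ordered == b.ordered

    def test_constant_feature_warned_and_deprioritized(self):
        rng = np.random.default_rng(10)
        X = self._frame(rng)
        X["flat"] = 1.0
        gender = np.array(["female", "male"] * 30)
        with pytest.warns(UserWarning, match="flat"):
            ranking = fs.rank_by_gender_separability(X, gender)
        assert dict(ranking.ordered)["flat"] == 1.0
        y = rng.normal(size=60)
        with pytest.warns(UserWarning, match="flat"):
            ranking = fs.rank_by_outcome_correlation(X, y)
        assert ranking.names[-1] == "flat"

    def test_null_features_rank_uniformly(self):
        """With pure-noise features the rank of a fixed feature is uniform
        over positions: its mean rank over seeds approaches (p-1)/2."""
        rng_master = np.random.default_rng(11)
        p, seeds = 8, 200
        ranks = []
        for _ in range(seeds):
            rng = np.random.default_rng(rng_master.integers(2**31))
            X = self._frame(rng, n=30, p=p)
            gender = np.array(["female", "male"] * 15)
            ranking = fs.rank_by_gender_separability(X, gender)
            ranks.append(ranking.names.index("f0"))
        mean_rank = float(np.mean(ranks))
        # uniform on 0..7: mean 3.5, sd 2.29; 3-sigma band for 200 draws
        assert abs(mean_rank - 3.5) < 3 * 2.29 / np.sqrt(seeds)
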
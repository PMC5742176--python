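"""Cohort statistics against the bundled reference table and hand oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import blinkrv as b


@pytest.fixture(scope="module")
def table():
    return b.load_cohort()


class TestLoadCohort:
    def test_bundled_table_has_24_records(self, table):
        assert len(table) == 24

    def test_subject_seven(self, table):
        rec = table.record(7)
        assert rec.rest_alpha == 1.29
        assert rec.iq_score == 7

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "id,rest_br,rest_alpha,iq_br,iq_alpha,iq_score\n"
            "1,10,0.5,10,0.5,3\n1,11,0.6,11,0.6,4\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            b.load_cohort(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "short.csv"
        p.write_text("id,rest_br\n1,10\n")
        with pytest.raises(ValueError, match="missing"):
            b.load_cohort(p)

    def test_out_of_range_score_rejected(self, tmp_path):
        p = tmp_path / "score.csv"
        p.write_text(
            "id,rest_br,rest_alpha,iq_br,iq_alpha,iq_score\n1,10,0.5,10,0.5,14\n"
        )
        with pytest.raises(ValueError, match="iq_score"):
            b.load_cohort(p)


class TestMedianSplit:
    def test_reference_cohort_splits_9_15_at_4(self, table):
        split = b.median_split(table)
        assert split.threshold == 4
        assert len(split.high_group) == 9
        assert len(split.low_group) == 15

    def test_partition_property(self, table):
        split = b.median_split(table)
        ids = set(table.df["id"])
        assert set(split.high_group) | set(split.low_group) == ids
        assert set(split.high_group) & set(split.low_group) == set()

    def test_all_equal_scores_leave_high_group_empty(self):
        df = pd.DataFrame(
            {
                "id": [1, 2, 3],
                "rest_br": [10.0] * 3,
                "rest_alpha": [0.5, 0.6, 0.7],
                "iq_br": [10.0] * 3,
                "iq_alpha": [0.5] * 3,
                "iq_score": [4, 4, 4],
            }
        )
        split = b.median_split(b.CohortTable(df))
        assert split.high_group == ()

    def test_hand_median_of_five(self):
        df = pd.DataFrame(
            {
                "id": [1, 2, 3, 4, 5],
                "rest_br": [10.0] * 5,
                "rest_alpha": [0.5] * 5,
                "iq_br": [10.0] * 5,
                "iq_alpha": [0.5] * 5,
                "iq_score": [1, 2, 3, 4, 5],
            }
        )
        split = b.median_split(b.CohortTable(df))
        assert split.threshold == 3
        assert set(split.high_group) == {4, 5}


class TestAnova:
    def test_resting_alpha_group_contrast_matches_t_squared_oracle(self, table):
        # independent route: F for two groups equals the squared pooled t
        split = b.median_split(table)
        hi = table.df[table.df["id"].isin(split.high_group)]["rest_alpha"]
        lo = table.df[table.df["id"].isin(split.low_group)]["rest_alpha"]
        t, _ = sps.ttest_ind(hi, lo)
        res = b.group_anova(table, "rest_alpha")
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.df == (1, 22)
        assert res.F == pytest.approx(6.33696, abs=1e-4)  # frozen via the t**2 oracle

    def test_identical_groups_give_zero_f(self):
        res = b.one_way_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.F == 0.0

    def test_hand_computed_sum_of_squares(self):
        # groups [1,2,3] and [2,4,6]: SSB=6, SSW=10, F = 6/(10/4) = 2.4
        res = b.one_way_anova([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.F == pytest.approx(2.4)
        assert res.df == (1, 4)

    def test_constant_unequal_groups_raise(self):
        with pytest.raises(ValueError, match="infinite F"):
            b.one_way_anova([1.0, 1.0], [2.0, 2.0])

    def test_constant_equal_groups_give_zero(self):
        res = b.one_way_anova([2.0, 2.0], [2.0, 2.0])
        assert res.F == 0.0 and res.p == 1.0

    @given(
        seed=st.integers(0, 10_000),
        na=st.integers(3, 12),
        nb=st.integers(3, 12),
    )
    def test_symmetry_and_t_squared_identity(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(na)
        c = rng.standard_normal(nb) + 0.5
        r1 = b.one_way_anova(a, c)
        r2 = b.one_way_anova(c, a)
        assert r1.F == pytest.approx(r2.F)
        t, _ = sps.ttest_ind(a, c)
        assert r1.F == pytest.approx(t**2, rel=1e-9)


class TestPearson:
    def test_resting_alpha_vs_iq_score(self, table):
        res = b.pearson(table.df["rest_alpha"], table.df["iq_score"])
        assert res.r == pytest.approx(0.4289, abs=1e-3)
        assert res.r_squared == pytest.approx(res.r**2)
        assert res.n == 24

    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = b.pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_hand_expanded_product_moment(self):
        # sum (x-2)(y-4) = -5; sqrt(2 * 14) -> r = -5/sqrt(28)
        res = b.pearson([1.0, 2.0, 3.0], [6.0, 5.0, 1.0])
        assert res.r == pytest.approx(-5.0 / np.sqrt(28.0), abs=1e-3)
        assert res.r == pytest.approx(-0.945, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            b.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
    )
    def test_affine_invariance_and_sign_flip(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        base = b.pearson(x, y).r
        assert b.pearson(scale * x + shift, y).r == pytest.approx(base, abs=1e-9)
        assert b.pearson(-scale * x, y).r == pytest.approx(-base, abs=1e-9)


class TestShapiroWilk:
    def test_gaussian_samples_pass(self):
        passes = 0
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(200)
            _, p = b.shapiro_wilk(x)
            passes += p > 0.05
        assert passes >= 45

    def test_lognormal_samples_rejected(self):
        rejections = 0
        for seed in range(50):
            x = np.exp(np.random.default_rng(seed).standard_normal(200))
            _, p = b.shapiro_wilk(x)
            rejections += p < 0.05
        assert rejections >= 45

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="3 <= n"):
            b.shapiro_wilk([1.0, 2.0])


class TestSessionSummary:
    def test_overall_resting_rates(self, table):
        s = b.session_summary(table)
        assert s.loc["overall", ("rest_br", "mean")] == pytest.approx(18.27, abs=0.01)
        assert s.loc["overall", ("rest_br", "sd")] == pytest.approx(10.44, abs=0.01)

    @pytest.mark.parametrize(
        "group,col,mean,sd",
        [
            ("high", "rest_br", 17.22, 6.01),
            ("low", "rest_br", 18.89, 12.54),
            ("high", "rest_alpha", 0.94, 0.25),
            ("low", "rest_alpha", 0.72, 0.18),
            ("high", "iq_br", 19.07, 8.42),
            ("low", "iq_br", 19.18, 12.72),
            ("high", "iq_alpha", 0.64, 0.10),
            ("low", "iq_alpha", 0.61, 0.19),
        ],
    )
    def test_group_cells(self, table, group, col, mean, sd):
        s = b.session_summary(table)
        assert s.loc[group, (col, "mean")] == pytest.approx(mean, abs=0.01)
        assert s.loc[group, (col, "sd")] == pytest.approx(sd, abs=0.01)

    def test_single_row_has_missing_sd(self):
        df = pd.DataFrame(
            {
                "id": [1],
                "rest_br": [10.0],
                "rest_alpha": [0.5],
                "iq_br": [10.0],
                "iq_alpha": [0.5],
                "iq_score": [3],
            }
        )
        s = b.session_summary(b.CohortTable(df))
        assert np.isnan(s.loc["overall", ("rest_br", "sd")])


class TestCompareSessions:
    def test_alpha_sessions_df(self, table):
        res = b.compare_sessions(table, ("rest_alpha", "iq_alpha"))
        assert res.df == (1, 46)
        assert res.F > 0

    def test_column_against_itself_is_zero(self, table):
        res = b.compare_sessions(table, ("rest_alpha", "rest_alpha"))
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_toy_table_hand_decomposition(self):
        # rest [0.5,0.6,0.7] vs iq [0.2,0.3,0.4]: SSB=0.135, MSW=0.01, F=13.5
        df = pd.DataFrame(
            {
                "id": [1, 2, 3],
                "rest_br": [10.0] * 3,
                "rest_alpha": [0.5, 0.6, 0.7],
                "iq_br": [10.0] * 3,
                "iq_alpha": [0.2, 0.3, 0.4],
                "iq_score": [3, 4, 5],
            }
        )
        res = b.compare_sessions(b.CohortTable(df), ("rest_alpha", "iq_alpha"))
        assert res.F == pytest.approx(13.5)
        assert res.df == (1, 4)
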
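"""Inferential battery: identities, oracles, and calibration checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pstmodels import (
    bonferroni_alpha,
    independent_t,
    one_way_anova,
    paired_t,
    partial_eta_squared,
    p_from_t,
    pearson_r,
    rm_anova_2x2,
    wilcoxon_signed_rank,
)


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by full enumeration of sign assignments.

    Assumes tie-free, non-zero differences.  The null statistic T (sum of
    positive ranks) is symmetric about M/2 with M = n(n+1)/2, so the
    two-sided p is P(|T - M/2| >= |t_obs - M/2|).
    """
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    t_obs = ranks[d > 0].sum()
    n = len(d)
    m = n * (n + 1) / 2
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if abs(t - m / 2) >= abs(t_obs - m / 2) - 1e-12:
            count += 1
    return count / 2**n


def rm_anova_ss_oracle(scores):
    """Classical sums-of-squares 2x2 repeated-measures ANOVA (oracle).

    Decomposes SS into A, B, AxB and their subject-interaction error
    terms on the full n x 2 x 2 cube; independent of the contrast-score
    implementation.
    """
    y = np.asarray(scores, dtype=float).reshape(-1, 2, 2)  # subject x A x B
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    ab_m = y.mean(axis=0)
    ss_a = 2 * n * ((a_m - grand) ** 2).sum()
    ss_b = 2 * n * ((b_m - grand) ** 2).sum()
    ss_ab = n * ((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    sa = y.mean(axis=2)  # subject x A
    sb = y.mean(axis=1)  # subject x B
    ss_sa = 2 * ((sa - subj[:, None] - a_m[None, :] + grand) ** 2).sum()
    ss_sb = 2 * ((sb - subj[:, None] - b_m[None, :] + grand) ** 2).sum()
    ss_sab = ((y - sa[:, :, None] - sb[:, None, :] - ab_m[None, :, :]
               + subj[:, None, None] + a_m[None, :, None] + b_m[None, None, :]
               - grand) ** 2).sum()
    df_e = n - 1
    out = {}
    for name, ss, ss_e in (("A", ss_a, ss_sa), ("B", ss_b, ss_sb),
                           ("AxB", ss_ab, ss_sab)):
        F = (ss / 1) / (ss_e / df_e)
        out[name] = (F, ss / (ss + ss_e))
    return out


class TestPValueIdentities:
    def test_t_zero_gives_p_one(self):
        assert p_from_t(0.0, 10) == pytest.approx(1.0)

    def test_published_t_identity(self):
        assert p_from_t(2.894, 16) == pytest.approx(0.0106, abs=0.0005)

    def test_f_t_equivalence(self):
        # F(1, df) = t(df)^2, so sqrt(F) recovers the two-tailed p
        assert p_from_t(math.sqrt(2.803), 16) == pytest.approx(0.114, abs=0.001)
        assert p_from_t(math.sqrt(4.692), 16) == pytest.approx(0.046, abs=0.001)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)


class TestEffectSizes:
    def test_eta_zero_when_f_zero(self):
        assert partial_eta_squared(0.0, 1, 16) == 0.0

    @pytest.mark.parametrize("F, expected", [(2.803, 0.149), (4.692, 0.227)])
    def test_published_eta_identities(self, F, expected):
        assert partial_eta_squared(F, 1, 16) == pytest.approx(expected, abs=5e-4)

    def test_paired_d_variants(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, 30)
        y = x + rng.normal(0.5, 1, 30)
        tr, es = paired_t(x, y)
        d = x - y
        assert es.d_z == pytest.approx(d.mean() / d.std(ddof=1))
        assert es.d_z == pytest.approx(tr.statistic / math.sqrt(tr.n))
        assert es.d_av == pytest.approx(
            d.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2)
        )


class TestBonferroni:
    def test_four_comparisons(self):
        assert bonferroni_alpha(0.05, 4) == pytest.approx(0.0125)

    def test_single_comparison_unchanged(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_five_comparisons(self):
        assert bonferroni_alpha(0.05, 5) == pytest.approx(0.01)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestPairedT:
    def test_identical_vectors_degenerate(self):
        tr, es = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert math.isnan(tr.statistic)

    def test_zero_mean_differences(self):
        tr, _ = paired_t([1, 0, 1, 0], [0, 1, 0, 1])
        assert tr.statistic == pytest.approx(0.0)
        assert tr.p == pytest.approx(1.0)

    def test_pairwise_deletion(self):
        x = [1.0, np.nan, 3.0, 4.0]
        y = [0.5, 2.0, 2.0, 3.0]
        tr, _ = paired_t(x, y)
        assert tr.n == 3

    def test_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 25))
        tr, _ = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert tr.statistic == pytest.approx(ref.statistic)
        assert tr.p == pytest.approx(ref.pvalue)


class TestRmAnova2x2:
    def test_constant_cells_give_zero_f(self):
        scores = np.tile([[60.0, 60.0, 60.0, 60.0]], (6, 1))
        res = rm_anova_2x2(scores)
        for name in ("A", "B", "AxB"):
            assert res[name][0].statistic == 0.0

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(70, 10, size=(6, 4))
        res = rm_anova_2x2(scores)
        oracle = rm_anova_ss_oracle(scores)
        for name in ("A", "B", "AxB"):
            tr, es = res[name]
            f_ref, eta_ref = oracle[name]
            assert tr.statistic == pytest.approx(f_ref, abs=1e-8)
            assert es.eta_p2 == pytest.approx(eta_ref, abs=1e-8)

    def test_matches_pingouin(self):
        """Independent cross-check against the reference RM-ANOVA."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        scores = rng.normal(0, 5, size=(10, 4))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 4),
                "a": np.tile([1, 1, 2, 2], 10),
                "b": np.tile([1, 2, 1, 2], 10),
                "y": scores.ravel(),
            }
        )
        ref = pingouin.rm_anova(
            data=long, dv="y", within=["a", "b"], subject="subject", detailed=True
        ).set_index("Source")
        res = rm_anova_2x2(scores)
        assert res["A"][0].statistic == pytest.approx(ref.loc["a", "F"], rel=1e-6)
        assert res["B"][0].statistic == pytest.approx(ref.loc["b", "F"], rel=1e-6)
        assert res["AxB"][0].statistic == pytest.approx(ref.loc["a * b", "F"], rel=1e-6)

    def test_interaction_null_under_additive_effect(self):
        rng = np.random.default_rng(4)
        sig = 0
        for _ in range(200):
            base = rng.normal(0, 1, size=(12, 1))
            effect_a = np.array([2.0, 2.0, 0.0, 0.0])
            scores = base + effect_a + rng.normal(0, 1, size=(12, 4))
            res = rm_anova_2x2(scores)
            sig += res["AxB"][0].p < 0.05
        assert sig / 200 == pytest.approx(0.05, abs=0.05)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_2x2(np.ones((2, 4)))

    @given(st.integers(0, 2**20))
    @settings(max_examples=20, deadline=None)
    def test_f_equals_t_squared_for_main_effect(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, size=(8, 4))
        res = rm_anova_2x2(scores)
        a1 = scores[:, :2].mean(axis=1)
        a2 = scores[:, 2:].mean(axis=1)
        tr, _ = paired_t(a1, a2)
        assert res["A"][0].statistic == pytest.approx(tr.statistic**2, abs=1e-9)
        assert res["A"][0].p == pytest.approx(tr.p, abs=1e-12)


class TestWilcoxon:
    def test_five_positive_differences(self):
        # all-positive signs: exact two-sided p = 2/32
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5)
        assert res.p == pytest.approx(0.0625)

    def test_antisymmetric_differences_not_significant(self):
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0], [0.0] * 4)
        assert res.p > 0.6

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 0.0], [1.0, 0.0, 0.0])
        assert res.n == 1

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 1.0], [1.0, 1.0])
        assert math.isnan(res.statistic)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, n)
            while len(np.unique(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(0.3, 1.0, n)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.p == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)


class TestOtherTests:
    def test_independent_t_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 22)
        tr, es = independent_t(x, y)
        ref = sps.ttest_ind(x, y)
        assert tr.statistic == pytest.approx(ref.statistic)
        assert tr.p == pytest.approx(ref.pvalue)

    def test_one_way_anova_eta(self):
        rng = np.random.default_rng(6)
        g1, g2, g3 = rng.normal(0, 1, 15), rng.normal(1, 1, 15), rng.normal(2, 1, 15)
        tr, es = one_way_anova(g1, g2, g3)
        assert tr.df == (2, 42)
        assert es.eta_p2 == pytest.approx(
            partial_eta_squared(tr.statistic, 2, 42)
        )

    def test_pearson_r_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        tr = pearson_r(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert tr.statistic == pytest.approx(r_ref)
        assert tr.p == pytest.approx(p_ref)
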
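"""Rank transform, RM ANOVA vs brute-force oracle, rank tests, descriptives."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phylloseal.stats import (
    mann_whitney,
    median_iqr,
    pairwise_bonferroni,
    rank_transform,
    rm_anova_two_way,
    spearman_rho,
    validate_rm_table,
)
from tests.conftest import make_rm_table


# --------------------------------------------------------------------------
# rank transform

class TestRankTransform:
    def test_permutation_values(self):
        df = pd.DataFrame(
            {"subject": list("abc"), "condition": "x", "time_min": [1, 2, 3],
             "gamma_deg": [3.0, 1.0, 2.0]}
        )
        out = rank_transform(df)
        assert list(out["gamma_deg"]) == [3.0, 1.0, 2.0]

    def test_average_ties(self):
        df = pd.DataFrame(
            {"subject": list("abc"), "condition": "x", "time_min": [1, 2, 3],
             "gamma_deg": [5.0, 5.0, 1.0]}
        )
        assert list(rank_transform(df)["gamma_deg"]) == [2.5, 2.5, 1.0]

    def test_rank_sum_conserved(self, rm_table):
        ranked = rank_transform(rm_table)
        n = len(rm_table)
        assert ranked["gamma_deg"].sum() == pytest.approx(n * (n + 1) / 2)

    def test_invariant_under_monotone_transform(self, rm_table):
        monotone = rm_table.copy()
        monotone["gamma_deg"] = np.exp(0.3 * monotone["gamma_deg"]) + 5.0
        pd.testing.assert_series_equal(
            rank_transform(rm_table)["gamma_deg"], rank_transform(monotone)["gamma_deg"]
        )


# --------------------------------------------------------------------------
# repeated-measures ANOVA

def _oracle_rm_anova(cube):
    """Naive loop-based sums-of-squares oracle for the within-subject design."""
    n, a, b = cube.shape
    gm = cube.mean()
    ss = {k: 0.0 for k in ("A", "B", "AB", "AS", "BS", "ABS")}
    mA = [cube[:, i, :].mean() for i in range(a)]
    mB = [cube[:, :, j].mean() for j in range(b)]
    mS = [cube[s].mean() for s in range(n)]
    for i in range(a):
        ss["A"] += n * b * (mA[i] - gm) ** 2
    for j in range(b):
        ss["B"] += n * a * (mB[j] - gm) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (cube[:, i, j].mean() - mA[i] - mB[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (cube[s, i, :].mean() - mS[s] - mA[i] + gm) ** 2
        for j in range(b):
            ss["BS"] += a * (cube[s, :, j].mean() - mS[s] - mB[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            for j in range(b):
                ss["ABS"] += (
                    cube[s, i, j]
                    - cube[s, i, :].mean()
                    - cube[s, :, j].mean()
                    - cube[:, i, j].mean()
                    + mS[s]
                    + mA[i]
                    + mB[j]
                    - gm
                ) ** 2
    F_A = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    F_B = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    F_AB = (ss["AB"] / ((a - 1) * (b - 1))) / (ss["ABS"] / ((a - 1) * (b - 1) * (n - 1)))
    return F_A, F_B, F_AB


def test_small_design_matches_hand_oracle():
    """2x2 design with 3 subjects: F identical to direct SS computation."""
    rng = np.random.default_rng(42)
    cube = rng.normal(0, 1, (3, 2, 2))
    res = rm_anova_two_way(cube)
    F_A, F_B, F_AB = _oracle_rm_anova(cube)
    assert res.condition.F == pytest.approx(F_A, abs=1e-10)
    assert res.time.F == pytest.approx(F_B, abs=1e-10)
    assert res.interaction.F == pytest.approx(F_AB, abs=1e-10)


def test_oracle_equivalence_on_many_random_designs():
    """Implementation equals the brute-force SS oracle on 100 random designs."""
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = int(rng.integers(3, 7))
        a = int(rng.integers(2, 5))
        b = int(rng.integers(2, 5))
        cube = rng.normal(0, 1, (n, a, b)) + rng.normal(0, 1, (n, 1, 1))
        res = rm_anova_two_way(cube)
        F = _oracle_rm_anova(cube)
        for eff, f_oracle in zip(res.effects(), F):
            assert eff.F == pytest.approx(f_oracle, abs=1e-8)


def test_df_pattern_of_published_design():
    """4 conditions x 6 times x 17 subjects gives df (3,48), (5,80), (15,240)."""
    rng = np.random.default_rng(1)
    res = rm_anova_two_way(rng.normal(0, 1, (17, 4, 6)))
    assert (res.condition.df1, res.condition.df2) == (3, 48)
    assert (res.time.df1, res.time.df2) == (5, 80)
    assert (res.interaction.df1, res.interaction.df2) == (15, 240)


def test_two_level_factor_sphericity_vacuous():
    rng = np.random.default_rng(2)
    res = rm_anova_two_way(rng.normal(0, 1, (6, 2, 3)))
    assert res.condition.sphericity.W == 1.0
    assert res.condition.gg_epsilon == 1.0
    assert res.condition.p == res.condition.p_gg


def test_epsilon_bounds():
    # n must exceed the interaction contrast dimension for a full-rank
    # covariance, as in the published design (17 subjects, 15 contrasts)
    rng = np.random.default_rng(3)
    res = rm_anova_two_way(rng.normal(0, 1, (20, 4, 6)))
    for eff in res.effects():
        assert 1.0 / eff.df1 <= eff.gg_epsilon <= 1.0
        assert 0.0 < eff.sphericity.W <= 1.0


def test_agrees_with_pingouin_two_way_rm():
    """Independent cross-check of F, p, GG epsilon and Mauchly's test."""
    pg = pytest.importorskip("pingouin")
    df = make_rm_table(np.random.default_rng(7), n=8, a=3, b=4, effect=0.5)
    res = rm_anova_two_way(df)
    aov = pg.rm_anova(
        data=df, dv="gamma_deg", within=["condition", "time_min"],
        subject="subject", detailed=True,
    )
    for eff, src in zip(res.effects()[:3], ["condition", "time_min", "condition * time_min"]):
        row = aov[aov["Source"] == src].iloc[0]
        assert eff.F == pytest.approx(row["F"], rel=1e-9)
        assert eff.p == pytest.approx(row["p_unc"], rel=1e-9)
    # per-main-effect sphericity diagnostics
    for factor, eff in (("condition", res.condition), ("time_min", res.time)):
        means = df.groupby(["subject", factor], as_index=False)["gamma_deg"].mean()
        sph = pg.sphericity(means, dv="gamma_deg", subject="subject", within=factor)
        eps = pg.epsilon(means, dv="gamma_deg", subject="subject", within=factor, correction="gg")
        assert eff.sphericity.W == pytest.approx(float(sph.W), rel=1e-9)
        assert eff.sphericity.p == pytest.approx(float(sph.pval), rel=1e-9)
        assert eff.gg_epsilon == pytest.approx(float(eps), rel=1e-9)


def test_missing_and_duplicated_cells_rejected(rm_table):
    with pytest.raises(ValueError, match="missing cells"):
        rm_anova_two_way(rm_table.iloc[:-1])
    dup = pd.concat([rm_table, rm_table.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicated"):
        validate_rm_table(dup)


def test_rank_argument_equals_manual_ranking(rm_table):
    via_flag = rm_anova_two_way(rm_table, rank=True)
    via_manual = rm_anova_two_way(rank_transform(rm_table))
    for e1, e2 in zip(via_flag.effects(), via_manual.effects()):
        assert e1.F == pytest.approx(e2.F, rel=1e-12)


# --------------------------------------------------------------------------
# pairwise comparisons

class TestPairwise:
    def test_bonferroni_multiplication_and_cap(self, rm_table):
        out = pairwise_bonferroni(rm_table, "condition")
        m = len(out)
        assert m == 3 * 2 // 2
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, m * out["p_raw"]), rtol=1e-12
        )

    def test_identical_samples_degenerate(self):
        df = pd.DataFrame(
            {
                "subject": list("abcd") * 2,
                "condition": ["x"] * 4 + ["y"] * 4,
                "time_min": 1.0,
                "gamma_deg": [1.0, 2.0, 3.0, 4.0] * 2,
            }
        )
        out = pairwise_bonferroni(df, "condition")
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p_raw"] == 1.0

    def test_matches_scipy_paired_t(self, rm_table):
        out = pairwise_bonferroni(rm_table, "condition")
        means = rm_table.groupby(["subject", "condition"])["gamma_deg"].mean().unstack()
        row = out.iloc[0]
        t, p = sps.ttest_rel(means[row["level_a"]], means[row["level_b"]])
        assert row["t"] == pytest.approx(t, rel=1e-12)
        assert row["p_raw"] == pytest.approx(p, rel=1e-12)


# --------------------------------------------------------------------------
# rank statistics

class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x**3)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, _ = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-12)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic, rel=1e-12)

    def test_exact_small_n_p_value(self):
        """n = 4 without ties: p equals the share of permutations with |rho|
        at least as extreme, enumerated independently here."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        rho, p = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        hits = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert rho == pytest.approx(obs)
        assert p == pytest.approx(hits / 24)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_large_n_approximation_close_to_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestMannWhitney:
    def test_identical_multisets_give_half_n1n2(self):
        x = np.arange(10.0)
        W, _ = mann_whitney(x, x.copy())
        assert W == 50.0  # n1*n2/2

    def test_complete_separation(self):
        W, p = mann_whitney([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert W == 9.0  # n1*n2
        assert p == pytest.approx(2 / 20)  # both extreme tails of C(6,3)

    def test_exact_p_equals_enumeration(self):
        """n1 = n2 = 4: exact p reproduces exhaustive label enumeration."""
        rng = np.random.default_rng(8)
        x = rng.normal(0.5, 1, 4)
        y = rng.normal(0.0, 1, 4)
        W, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert W == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.8, 1, 30)
        y = rng.normal(0.0, 1, 25)
        W, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert W == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestMedianIqr:
    def test_median_of_five(self):
        assert median_iqr([1, 2, 3, 4, 5])["median"] == 3.0

    def test_constant_vector_zero_iqr(self):
        out = median_iqr([7.0] * 6)
        assert out["iqr"] == 0.0 and out["min"] == out["max"] == 7.0

    def test_six_values_linear_interpolation_rule(self):
        # sorted x: quartiles by linear interpolation between closest ranks:
        # Q1 at rank 1 + 0.25*5 = 2.25 -> x[1] + 0.25 (x[2]-x[1]), etc.
        x = np.array([2.0, 4.0, 5.0, 9.0, 11.0, 20.0])
        out = median_iqr(x)
        q1 = 4.0 + 0.25 * (5.0 - 4.0)
        q3 = 9.0 + 0.75 * (11.0 - 9.0)
        assert out["median"] == pytest.approx(7.0)
        assert out["iqr"] == pytest.approx(q3 - q1)
        assert out["n"] == 6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])
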
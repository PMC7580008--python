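import math

import numpy as np
import pandas as pd
import pytest

from chronodiet.stats import (
    anova_tukey,
    benjamini_hochberg,
    chi_square,
    ols,
    random_intercept_meals,
    spearman,
    two_sample_t,
)


def bh_stepup_bruteforce(pvals, alpha):
    """Independent step-up oracle: largest k with p_(k) <= k*alpha/m."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * alpha / m:
            k_star = k
    flags = [False] * m
    for i in order[:k_star]:
        flags[i] = True
    return flags


class TestTwoSampleT:
    def test_identical_groups(self):
        r = two_sample_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_clear_separation(self):
        r = two_sample_t([1, 2, 3], [11, 12, 13])
        assert r.p_value < 0.01

    def test_welch_matches_formula(self):
        a = np.array([2.1, 2.4, 2.2, 2.5])
        b = np.array([2.0, 2.3, 2.1])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / len(a) + vb / len(b)
        t_hand = (a.mean() - b.mean()) / math.sqrt(se2)
        df_hand = se2**2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        r = two_sample_t(a, b, variant="welch")
        assert r.statistic == pytest.approx(t_hand, rel=1e-12)
        assert r.df == pytest.approx(df_hand, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1, 2, 3])


class TestChiSquare:
    def test_proportional_table(self):
        r = chi_square([[10, 20], [20, 40]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        r = chi_square([[10, 0], [0, 10]])
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 1

    def test_df_of_2x3(self):
        assert chi_square([[5, 5, 5], [5, 5, 6]]).df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 0], [5, 5]])


class TestBenjaminiHochberg:
    def test_single_pvalue(self):
        r = benjamini_hochberg([0.04], alpha=0.05)
        assert r.significant == (True,)

    def test_all_ones(self):
        r = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not any(r.significant)
        assert all(a == 1.0 for a in r.adjusted_p)

    def test_matches_bruteforce_stepup_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            m = int(rng.integers(1, 7))
            p = np.round(rng.random(m), 3)
            r = benjamini_hochberg(p, alpha=0.05)
            assert list(r.significant) == bh_stepup_bruteforce(list(p), 0.05)

    def test_adjusted_monotone_in_raw_rank(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        r = benjamini_hochberg(p)
        order = np.argsort(p)
        adj_sorted = np.asarray(r.adjusted_p)[order]
        assert np.all(np.diff(adj_sorted) >= -1e-15)
        assert np.all(np.asarray(r.adjusted_p) >= p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, x).statistic == pytest.approx(1.0)
        assert spearman(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        r = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.statistic == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        r = anova_tukey([g, g, g])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in r.pairwise_p.values())

    def test_two_groups_equal_pooled_t(self):
        """With two groups, one-way ANOVA reproduces the pooled t-test:
        F = t^2 and the p-values agree."""
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        r_anova = anova_tukey([a, b])
        r_t = two_sample_t(a, b, variant="pooled")
        assert r_anova.statistic == pytest.approx(r_t.statistic**2, rel=1e-10)
        assert r_anova.p_value == pytest.approx(r_t.p_value, rel=1e-10)

    def test_log_transform_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            anova_tukey([[1.0, 2.0], [0.0, 3.0]], log_transform=True)

    def test_log_transform_applied(self):
        g1, g2 = [100.0, 120.0, 110.0], [800.0, 900.0, 850.0]
        r = anova_tukey([g1, g2], log_transform=True)
        expected = anova_tukey([np.log(g1), np.log(g2)])
        assert r.statistic == pytest.approx(expected.statistic)

    def test_equal_means_rarely_flagged(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(5, s, 30) for s in (1.0, 2.0, 3.0)]
        r = anova_tukey(groups)
        assert min(r.pairwise_p.values()) > 0.05


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        r = ols(0.03 * x, pd.DataFrame({"x": x}))
        assert r.coef("x") == pytest.approx(0.03, abs=1e-12)
        assert r.se("x") == pytest.approx(0.0, abs=1e-10)

    def test_hand_normal_equations(self):
        """4-point example solved by the normal equations."""
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        X = np.column_stack([np.ones(4), x])
        beta_hand = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hand
        s2 = resid @ resid / (4 - 2)
        se_hand = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        r = ols(y, pd.DataFrame({"x": x}))
        assert r.coef("x") == pytest.approx(beta_hand[1], rel=1e-12)
        assert r.se("x") == pytest.approx(se_hand, rel=1e-12)

    def test_rank_deficiency_names_column(self):
        x = np.arange(8, dtype=float)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            ols(np.ones(8), X)

    def test_adjustment_recovers_direct_effect(self):
        """When the outcome depends on x only, adding correlated covariates
        leaves the x coefficient unbiased (large-n sanity check)."""
        rng = np.random.default_rng(9)
        n = 4000
        t = rng.normal(size=n)
        x = 10 * t + rng.normal(size=n)
        age = 40 + 5 * t + rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        r = ols(y, pd.DataFrame({"x": x, "age": age}))
        assert r.coef("x") == pytest.approx(0.5, abs=0.01)


class TestRandomInterceptMeals:
    @staticmethod
    def _balanced_table(rng, n_subjects=40, sd_u=150.0, sd_e=100.0,
                        means=(537.0, 761.0, 568.0)):
        rows = []
        for i in range(n_subjects):
            u = rng.normal(0, sd_u)
            for day in (1, 2):
                for meal, mu in zip(("breakfast", "lunch", "dinner"), means):
                    rows.append({"subject": f"S{i}", "meal": meal,
                                 "kcal": mu + u + rng.normal(0, sd_e)})
        return pd.DataFrame(rows)

    def test_balanced_marginal_means_equal_sample_means(self):
        rng = np.random.default_rng(5)
        df = self._balanced_table(rng)
        res = random_intercept_meals(df)
        for meal in res.meals:
            sample_mean = df.loc[df["meal"] == meal, "kcal"].mean()
            assert res.marginal_means[meal] == pytest.approx(sample_mean, abs=1e-8)

    def test_balanced_contrast_matches_paired_t(self):
        """Under balance and compound symmetry the lunch-vs-breakfast Wald
        contrast equals a paired t-test on subject means (z vs t df)."""
        from scipy import stats as sps

        rng = np.random.default_rng(6)
        df = self._balanced_table(rng, n_subjects=120)
        res = random_intercept_meals(df)
        wide = df.groupby(["subject", "meal"])["kcal"].mean().unstack()
        t_stat, t_p = sps.ttest_rel(wide["lunch"], wide["breakfast"])
        key = ("breakfast", "lunch")
        assert res.pairwise_p[key] == pytest.approx(t_p, rel=0.1)

    def test_zero_between_subject_variance(self):
        """With no subject effect the between-subject component collapses to
        ~0 and the marginal means match the plain per-meal means."""
        rng = np.random.default_rng(7)
        df = self._balanced_table(rng, n_subjects=60, sd_u=0.0, sd_e=80.0)
        res = random_intercept_meals(df)
        assert res.var_between <= 0.05 * res.var_residual
        for meal in res.meals:
            assert res.marginal_means[meal] == pytest.approx(
                df.loc[df["meal"] == meal, "kcal"].mean(), rel=1e-4
            )

    def test_variance_component_recovery(self):
        """REML recovers the generating variance components at n=500."""
        rng = np.random.default_rng(8)
        df = self._balanced_table(rng, n_subjects=500, sd_u=200.0, sd_e=150.0)
        res = random_intercept_meals(df)
        assert res.var_between == pytest.approx(200.0**2, rel=0.15)
        assert res.var_residual == pytest.approx(150.0**2, rel=0.15)

    def test_missing_meal_category_rejected(self):
        df = pd.DataFrame(
            {"subject": ["a", "b"], "meal": ["lunch", "lunch"], "kcal": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            random_intercept_meals(df)
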
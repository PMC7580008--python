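"""Statistical procedures used by the survey analysis.

Thin, validated wrappers with uniform result objects around scipy and
statsmodels: two-sample t-tests (Welch by default), Pearson chi-square,
Benjamini-Hochberg FDR, Spearman rank correlation, one-way ANOVA with Tukey
HSD post-hoc (Tukey-Kramer SE for unequal n), OLS regression, and a
random-intercept linear mixed model for per-meal energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "FDRResult",
    "RegressionResult",
    "MixedModelResult",
    "two_sample_t",
    "chi_square",
    "benjamini_hochberg",
    "spearman",
    "anova_tukey",
    "ols",
    "random_intercept_meals",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    group_summaries: list[dict] = field(default_factory=list)
    pairwise_p: dict[tuple, float] | None = None


@dataclass(frozen=True)
class FDRResult:
    raw_p: tuple[float, ...]
    adjusted_p: tuple[float, ...]
    significant: tuple[bool, ...]
    alpha: float
    largest_significant_raw_p: float | None


@dataclass(frozen=True)
class RegressionResult:
    names: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    p_values: tuple[float, ...]
    n: int

    def coef(self, name: str) -> float:
        return self.coefficients[self.names.index(name)]

    def se(self, name: str) -> float:
        return self.standard_errors[self.names.index(name)]

    def p(self, name: str) -> float:
        return self.p_values[self.names.index(name)]


@dataclass(frozen=True)
class MixedModelResult:
    meals: tuple[str, ...]
    marginal_means: dict[str, float]
    standard_errors: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    var_between: float
    var_residual: float
    n_subjects: int


def _summary(values, label) -> dict:
    a = np.asarray(values, dtype=float)
    return {"group": label, "n": a.size, "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)) if a.size > 1 else float("nan")}


def two_sample_t(group_a, group_b, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t-test; ``variant`` is "welch" (default) or "pooled"."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_summaries=[_summary(a, "A"), _summary(b, "B")],
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total; expected counts undefined")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected count <= 0")
    return TestResult(statistic=float(stat), df=float(dof), p_value=float(p))


def benjamini_hochberg(pvals, alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR control.

    Flags the k smallest p-values where k is the largest index with
    p_(k) <= k * alpha / m; adjusted p_(i) = min_{j>=i} m p_(j) / j, capped
    at 1.  Results are returned in the input order.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    largest = float(p[reject].max()) if reject.any() else None
    return FDRResult(
        raw_p=tuple(float(x) for x in p),
        adjusted_p=tuple(float(x) for x in adjusted),
        significant=tuple(bool(x) for x in reject),
        alpha=alpha,
        largest_significant_raw_p=largest,
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (ties averaged), p via the t approximation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(xa, ya)
    return TestResult(statistic=float(rho), df=float(xa.size - 2), p_value=float(p))


def anova_tukey(groups, log_transform: bool = False) -> TestResult:
    """One-way ANOVA with Tukey HSD post-hoc p-values.

    With ``log_transform`` the analysis runs on ln(values) (all values must
    be positive); pairwise SEs use the Tukey-Kramer form for unequal n.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if log_transform:
        if any((a <= 0).any() for a in arrays):
            raise ValueError("log transform requires strictly positive values")
        arrays = [np.log(a) for a in arrays]
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairwise = {
        (i, j): float(hsd.pvalue[i, j])
        for i in range(len(arrays))
        for j in range(i + 1, len(arrays))
    }
    return TestResult(
        statistic=float(f),
        df=(float(len(arrays) - 1), float(sum(a.size for a in arrays) - len(arrays))),
        p_value=float(p),
        group_summaries=[_summary(a, i) for i, a in enumerate(arrays)],
        pairwise_p=pairwise,
    )


def ols(y, X: pd.DataFrame) -> RegressionResult:
    """Least-squares regression of y on the columns of X, with an intercept.

    Raises on rank deficiency, naming the collinear column(s).
    """
    X = pd.DataFrame(X).astype(float)
    ya = np.asarray(y, dtype=float)
    if ya.size <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = []
        for col in X.columns:
            reduced = design.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(str(col))
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    fit = sm.OLS(ya, design).fit()
    return RegressionResult(
        names=tuple(design.columns),
        coefficients=tuple(float(b) for b in fit.params),
        standard_errors=tuple(float(s) for s in fit.bse),
        p_values=tuple(float(p) for p in fit.pvalues),
        n=int(ya.size),
    )


def random_intercept_meals(long_table: pd.DataFrame) -> MixedModelResult:
    """Compare per-meal energy with a subject random-intercept linear model.

    ``long_table`` needs columns ``subject``, ``meal`` and ``kcal`` (one row
    per subject-day-meal observation).  Fits, by REML,

        kcal_ij = mu + meal_j + u_i + e_ij,   u_i ~ N(0, sigma_u^2)

    using cell-means coding so the fixed effects are the per-meal marginal
    means directly.  Pairwise meal contrasts use Wald z tests.
    """
    df = pd.DataFrame(long_table)
    for col in ("subject", "meal", "kcal"):
        if col not in df.columns:
            raise ValueError(f"long table missing column {col!r}")
    df = df.dropna(subset=["kcal"])
    meals = tuple(sorted(df["meal"].unique()))
    counts = df["meal"].value_counts()
    if any(counts.get(m, 0) == 0 for m in meals) or len(meals) < 2:
        raise ValueError("each meal category needs at least one observation")
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")

    model = smf.mixedlm("kcal ~ 0 + C(meal)", data=df, groups=df["subject"])
    fit = model.fit(reml=True)

    names = {m: f"C(meal)[{m}]" for m in meals}
    means = {m: float(fit.params[names[m]]) for m in meals}
    ses = {m: float(fit.bse[names[m]]) for m in meals}
    cov = fit.cov_params()
    pairwise = {}
    for i, a in enumerate(meals):
        for b in meals[i + 1:]:
            diff = means[a] - means[b]
            var = (
                cov.loc[names[a], names[a]]
                + cov.loc[names[b], names[b]]
                - 2 * cov.loc[names[a], names[b]]
            )
            z = diff / math.sqrt(var)
            pairwise[(a, b)] = float(2 * sps.norm.sf(abs(z)))
    return MixedModelResult(
        meals=meals,
        marginal_means=means,
        standard_errors=ses,
        pairwise_p=pairwise,
        var_between=float(np.asarray(fit.cov_re)[0, 0]),
        var_residual=float(fit.scale),
        n_subjects=int(df["subject"].nunique()),
    )
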
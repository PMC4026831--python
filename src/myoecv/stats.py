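"""Cohort statistics: group comparisons, ANOVA with Bonferroni-adjusted
pairwise contrasts, chi-square proportion tests and uni/multivariate
linear regression of ECV on covariates."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "RegressionResult",
    "compare_groups",
    "anova_bonferroni",
    "proportion_test",
    "regress_ecv",
]

ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    group_summaries: dict = field(default_factory=dict)
    pairwise_p: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RegressionResult:
    model_type: str  # {univariate, multivariate}
    coefficients: dict
    p_values: dict
    correlations: dict = field(default_factory=dict)  # univariate R only
    condition_flag: bool = False
    n: int = 0


def _two_group_arrays(
    table: pd.DataFrame, value_column: str, group_column: str
) -> tuple[str, np.ndarray, str, np.ndarray]:
    sub = table[[value_column, group_column]].dropna()
    levels = sorted(sub[group_column].unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    arrays = [
        sub.loc[sub[group_column] == g, value_column].to_numpy(dtype=float)
        for g in levels
    ]
    for g, arr in zip(levels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return levels[0], arrays[0], levels[1], arrays[1]


def compare_groups(
    table: pd.DataFrame,
    value_column: str,
    group_column: str,
    method: str = "student_t",
) -> TestResult:
    """Two-sided two-group comparison with mean +/- SD summaries.

    ``method``: pooled-variance Student's t (default), Welch's t, or the
    Mann-Whitney U test as the non-parametric fallback.
    """
    g1, x1, g2, x2 = _two_group_arrays(table, value_column, group_column)
    if method == "student_t":
        stat, p = sps.ttest_ind(x1, x2, equal_var=True)
        df = x1.size + x2.size - 2
    elif method == "welch_t":
        res = sps.ttest_ind(x1, x2, equal_var=False)
        stat, p = res.statistic, res.pvalue
        df = float(res.df)
    elif method == "mann_whitney":
        stat, p = sps.mannwhitneyu(x1, x2, alternative="two-sided")
        df = None
    else:
        raise ValueError(f"unknown method {method!r}")
    summaries = {
        g1: {"n": int(x1.size), "mean": float(x1.mean()), "sd": float(x1.std(ddof=1))},
        g2: {"n": int(x2.size), "mean": float(x2.mean()), "sd": float(x2.std(ddof=1))},
    }
    return TestResult(
        test_name=method,
        statistic=float(stat),
        p_value=float(p),
        df=df,
        group_summaries=summaries,
    )


def anova_bonferroni(
    table: pd.DataFrame, value_column: str, factor: str
) -> TestResult:
    """One-way ANOVA plus Bonferroni-adjusted pairwise Student t-tests.

    Each pairwise p is multiplied by the number of pairs and capped at 1.
    """
    sub = table[[value_column, factor]].dropna()
    levels = sorted(sub[factor].unique(), key=str)
    if len(levels) < 3:
        raise ValueError("ANOVA requires at least three factor levels")
    groups = {
        g: sub.loc[sub[factor] == g, value_column].to_numpy(dtype=float)
        for g in levels
    }
    for g, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"level {g!r} has fewer than 2 observations")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        stat, p = 0.0, 1.0  # all values identical: no effect, by convention
    else:
        stat, p = sps.f_oneway(*arrays)
        if not np.isfinite(stat):  # zero within-group variance
            means = [arr.mean() for arr in arrays]
            stat, p = (0.0, 1.0) if np.ptp(means) == 0 else (np.inf, 0.0)
    n_pairs = len(levels) * (len(levels) - 1) // 2
    pairwise = {}
    for a, b in combinations(levels, 2):
        if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0 and (
            groups[a].mean() == groups[b].mean()
        ):
            raw = 1.0
        else:
            _, raw = sps.ttest_ind(groups[a], groups[b], equal_var=True)
            if not np.isfinite(raw):  # both groups constant, means differ
                raw = 0.0
        pairwise[(a, b)] = min(1.0, float(raw) * n_pairs)
    summaries = {
        g: {"n": int(arr.size), "mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}
        for g, arr in groups.items()
    }
    return TestResult(
        test_name="anova_bonferroni",
        statistic=float(stat),
        p_value=float(p),
        df=float(len(levels) - 1),
        group_summaries=summaries,
        pairwise_p=pairwise,
    )


def proportion_test(counts, correction: bool = False) -> TestResult:
    """Chi-square test of homogeneity on a 2x2 table.

    Continuity correction is off by default; enable with ``correction``.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _exp = sps.chi2_contingency(obs, correction=correction)
    return TestResult(
        test_name="chi_square",
        statistic=float(chi2),
        p_value=float(p),
        df=float(df),
        group_summaries={
            "proportions": (obs[:, 0] / obs.sum(axis=1)).tolist(),
        },
    )


_CONDITION_LIMIT = 1e8


def regress_ecv(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    multivariate: bool = False,
    alpha: float = ALPHA,
) -> RegressionResult:
    """Linear regression of the response on covariates.

    Univariate mode reports per-predictor Pearson R, slope and p.
    Multivariate mode first screens predictors univariately and jointly
    fits those with univariate p < ``alpha`` (all predictors if none
    pass, so the caller always gets a model).  Binary/string predictors
    are 0/1 encoded.  A condition number above 1e8 sets
    ``condition_flag``.
    """
    data = table[[response] + predictors].dropna().copy()
    y = data[response].to_numpy(dtype=float)
    enc = {}
    for pred in predictors:
        col = data[pred]
        if col.dtype == object or col.dtype == bool:
            levels = sorted(col.unique(), key=str)
            if len(levels) > 2:
                raise ValueError(f"predictor {pred!r} has >2 categorical levels")
            enc[pred] = (col == levels[-1]).to_numpy(dtype=float)
        else:
            enc[pred] = col.to_numpy(dtype=float)

    correlations, uni_p, uni_coef = {}, {}, {}
    for pred, x in enc.items():
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {pred!r} is constant")
        r, p = sps.pearsonr(x, y)
        correlations[pred] = float(r)
        uni_p[pred] = float(p)
        slope = float(np.polyfit(x, y, 1)[0])
        uni_coef[pred] = slope

    if not multivariate:
        return RegressionResult(
            model_type="univariate",
            coefficients=uni_coef,
            p_values=uni_p,
            correlations=correlations,
            n=y.size,
        )

    selected = [p_ for p_ in predictors if uni_p[p_] < alpha] or list(predictors)
    X = sm.add_constant(np.column_stack([enc[p_] for p_ in selected]))
    model = sm.OLS(y, X).fit()
    coefficients = {"const": float(model.params[0])}
    p_values = {"const": float(model.pvalues[0])}
    for i, pred in enumerate(selected, start=1):
        coefficients[pred] = float(model.params[i])
        p_values[pred] = float(model.pvalues[i])
    return RegressionResult(
        model_type="multivariate",
        coefficients=coefficients,
        p_values=p_values,
        correlations=correlations,
        condition_flag=bool(np.linalg.cond(X) > _CONDITION_LIMIT),
        n=y.size,
    )
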
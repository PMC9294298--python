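"""Statistical battery for dynamics metrics and ROI-level CAP values.

Covers the designs used to compare CAP metrics across frequency bands and
between diagnostic groups: one-way repeated-measures ANOVA for the band
factor, a two-level mixed (split-plot) group-by-band ANOVA with age/sex/
mean-FD covariates, paired and covariate-adjusted two-sample t-tests, a
permutation test for non-Gaussian head-motion summaries, the chi-square
cross-table test, and Bonferroni / Benjamini-Hochberg multiplicity control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "repeated_measures_anova",
    "mixed_anova",
    "paired_t",
    "two_sample_t",
    "two_sample_t_adjusted",
    "two_sample_t_from_stats",
    "permutation_test",
    "chi_square_table",
    "bonferroni",
    "fdr_bh",
]


@dataclass(frozen=True)
class StatResult:
    effect: str
    statistic: float
    df: tuple[float, ...] | float
    p: float
    p_adjusted: float | None = None
    correction: str = "none"


def repeated_measures_anova(values: np.ndarray) -> StatResult:
    """One-way within-subject ANOVA: subjects x conditions, complete matrix.

    Classic decomposition: SS_cond on (b-1) df against the subject-by-
    condition residual on (n-1)(b-1) df.  A matrix with zero residual *and*
    zero condition variation (all cells equal) reports F=0, p=1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not allowed (no imputation)")
    n, b = x.shape
    grand = x.mean()
    cond_mean = x.mean(axis=0)
    subj_mean = x.mean(axis=1)
    ss_cond = n * np.sum((cond_mean - grand) ** 2)
    resid = x - subj_mean[:, None] - cond_mean[None, :] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = b - 1, (n - 1) * (b - 1)
    if ss_err == 0.0:
        if ss_cond == 0.0:
            return StatResult("band", 0.0, (df1, df2), 1.0)
        return StatResult("band", np.inf, (df1, df2), 0.0)
    f = (ss_cond / df1) / (ss_err / df2)
    return StatResult("band", float(f), (df1, df2), float(st.f.sf(f, df1, df2)))


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray | None:
    """Numeric, centered covariate block ('sex' coded 0/1 before centering)."""
    if covariates is None:
        return None
    cov = covariates.copy()
    for c in cov.columns:
        if cov[c].dtype == object or str(cov[c].dtype) == "category":
            levels = sorted(cov[c].astype(str).unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {c!r} has more than two levels")
            cov[c] = (cov[c].astype(str) == levels[-1]).astype(float)
    block = cov.to_numpy(dtype=float)
    if block.shape[0] != n:
        raise ValueError("covariate rows do not match subjects")
    return block - block.mean(axis=0)


def _ols_coef_test(y, design, effect, coef_index=1, as_f=False) -> StatResult:
    model = sm.OLS(y, design)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design (collinear covariates?)")
    fit = model.fit()
    t = fit.tvalues[coef_index]
    p = fit.pvalues[coef_index]
    if as_f:
        return StatResult(effect, float(t**2), (1, float(fit.df_resid)), float(p))
    return StatResult(effect, float(t), float(fit.df_resid), float(p))


def mixed_anova(
    values: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict[str, StatResult]:
    """Two-group x two-band split-plot ANOVA with fixed nuisance covariates.

    ``values`` is subjects x 2 (one column per band); ``group`` the
    between-subject factor.  With only two within-subject levels the design
    decomposes exactly: the group main effect is the group test on subject
    means, and the band main effect / interaction are the intercept and group
    tests on within-subject band differences, all with centered covariates so
    main effects are evaluated at the covariate mean.  Returns StatResults
    keyed 'group', 'band', 'group x band' with F = t^2 on (1, df) df.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("values must be subjects x 2 bands")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not allowed")
    group = np.asarray(group)
    ugroups = np.unique(group)
    if ugroups.size != 2:
        raise ValueError(f"need exactly two groups, got {ugroups.tolist()}")
    g = (group == ugroups[-1]).astype(float)
    g = g - g.mean()  # centered contrast: intercepts estimate averages
    n = x.shape[0]
    cov = _design_matrix(covariates, n)
    blocks = [np.ones(n), g]
    if cov is not None:
        blocks.extend(cov.T)
    design = np.column_stack(blocks)

    subj_mean = x.mean(axis=1)
    band_diff = x[:, 1] - x[:, 0]
    return {
        "group": _ols_coef_test(subj_mean, design, "group", 1, as_f=True),
        "band": _ols_coef_test(band_diff, design, "band", 0, as_f=True),
        "group x band": _ols_coef_test(
            band_diff, design, "group x band", 1, as_f=True
        ),
    }


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-tailed paired t-test on per-subject differences."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.allclose(x, y):
        return StatResult("paired", 0.0, float(x.size - 1), 1.0)
    res = st.ttest_rel(x, y)
    return StatResult("paired", float(res.statistic), float(x.size - 1),
                      float(res.pvalue))


def two_sample_t(x: np.ndarray, y: np.ndarray, equal_var: bool = False) -> StatResult:
    """Two-tailed two-sample t-test (Welch by default)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.std(x) == 0 and np.std(y) == 0 and np.mean(x) == np.mean(y):
        return StatResult("group", 0.0, float(x.size + y.size - 2), 1.0)
    res = st.ttest_ind(x, y, equal_var=equal_var)
    return StatResult("group", float(res.statistic), float(res.df), float(res.pvalue))


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> StatResult:
    """Two-sample t-test from printed summary statistics (Welch by default)."""
    res = st.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                  equal_var=equal_var)
    df = n1 + n2 - 2 if equal_var else _welch_df(sd1, n1, sd2, n2)
    return StatResult("group", float(res.statistic), float(df), float(res.pvalue))


def _welch_df(sd1: float, n1: int, sd2: float, n2: int) -> float:
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def two_sample_t_adjusted(
    x: np.ndarray,
    y: np.ndarray,
    covariates_x: pd.DataFrame | None = None,
    covariates_y: pd.DataFrame | None = None,
) -> StatResult:
    """Group difference with nuisance covariates regressed out.

    Realized as the t-test on the group coefficient of the linear model
    outcome ~ group + covariates.  Without covariates it falls back to the
    plain two-sample t-test.
    """
    if covariates_x is None and covariates_y is None:
        return two_sample_t(x, y)
    if covariates_x is None or covariates_y is None:
        raise ValueError("covariates must be given for both groups or neither")
    outcome = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    cov = pd.concat([covariates_x, covariates_y], ignore_index=True)
    g = np.concatenate([np.zeros(len(x)), np.ones(len(y))])
    block = _design_matrix(cov, outcome.size)
    design = np.column_stack([np.ones(outcome.size), g - g.mean(), *block.T])
    return _ols_coef_test(outcome, design, "group", 1)


def permutation_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> StatResult:
    """Two-sided permutation test on the difference of group means.

    p = (1 + #{permuted |diff| >= observed}) / (1 + n_perm); the add-one
    estimator keeps p strictly positive.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([x, y])
    nx = x.size
    observed = abs(x.mean() - y.mean())
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: each row of `order` is one permutation
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm = pooled[order]
    diffs = np.abs(perm[:, :nx].mean(axis=1) - perm[:, nx:].mean(axis=1))
    p = (1 + int(np.sum(diffs >= observed - 1e-12))) / (1 + n_perm)
    return StatResult("group", float(observed), float(n_perm), float(p))


def chi_square_table(table: np.ndarray) -> StatResult:
    """Pearson chi-square on a 2x2 contingency table, no continuity correction."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = st.chi2_contingency(t, correction=False)
    return StatResult("sex", float(res.statistic), float(res.dof), float(res.pvalue))


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m); m defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
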
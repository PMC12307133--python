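"""Group statistics: ANOVA/ANCOVA, region screening, correlations,
multiple-testing control, and the velocity-ALPS association.

ANCOVA is implemented as a nested linear-model F test (covariates-only
versus covariates + group), which is the classical sequential
sums-of-squares comparison for a single factor after adjustment.  The
velocity-ALPS association is reported as the partial correlation of
velocity with the ALPS index given age, sex and education.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def anova_from_summary(summaries: Sequence[tuple]) -> tuple:
    """One-way ANOVA F and p from per-group (n, mean, sd) summaries.

    Between/within mean squares are rebuilt from the summaries, with
    df = (k-1, N-k); sd is the sample standard deviation (ddof=1).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([s[0] for s in summaries], dtype=float)
    m = np.array([s[1] for s in summaries], dtype=float)
    sd = np.array([s[2] for s in summaries], dtype=float)
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    N = n.sum()
    k = len(summaries)
    grand = np.sum(n * m) / N
    ss_between = np.sum(n * (m - grand) ** 2)
    ss_within = np.sum((n - 1) * sd**2)
    F = (ss_between / (k - 1)) / (ss_within / (N - k))
    p = stats.f.sf(F, k - 1, N - k)
    return float(F), float(p)


def anova_raw(values: np.ndarray, groups: np.ndarray) -> tuple:
    """One-way ANOVA on raw data (scipy), returned as (F, p)."""
    levels = pd.unique(np.asarray(groups))
    samples = [np.asarray(values)[np.asarray(groups) == g] for g in levels]
    F, p = stats.f_oneway(*samples)
    return float(F), float(p)


def chisq_from_counts(table) -> tuple:
    """Pearson chi-square of independence on an r x c count table.

    No continuity correction; df = (r-1)(c-1).
    """
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def _design(groups: np.ndarray, covariates: Optional[pd.DataFrame]):
    """Covariate design (with intercept) and group dummy columns."""
    n = len(groups)
    cov_cols = [np.ones(n)]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or str(col.dtype).startswith("category"):
                levels = pd.unique(col)
                for lev in levels[1:]:
                    cov_cols.append((col == lev).to_numpy(float))
            else:
                cov_cols.append(col.to_numpy(float))
    Xc = np.column_stack(cov_cols)
    levels = pd.unique(np.asarray(groups))
    if len(levels) > 1:
        dummies = np.column_stack(
            [(np.asarray(groups) == g).astype(float) for g in levels[1:]]
        )
    else:
        dummies = np.empty((n, 0))
    return Xc, dummies


def ancova_group_test(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
) -> tuple:
    """F test for the group factor after covariate adjustment.

    Nested-model comparison: reduced = covariates (+ intercept), full =
    reduced + group dummies.  Returns (F, p).
    """
    y = np.asarray(values, dtype=float)
    Xc, dummies = _design(groups, covariates)
    Xf = np.column_stack([Xc, dummies])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("rank-deficient design")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_r, rss_f = rss(Xc), rss(Xf)
    df_num = dummies.shape[1]
    df_den = len(y) - Xf.shape[1]
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    p = stats.f.sf(F, df_num, df_den)
    return float(F), float(p)


def region_selection(
    cohort: pd.DataFrame,
    region_cols: Optional[Sequence[str]] = None,
    q_threshold: float = 0.05,
    group_col: str = "diagnosis",
    covariate_cols: Sequence[str] = ("age", "sex", "education_years"),
) -> pd.DataFrame:
    """Screen regions for group differences: per-region ANCOVA + BH FDR.

    Returns a table (region, F, p, q, selected) where selected means
    FDR-adjusted p < q_threshold.  Mirrors restricting downstream driving-
    score analysis to regions with significant group differences.
    """
    if region_cols is None:
        region_cols = [c for c in cohort.columns if c.startswith("vel_")]
    cov = cohort[list(covariate_cols)] if covariate_cols else None
    groups = cohort[group_col].to_numpy()
    rows = []
    for col in region_cols:
        F, p = ancova_group_test(cohort[col].to_numpy(), groups, cov)
        rows.append((col.removeprefix("vel_"), F, p))
    out = pd.DataFrame(rows, columns=["region", "F", "p"])
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["selected"] = out["q"] < q_threshold
    return out


def bonferroni_posthoc(p_values, m: Optional[int] = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    m = len(p) if m is None else int(m)
    return np.minimum(p * m, 1.0)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    return multipletests(p, method="fdr_bh")[1]


def correlate(x, y, method: str = "auto", normality_alpha: float = 0.05) -> tuple:
    """Correlation between a cognitive score and a regional velocity.

    method "pearson" or "spearman"; "auto" uses Pearson when both variables
    pass a Shapiro-Wilk normality screen at ``normality_alpha``, Spearman
    otherwise.  Returns (r, p, method_used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if method == "auto":
        normal = (
            stats.shapiro(x).pvalue > normality_alpha
            and stats.shapiro(y).pvalue > normality_alpha
        )
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), method


def regression_velocity_alps(
    velocity,
    alps,
    covariates: Optional[pd.DataFrame] = None,
) -> tuple:
    """Partial association of regional velocity with the ALPS index given
    age/sex/education.

    Both variables are residualized on the covariates (with intercept); the
    correlation of the residuals is the reported association coefficient r,
    with p from a t test on n - 2 - k degrees of freedom.  With covariates
    orthogonal to both variables this reduces to the simple correlation.
    """
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(alps, dtype=float)
    if np.ptp(a) == 0:
        raise ValueError("ALPS index is constant")
    if np.ptp(v) == 0:
        raise ValueError("velocity is constant")
    n = len(v)
    if covariates is not None:
        Xc, _ = _design(np.zeros(n), covariates)
    else:
        Xc = np.ones((n, 1))
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient covariate design")

    def residualize(y):
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        return y - Xc @ beta

    rv, ra = residualize(v), residualize(a)
    r = float(np.dot(rv, ra) / np.sqrt(np.dot(rv, rv) * np.dot(ra, ra)))
    k = Xc.shape[1] - 1
    dof = n - 2 - k
    t = r * np.sqrt(dof / max(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(abs(t), dof)
    return r, float(p)


def velocity_alps_table(
    cohort: pd.DataFrame,
    region_cols: Optional[Sequence[str]] = None,
    covariate_cols: Sequence[str] = ("age", "sex", "education_years"),
    alps_col: str = "alps_index",
) -> pd.DataFrame:
    """Velocity-ALPS partial associations per region, FDR-adjusted."""
    if region_cols is None:
        region_cols = [c for c in cohort.columns if c.startswith("vel_")]
    cov = cohort[list(covariate_cols)] if covariate_cols else None
    rows = []
    for col in region_cols:
        r, p = regression_velocity_alps(cohort[col], cohort[alps_col], cov)
        rows.append((col.removeprefix("vel_"), r, p))
    out = pd.DataFrame(rows, columns=["region", "r", "p"])
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out
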
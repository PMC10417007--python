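"""Cohort-level statistics for per-subject mean VTI.

Reproduces the study-style analysis: descriptive group summaries,
demographic homogeneity tests (Welch t / one-way F for age, chi-squared
or Fisher's exact for sex composition), an ordinary least-squares model
of mean VTI on group with age as covariate, and Tukey–Kramer adjusted
pairwise contrasts of the age-adjusted group means with simultaneous
95 % confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

REQUIRED_COLUMNS = ("subject_id", "group", "onset", "sex", "age", "mean_vti")

__all__ = [
    "REQUIRED_COLUMNS",
    "ContrastResult",
    "VtiModelFit",
    "validate_cohort_table",
    "describe_groups",
    "fit_vti_model",
    "tukey_contrasts",
    "demographics_tests",
]


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise contrast of age-adjusted group means."""

    group_a: str
    group_b: str
    estimate: float
    lower: float
    upper: float
    p_adj: float

    @property
    def comparison(self) -> str:
        return f"{self.group_a}-{self.group_b}"


@dataclass
class VtiModelFit:
    """OLS fit of mean VTI on group indicators plus age.

    ``params`` holds the coefficients in the order (intercept, group
    effects vs the first group, age); ``cov`` their covariance matrix.
    """

    groups: list[str]
    params: np.ndarray
    cov: np.ndarray
    df_resid: int
    resid_var: float
    mean_age: float

    def adjusted_means(self) -> dict[str, float]:
        """Group means adjusted to the grand mean age (emmeans-style)."""
        out = {}
        for i, grp in enumerate(self.groups):
            l = self._mean_vector(i)
            out[grp] = float(l @ self.params)
        return out

    def _mean_vector(self, i: int) -> np.ndarray:
        k = len(self.groups)
        l = np.zeros(k + 1)
        l[0] = 1.0
        if i > 0:
            l[i] = 1.0
        l[-1] = self.mean_age
        return l


def validate_cohort_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if len(table) == 0:
        raise ValueError("cohort table is empty")


def describe_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, mean (SD) of age and mean VTI, plus an overall column.

    SDs are sample (n-1) standard deviations, the convention of clinical
    summary tables.
    """
    validate_cohort_table(table)
    rows = []
    groups = list(dict.fromkeys(table["group"]))
    for grp in [*groups, "all"]:
        sub = table if grp == "all" else table[table["group"] == grp]
        rows.append(
            {
                "group": grp,
                "n": len(sub),
                "age_mean": sub["age"].mean() if len(sub) else np.nan,
                "age_sd": sub["age"].std(ddof=1) if len(sub) > 1 else np.nan,
                "vti_mean": sub["mean_vti"].mean() if len(sub) else np.nan,
                "vti_sd": sub["mean_vti"].std(ddof=1) if len(sub) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def fit_vti_model(table: pd.DataFrame) -> VtiModelFit:
    """OLS of mean VTI on group indicators and age (treatment coding)."""
    validate_cohort_table(table)
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to fit the model")
    counts = table["group"].value_counts()
    empty = [g for g in groups if counts.get(g, 0) == 0]
    if empty:
        raise ValueError(f"groups without observations make the design rank-deficient: {empty}")

    n = len(table)
    k = len(groups)
    X = np.zeros((n, k + 1))
    X[:, 0] = 1.0
    for i, grp in enumerate(groups[1:], start=1):
        X[:, i] = (table["group"] == grp).to_numpy(dtype=float)
    X[:, -1] = table["age"].to_numpy(dtype=float)
    y = table["mean_vti"].to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (collinear group/age structure); "
            "check group sizes and age variation"
        )
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    res = sm.OLS(y, X).fit()
    s2 = float(res.mse_resid)
    # exact-tie data: rounding leaves ~1e-30 residual variance; clamp so the
    # degenerate case is handled explicitly rather than through 0/0 noise
    if s2 <= 1e-20 * (1.0 + float(y @ y) / n):
        s2 = 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return VtiModelFit(
        groups=groups,
        params=np.asarray(res.params),
        cov=s2 * xtx_inv,
        df_resid=int(res.df_resid),
        resid_var=s2,
        mean_age=float(table["age"].mean()),
    )


def tukey_contrasts(fit: VtiModelFit, alpha: float = 0.05) -> list[ContrastResult]:
    """Tukey–Kramer adjusted pairwise contrasts of age-adjusted means.

    For each pair the difference of adjusted means (evaluated at the
    grand mean age, where the age term cancels), its model-based standard
    error, the studentized-range adjusted p-value
    ``P(q_{k,df} >= sqrt(2) |t|)`` and simultaneous ``1 - alpha``
    confidence limits using the same critical value.
    """
    if fit.df_resid <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    k = len(fit.groups)
    q_crit = None
    if fit.resid_var > 0:
        q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, fit.df_resid))
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            l = fit._mean_vector(i) - fit._mean_vector(j)
            diff = float(l @ fit.params)
            se = float(np.sqrt(l @ fit.cov @ l))
            if se == 0.0:
                # exact-tie degenerate case (zero residual variance)
                p = 1.0 if abs(diff) < 1e-10 else 0.0
                results.append(ContrastResult(fit.groups[i], fit.groups[j], diff, diff, diff, p))
                continue
            t = diff / se
            p = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, fit.df_resid))
            half = q_crit / np.sqrt(2.0) * se
            results.append(
                ContrastResult(
                    fit.groups[i], fit.groups[j], diff, diff - half, diff + half, min(max(p, 0.0), 1.0)
                )
            )
    return results


def tukey_pvalue(fit: VtiModelFit, group_a: str, group_b: str) -> float:
    """Tukey-adjusted p-value for a single group pair (no CI computed)."""
    k = len(fit.groups)
    i, j = fit.groups.index(group_a), fit.groups.index(group_b)
    l = fit._mean_vector(i) - fit._mean_vector(j)
    diff = float(l @ fit.params)
    se = float(np.sqrt(l @ fit.cov @ l))
    if se == 0.0:
        return 1.0 if abs(diff) < 1e-10 else 0.0
    return float(sps.studentized_range.sf(np.sqrt(2.0) * abs(diff / se), k, fit.df_resid))


def max_q_statistic(fit: VtiModelFit) -> float:
    """Largest studentized-range statistic ``sqrt(2)|t|`` over all pairs.

    A replicate rejects some pairwise contrast at level ``alpha`` exactly
    when this exceeds the studentized-range critical value
    ``q_{k, df, 1-alpha}``; useful for family-wise error simulations
    without evaluating each pair's p-value.
    """
    k = len(fit.groups)
    best = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            l = fit._mean_vector(i) - fit._mean_vector(j)
            diff = float(l @ fit.params)
            se = float(np.sqrt(l @ fit.cov @ l))
            if se > 0:
                best = max(best, np.sqrt(2.0) * abs(diff / se))
    return best


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "comparison": [c.comparison for c in contrasts],
            "diff": [c.estimate for c in contrasts],
            "lcl": [c.lower for c in contrasts],
            "ucl": [c.upper for c in contrasts],
            "p_adj": [c.p_adj for c in contrasts],
        }
    )


def demographics_tests(table: pd.DataFrame) -> dict:
    """Homogeneity tests for age and sex composition across groups.

    Age: Welch t-test for two groups, one-way ANOVA F for more.  Sex:
    Pearson chi-squared when all expected counts are at least 5,
    otherwise Fisher's exact test (2x2 tables).
    """
    validate_cohort_table(table)
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ages = [table.loc[table["group"] == g, "age"].to_numpy() for g in groups]
    if len(groups) == 2:
        age_stat, age_p = sps.ttest_ind(ages[0], ages[1], equal_var=False)
        age_test = "welch_t"
    else:
        age_stat, age_p = sps.f_oneway(*ages)
        age_test = "anova_f"

    ct = pd.crosstab(table["sex"], table["group"]).to_numpy()
    if ct.shape[0] < 2 or ct.shape[1] < 2 or ct.sum(axis=0).min() == 0 or ct.sum(axis=1).min() == 0:
        raise ValueError("degenerate sex-by-group margins")
    chi2, chi_p, _, expected = sps.chi2_contingency(ct, correction=False)
    if (expected < 5).any() and ct.shape == (2, 2):
        _, sex_p = sps.fisher_exact(ct)
        sex_test = "fisher_exact"
        sex_stat = np.nan
    else:
        sex_p, sex_test, sex_stat = chi_p, "chi2", chi2
    return {
        "age_test": age_test,
        "age_stat": float(age_stat),
        "age_p": float(age_p),
        "sex_test": sex_test,
        "sex_stat": float(sex_stat) if np.isfinite(sex_stat) else None,
        "sex_p": float(sex_p),
    }
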
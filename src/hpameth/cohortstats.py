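"""Group-comparison statistics for the cohort characteristics table.

Continuous variables are gated by Shapiro-Wilk normality per group: when both
groups look normal (p >= 0.05) a Welch t-test is used, otherwise the
Kruskal-Wallis rank test. Categorical variables get a chi-squared test of
independence with Yates continuity correction (the R ``chisq.test`` default
for 2x2 tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "normality_gate", "compare_continuous", "compare_categorical", "table1"]


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t" | "kruskal-wallis" | "chi-squared"
    statistic: float
    p: float
    summary_case: str
    summary_control: str


def normality_gate(x, alpha: float = 0.05) -> bool:
    """True when a Shapiro-Wilk test does not reject normality (p >= alpha)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk supports 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        warnings.warn("constant vector; treating as non-normal")
        return False
    return bool(stats.shapiro(x).pvalue >= alpha)


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.1f} ({x.std(ddof=1):.1f})"


def compare_continuous(x_case, x_control, variable: str = "") -> GroupComparison:
    """Welch t-test when both groups pass the normality gate, else Kruskal-Wallis."""
    xc = np.asarray(x_case, dtype=float)
    xk = np.asarray(x_control, dtype=float)
    xc, xk = xc[~np.isnan(xc)], xk[~np.isnan(xk)]
    if xc.size < 2 or xk.size < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    both_constant = np.ptp(xc) == 0 and np.ptp(xk) == 0 and xc[0] == xk[0]
    if both_constant:
        # fully tied data carries no evidence of a difference
        return GroupComparison(variable, "kruskal-wallis", 0.0, 1.0, _mean_sd(xc), _mean_sd(xk))
    normal = np.ptp(xc) > 0 and np.ptp(xk) > 0 and normality_gate(xc) and normality_gate(xk)
    if normal:
        res = stats.ttest_ind(xc, xk, equal_var=False)
        test = "t"
    else:
        res = stats.kruskal(xc, xk)
        test = "kruskal-wallis"
    return GroupComparison(variable, test, float(res.statistic), float(res.pvalue), _mean_sd(xc), _mean_sd(xk))


def compare_categorical(table, variable: str = "", correction: bool = True) -> GroupComparison:
    """Chi-squared independence test on a 2x2 count table, Yates-corrected by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(t, correction=correction)
    n_case, n_ctrl = t[0].sum(), t[1].sum()
    return GroupComparison(
        variable,
        "chi-squared",
        float(res.statistic),
        float(res.pvalue),
        f"{int(t[0, 0])} ({100 * t[0, 0] / n_case:.1f})",
        f"{int(t[1, 0])} ({100 * t[1, 0] / n_ctrl:.1f})",
    )


def table1(
    pheno: pd.DataFrame,
    group: str,
    continuous: list[str],
    categorical: list[str],
) -> pd.DataFrame:
    """Cohort characteristics table: one comparison per clinical variable.

    ``group`` names a binary column (1 = case); categorical variables must be
    binary 0/1 columns, tabulated against the group.
    """
    g = pheno[group].astype(int)
    rows = []
    for var in continuous:
        x = pd.to_numeric(pheno[var])
        rows.append(compare_continuous(x[g == 1], x[g == 0], variable=var))
    for var in categorical:
        v = pheno[var].astype(int)
        tab = [
            [int(((g == 1) & (v == 1)).sum()), int(((g == 1) & (v == 0)).sum())],
            [int(((g == 0) & (v == 1)).sum()), int(((g == 0) & (v == 0)).sum())],
        ]
        rows.append(compare_categorical(tab, variable=var))
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "test": [r.test for r in rows],
            "statistic": [r.statistic for r in rows],
            "p": [r.p for r in rows],
            "cases": [r.summary_case for r in rows],
            "controls": [r.summary_control for r in rows],
        }
    )
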
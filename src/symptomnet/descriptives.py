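"""Group comparisons and reliabilities for the descriptive table.

Pearson chi-square (no continuity correction) for sex-by-category counts,
pooled-variance two-sample t-tests for continuous measures, and Cronbach's
alpha for scale reliability.  The uncorrected chi-square and pooled t are
the constructions that reproduce the published descriptive statistics from
the printed counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scales import ScaleSpec, gad7, phq9

__all__ = [
    "build_table_one",
    "chi_square",
    "cronbach_alpha",
    "pooled_t_test",
]


def chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    No Yates continuity correction.  Returns (statistic, df, p).  Requires
    at least a 2x2 table with all row and column margins positive.
    """
    T = np.asarray(table, dtype=np.float64)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(T < 0):
        raise ValueError("counts must be non-negative")
    if np.any(T.sum(axis=0) <= 0) or np.any(T.sum(axis=1) <= 0):
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(T, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pooled_t_test(x, y) -> tuple[float, int, float]:
    """Equal-variance (pooled) two-sample t-test; returns (t, df, p).

    Degenerate case: zero pooled variance with equal means gives t = 0,
    p = 1; with unequal means it is an error.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(total)).

    Sample (ddof=1) variances; requires >= 2 items, >= 2 rows, and a
    non-constant total score.
    """
    X = np.asarray(items, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows and 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


_CATEGORICAL = ["residence", "ethnicity", "family_type", "income_band", "only_child"]


def build_table_one(
    cohort: pd.DataFrame,
    gad_spec: ScaleSpec | None = None,
    phq_spec: ScaleSpec | None = None,
) -> pd.DataFrame:
    """Sex-stratified descriptive table.

    One row per category level with counts (percent of sex group), a
    chi-square statistic/p on the variable's first row; then mean (SD) rows
    with pooled t statistics for age and the GAD-7/PHQ-9 totals.
    Percentages are formatted to one decimal and statistics to two.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if "sex" not in cohort.columns:
        raise ValueError("cohort lacks a 'sex' column")
    gad_spec = gad_spec or gad7()
    phq_spec = phq_spec or phq9()
    male = cohort[cohort["sex"] == "male"]
    female = cohort[cohort["sex"] == "female"]
    rows = []
    for var in _CATEGORICAL:
        if var not in cohort.columns:
            continue
        levels = [
            lv for lv in pd.unique(cohort[var]) if pd.notna(lv)
        ]
        counts = np.array(
            [
                [(male[var] == lv).sum() for lv in levels],
                [(female[var] == lv).sum() for lv in levels],
            ]
        )
        stat, df, p = chi_square(counts)
        for i, lv in enumerate(levels):
            m, f = counts[0, i], counts[1, i]
            rows.append(
                {
                    "variable": var,
                    "level": str(lv),
                    "male": f"{m} ({100 * m / max(len(male), 1):.1f})",
                    "female": f"{f} ({100 * f / max(len(female), 1):.1f})",
                    "statistic": f"{stat:.2f}" if i == 0 else "",
                    "p": f"{p:.3f}" if i == 0 else "",
                }
            )
    continuous = {"age": cohort.get("age")}
    for label, spec in (("GAD-7", gad_spec), ("PHQ-9", phq_spec)):
        if all(i in cohort.columns for i in spec.items):
            continuous[label] = cohort[list(spec.items)].sum(axis=1)
    for label, series in continuous.items():
        if series is None:
            continue
        xm = series[cohort["sex"] == "male"]
        xf = series[cohort["sex"] == "female"]
        t, df, p = pooled_t_test(xm, xf)
        rows.append(
            {
                "variable": label,
                "level": "mean (SD)",
                "male": f"{xm.mean():.2f} ({xm.std(ddof=1):.2f})",
                "female": f"{xf.mean():.2f} ({xf.std(ddof=1):.2f})",
                "statistic": f"{t:.2f}",
                "p": f"{p:.3f}",
            }
        )
    return pd.DataFrame(rows)
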
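"""Reliability statistics: internal consistency and test-retest agreement.

Cronbach's alpha and corrected item-total correlations summarise internal
consistency of a form; Pearson r and ICC(2,1) summarise test-retest
performance.  ICC(2,1) is the two-way random-effects, absolute-agreement,
single-measurement coefficient — unlike Pearson r it is sensitive to a
systematic shift between occasions, which is why both are reported.
Conventional interpretive thresholds (> 0.80 good, 0.70-0.80 acceptable)
are a reporting convention, not enforced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bankio import ResponseMatrix

__all__ = ["cronbach_alpha", "test_retest", "RetestReport"]


def cronbach_alpha(data: ResponseMatrix | pd.DataFrame
                   ) -> tuple[float, pd.Series]:
    """Cronbach's alpha and corrected item-total correlations.

    Rows with any missing response are dropped (listwise).  The corrected
    item-total correlation for an item excludes that item from the total.
    """
    frame = data.responses if isinstance(data, ResponseMatrix) else data
    frame = frame.dropna()
    if frame.shape[1] < 2:
        raise ValueError("alpha needs >= 2 items")
    if len(frame) < 30:
        import warnings
        warnings.warn(f"only {len(frame)} listwise-complete rows", stacklevel=2)
    X = frame.to_numpy(dtype=float)
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    total = X.sum(axis=1)
    corrected = {}
    for j, col in enumerate(frame.columns):
        rest = total - X[:, j]
        corrected[col] = float(np.corrcoef(X[:, j], rest)[0, 1])
    return float(alpha), pd.Series(corrected, name="corrected_item_total")


@dataclass(frozen=True)
class RetestReport:
    pearson_r: float
    pearson_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    n: int


def test_retest(scores_t1, scores_t2, ci_level: float = 0.95) -> RetestReport:
    """Pearson r and ICC(2,1) with confidence intervals for paired scores.

    ICC(2,1) is computed from the two-way person x occasion ANOVA mean
    squares (McGraw & Wong), with the standard F-distribution confidence
    bounds; the Pearson CI uses the Fisher z transformation.
    """
    x = np.asarray(scores_t1, dtype=float)
    y = np.asarray(scores_t2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired score vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")

    r = float(np.corrcoef(x, y)[0, 1]) if (x.std() > 0 and y.std() > 0) else float("nan")
    alpha = 1.0 - ci_level
    if np.isfinite(r) and abs(r) < 1:
        z = np.arctanh(r)
        half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        r_ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        r_ci = (r, r)

    # two-way ANOVA mean squares, k = 2 occasions
    k = 2
    M = np.column_stack([x, y])
    grand = M.mean()
    person_means = M.mean(axis=1)
    occ_means = M.mean(axis=0)
    ss_rows = k * np.sum((person_means - grand) ** 2)
    ss_cols = n * np.sum((occ_means - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        raise ValueError("zero between-person variance; ICC undefined")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom > 0 else float("nan")

    # F-based CI (McGraw & Wong 1996, ICC(A,1))
    if mse > 0:
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        v = ((a * msc + b * mse) ** 2 /
             ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_star = msr / mse
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (n * (msr - f_l * mse) /
                 (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_u * msr - mse) /
                 (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        icc_ci = (float(lower), float(upper))
    else:
        icc_ci = (icc, icc)

    return RetestReport(pearson_r=r, pearson_ci=r_ci, icc=icc,
                        icc_ci=icc_ci, n=n)
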
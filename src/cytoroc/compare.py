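"""Between-group hypothesis tests: Mann-Whitney U, unpaired t, chi-square.

The marker distributions are compared between the suboptimal and optimal
cytoreduction groups. Rather than gating the choice of test on a normality
pre-test, both the Mann-Whitney U (normal approximation, tie-corrected, with
continuity correction) and the unpaired t (Welch by default) are always
reported, labelled. Categorical covariate tables use the Pearson chi-square
without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n_x": self.n_x,
            "n_y": self.n_y,
        }


def _clean(x, name) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError(f"{name} must be a nonempty 1-D sequence")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    return x


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U for the first sample.

    U counts pairs where x beats y, ties 1/2, so U/(n_x*n_y) equals the AUC
    of x-as-positives vs y-as-negatives. The p-value uses the normal
    approximation with tie-corrected variance and continuity correction; if
    every pooled value is identical the test is vacuous (U = n_x*n_y/2,
    p = 1).
    """
    x = _clean(x, "x")
    y = _clean(y, "y")
    n_x, n_y = len(x), len(y)
    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult(n_x * n_y / 2.0, 1.0, "mann-whitney-u", n_x, n_y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-u", n_x, n_y)


def t_test_unpaired(x, y, welch: bool = True) -> TestResult:
    """Two-sided unpaired t-test (Welch by default, pooled-variance otherwise)."""
    x = _clean(x, "x")
    y = _clean(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    method = "welch-t" if welch else "pooled-t"
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, method, len(x), len(y))
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return TestResult(float(res.statistic), float(res.pvalue), method, len(x), len(y))


def chi_square_test(table) -> TestResult:
    """Pearson chi-square on an r x c count table, no continuity correction.

    Errors loudly on any zero expected count (no Fisher fallback).
    """
    table = np.asarray(table, float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (table < 0).any() or not np.isfinite(table).all():
        raise ValueError("counts must be finite and non-negative")
    expected = stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise ValueError("all expected counts must be > 0")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p), f"chi-square(df={dof})", int(table.sum()), 0)
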
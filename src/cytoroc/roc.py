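"""ROC curves, AUC (two routes), Youden-optimal cutoffs and AUC intervals.

The cut-off point for every marker and combined score is chosen from the
empirical ROC curve by maximizing Youden's J = sensitivity + specificity - 1.
Candidate cutoffs are the midpoints between consecutive distinct pooled
values (the published cut-offs carry midpoint-style extra decimals, e.g.
248.55, 22.895), with ties in J broken toward the smaller cutoff, i.e.
toward higher sensitivity — the preferable error direction when the positive
call flags patients at risk of suboptimal debulking.

The AUC is computed both as the trapezoidal area under the empirical curve
and as the normalized Mann-Whitney statistic U/(n_pos*n_neg) with ties
counted 1/2; the two are algebraically identical and the second serves as an
independent oracle for the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diagnostics import _check_values_labels


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC trace.

    ``thresholds`` ascend from ``-inf`` (everyone test-positive: tpr=fpr=1)
    to ``+inf`` (nobody: tpr=fpr=0); ``tpr``/``fpr`` are aligned and
    non-increasing.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def finite_thresholds(self) -> np.ndarray:
        return self.thresholds[np.isfinite(self.thresholds)]


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    if len(distinct) < 2:
        # degenerate pooled sample: the single value itself is the only
        # usable cutoff (every patient ties, J = 0)
        return distinct.astype(float)
    return (distinct[:-1] + distinct[1:]) / 2.0


def roc_curve(values, labels) -> RocCurve:
    """Empirical ROC over midpoint candidate thresholds plus +/-inf anchors."""
    values, pos = _check_values_labels(values, labels)
    n_pos = int(pos.sum())
    n_neg = len(values) - n_pos
    cand = _candidate_thresholds(values)
    thresholds = np.concatenate(([-np.inf], cand, [np.inf]))
    # test-positive iff value > threshold
    pos_vals = np.sort(values[pos])
    neg_vals = np.sort(values[~pos])
    tpr = 1.0 - np.searchsorted(pos_vals, thresholds, side="right") / n_pos
    fpr = 1.0 - np.searchsorted(neg_vals, thresholds, side="right") / n_neg
    # +inf anchor: nobody exceeds it
    tpr[-1] = 0.0
    fpr[-1] = 0.0
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, n_pos=n_pos, n_neg=n_neg)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the (fpr, tpr) trace.

    Traversed by descending threshold, so both rates are non-decreasing and
    tie-induced diagonal segments are integrated correctly.
    """
    return float(np.trapezoid(curve.tpr[::-1], curve.fpr[::-1]))


def auc_mannwhitney(values, labels) -> float:
    """AUC as P(random positive > random negative) + P(tie)/2.

    Computed from midranks: U = R_pos - n_pos(n_pos+1)/2, AUC = U/(n_pos*n_neg).
    """
    values, pos = _check_values_labels(values, labels)
    n_pos = int(pos.sum())
    n_neg = len(values) - n_pos
    ranks = stats.rankdata(values)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_optimal_cutoff(curve: RocCurve) -> CutoffResult:
    """Cutoff maximizing J over the finite candidates; ties -> smallest cutoff."""
    finite = np.isfinite(curve.thresholds)
    # exact integer counts avoid float jitter deciding ties in J
    tp = np.rint(curve.tpr[finite] * curve.n_pos).astype(np.int64)
    tn = np.rint((1.0 - curve.fpr[finite]) * curve.n_neg).astype(np.int64)
    j_scaled = tp * curve.n_neg + tn * curve.n_pos  # J*n_pos*n_neg + const
    best = int(np.argmax(j_scaled))  # argmax takes the first (smallest) maximizer
    sens = tp[best] / curve.n_pos
    spec = tn[best] / curve.n_neg
    return CutoffResult(
        cutoff=float(curve.thresholds[finite][best]),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(sens + spec - 1.0),
    )


def auc_ci_hanley_mcneil(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Wald confidence interval for the AUC with the Hanley-McNeil SE.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the interval A +/- z*SE is clipped
    to [0, 1].
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group sizes must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se = math.sqrt(
        (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
        / (n_pos * n_neg)
    )
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return max(0.0, a - z * se), min(1.0, a + z * se)


def correctly_predicted(auc: float, n_total: int) -> int:
    """Expected number of correct predictions, round(AUC * n) half-up.

    This is the arithmetic behind figure legends of the form "can predict
    cytoreduction correctly in N patients out of a total of M".
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(math.floor(auc * n_total + 0.5))
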
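"""Confusion-matrix machinery and diagnostic-accuracy panels.

Conventions, fixed throughout the package: the positive class is suboptimal
cytoreduction; a patient tests positive when the marker (or combined score)
is strictly greater than the cutoff — a value equal to the cutoff is
test-negative, matching the category coding "1 if <= COP, 2 if > COP".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import POSITIVE_LABEL, NEGATIVE_LABEL


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2x2 counts at a fixed cutoff."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class DiagnosticSummary:
    """The five-rate panel derived from a confusion matrix.

    ``ppv``/``npv`` are ``None`` (undefined) when no patient tests
    positive/negative — never silently coerced to 0 or 1.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float | None
    npv: float | None
    matrix: ConfusionMatrix

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "tp": self.matrix.tp,
            "fn": self.matrix.fn,
            "tn": self.matrix.tn,
            "fp": self.matrix.fp,
        }


def percent(rate: float | None, decimals: int = 1) -> float | None:
    """Rate as a percentage rounded half-up (the reporting convention)."""
    if rate is None:
        return None
    scale = 10.0 ** decimals
    return math.floor(rate * 100.0 * scale + 0.5) / scale


def _check_values_labels(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, float)
    labels = np.asarray(labels, str)
    if values.shape != labels.shape or values.ndim != 1 or len(values) == 0:
        raise ValueError("values and labels must be equal-length 1-D sequences")
    if not np.isfinite(values).all():
        raise ValueError("marker values must be finite")
    known = np.isin(labels, (POSITIVE_LABEL, NEGATIVE_LABEL))
    if not known.all():
        bad = labels[~known][0]
        raise ValueError(f"unknown outcome label {bad!r}")
    pos = labels == POSITIVE_LABEL
    if pos.all() or not pos.any():
        raise ValueError("both outcome classes must be present")
    return values, pos


def confusion_at_cutoff(values, labels, cutoff: float) -> ConfusionMatrix:
    """Classify every patient at ``cutoff`` (test-positive iff value > cutoff)."""
    values, pos = _check_values_labels(values, labels)
    test_pos = values > cutoff
    return ConfusionMatrix(
        tp=int((test_pos & pos).sum()),
        fn=int((~test_pos & pos).sum()),
        tn=int((~test_pos & ~pos).sum()),
        fp=int((test_pos & ~pos).sum()),
    )


def summarize(cm: ConfusionMatrix) -> DiagnosticSummary:
    """Exact-ratio sensitivity, specificity, accuracy, PPV and NPV."""
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise ValueError("confusion matrix must contain both classes")
    return DiagnosticSummary(
        sensitivity=cm.tp / cm.n_pos,
        specificity=cm.tn / cm.n_neg,
        accuracy=(cm.tp + cm.tn) / cm.total,
        ppv=cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None,
        npv=cm.tn / (cm.tn + cm.fn) if cm.tn + cm.fn > 0 else None,
        matrix=cm,
    )


def _nearest_count(rate: float, n: int) -> int:
    # integer k in [0, n] minimizing |k/n - rate|; ties resolved upward
    k = np.arange(n + 1)
    err = np.abs(k / n - rate)
    best = err.min()
    return int(k[np.isclose(err, best, rtol=0.0, atol=1e-12)].max())

def reconstruct_confusion(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Invert published sensitivity/specificity back to integer counts.

    Picks tp in [0, n_pos] whose rate is nearest ``sens`` (ties toward the
    larger count) and tn likewise; the achieved rates are within 0.5/n of the
    inputs. Useful for verifying published accuracy/PPV/NPV cells.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group sizes must be positive")
    tp = _nearest_count(sens, n_pos)
    tn = _nearest_count(spec, n_neg)
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
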
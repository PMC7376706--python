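"""End-to-end study pipeline.

``run_study`` reproduces the shape of the original analysis on any cohort:

stage 1 — for each single marker: group summary statistics, the
Youden-optimal cut-off (or a pinned published value), the diagnostic rate
panel at that cut-off, the AUC with its Hanley-McNeil interval and the
correctly-predicted count, plus Mann-Whitney and Welch-t group comparisons;

stage 2 — with the stage-1 cut-offs frozen, build the three multiplicative
combined panels (CA-125+FASN, CA-125+GLS, CA-125+FASN+GLS) and run the same
metric block on each panel's scores.

There is no joint optimization across stages and no holdout: panel cut-offs
are re-derived on the same cohort, mirroring the original procedure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, MARKERS, POSITIVE_LABEL, read_cohort_csv, write_cohort_csv  # noqa: F401 (re-exported)
from .combine import PANEL_NAMES, build_combined_panel, study_panels
from .compare import TestResult, mann_whitney_u, t_test_unpaired
from .diagnostics import DiagnosticSummary, confusion_at_cutoff, percent, summarize
from .roc import (
    auc_ci_hanley_mcneil,
    auc_trapezoid,
    correctly_predicted,
    roc_curve,
    youden_optimal_cutoff,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class MarkerReport:
    """Full metric block for one marker or combined panel."""

    name: str
    group_stats: dict[str, GroupStats]
    cutoff: float
    cutoff_pinned: bool
    summary: DiagnosticSummary
    auc: float
    auc_ci: tuple[float, float]
    correctly_predicted: int
    tests: dict[str, TestResult]


@dataclass(frozen=True)
class StudyReport:
    markers: dict[str, MarkerReport]
    n_pos: int
    n_neg: int


def _group_stats(values: np.ndarray, labels: np.ndarray) -> dict[str, GroupStats]:
    out = {}
    for group in ("suboptimal", "optimal"):
        v = values[labels == group]
        out[group] = GroupStats(
            n=len(v),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            median=float(np.median(v)),
            min=float(np.min(v)),
            max=float(np.max(v)),
        )
    return out


def _metric_block(
    name: str, values: np.ndarray, labels: np.ndarray, pinned: float | None
) -> MarkerReport:
    curve = roc_curve(values, labels)
    if pinned is None:
        cut = youden_optimal_cutoff(curve).cutoff
    else:
        cut = float(pinned)
    cm = confusion_at_cutoff(values, labels, cut)
    summary = summarize(cm)
    if summary.sensitivity in (0.0, 1.0) or summary.specificity in (0.0, 1.0):
        logger.warning("%s: degenerate operating point at cutoff %g", name, cut)
    auc = auc_trapezoid(curve)
    ci = auc_ci_hanley_mcneil(auc, curve.n_pos, curve.n_neg, 0.95)
    x = values[labels == "suboptimal"]
    y = values[labels == "optimal"]
    logger.info("%s: cutoff=%g (pinned=%s) auc=%.4f", name, cut, pinned is not None, auc)
    return MarkerReport(
        name=name,
        group_stats=_group_stats(values, labels),
        cutoff=cut,
        cutoff_pinned=pinned is not None,
        summary=summary,
        auc=auc,
        auc_ci=ci,
        correctly_predicted=correctly_predicted(auc, len(values)),
        tests={
            "mann_whitney": mann_whitney_u(x, y),
            "welch_t": t_test_unpaired(x, y, welch=True),
        },
    )


def run_study(
    cohort: Cohort, pinned_cutoffs: dict[str, float] | None = None
) -> StudyReport:
    """Run the two-stage analysis; see the module docstring.

    ``pinned_cutoffs`` maps marker/panel names to cut-offs imposed instead of
    the Youden-derived ones (e.g. the published 248.55 for CA-125 and 22.895
    for GLS when reproducing worked examples).
    """
    pinned = dict(pinned_cutoffs or {})
    labels = cohort.labels
    logger.info(
        "cohort: n=%d (suboptimal %d / optimal %d)", len(cohort), cohort.n_pos,
        cohort.n_neg,
    )
    reports: dict[str, MarkerReport] = {}
    for marker in MARKERS:
        reports[marker] = _metric_block(
            marker, cohort.marker_values(marker), labels, pinned.get(marker)
        )
    stage1_cutoffs = {m: reports[m].cutoff for m in MARKERS}
    for name, spec in study_panels(stage1_cutoffs).items():
        scores = build_combined_panel(cohort, spec).to_numpy()
        reports[name] = _metric_block(name, scores, labels, pinned.get(name))
    return StudyReport(markers=reports, n_pos=cohort.n_pos, n_neg=cohort.n_neg)


def report_to_dict(report: StudyReport) -> dict:
    out: dict = {"n_pos": report.n_pos, "n_neg": report.n_neg, "markers": {}}
    for name, mr in report.markers.items():
        out["markers"][name] = {
            "cutoff": mr.cutoff,
            "cutoff_pinned": mr.cutoff_pinned,
            "groups": {g: dataclasses.asdict(s) for g, s in mr.group_stats.items()},
            "diagnostics": mr.summary.as_dict(),
            "auc": mr.auc,
            "auc_ci": list(mr.auc_ci),
            "correctly_predicted": mr.correctly_predicted,
            "tests": {k: t.as_dict() for k, t in mr.tests.items()},
        }
    return out


def write_report(report: StudyReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2)


def report_to_table(report: StudyReport) -> pd.DataFrame:
    """Flat per-variable table mirroring the published column order:
    cut-off, sensitivity, specificity, accuracy, PPV, NPV (percent)."""
    rows = []
    for name, mr in report.markers.items():
        s = mr.summary
        rows.append(
            {
                "variable": name,
                "cutoff": mr.cutoff,
                "sensitivity_pct": percent(s.sensitivity),
                "specificity_pct": percent(s.specificity),
                "accuracy_pct": percent(s.accuracy),
                "ppv_pct": percent(s.ppv),
                "npv_pct": percent(s.npv),
                "auc_pct": percent(mr.auc),
                "correctly_predicted": mr.correctly_predicted,
            }
        )
    return pd.DataFrame(rows)
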
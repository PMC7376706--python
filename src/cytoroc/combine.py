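"""Multiplicative dichotomized-combination scores.

The combined scores keep one marker on its numeric scale and multiply it by
category values derived from the other markers: a marker at or below its
cut-off contributes a factor 1, above it a factor 2. The three study panels
are

=====================  ==============  ==========================
panel                  numeric marker  category markers
=====================  ==============  ==========================
ca125_fasn             FASN            CA-125
ca125_gls              GLS             CA-125
ca125_fasn_gls         FASN            CA-125, GLS
=====================  ==============  ==========================

The numeric/category assignment is forced by arithmetic on the published
panel ranges (e.g. the CA-125+GLS suboptimal maximum 75.00 equals the GLS
maximum 37.50 doubled, and its optimal minimum 10.81 equals the GLS minimum
untouched). Panel cut-offs are then found by running the same ROC/Youden
machinery on the panel scores — a two-stage procedure in which the
single-marker cut-offs are frozen before any combination is formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

PANEL_NAMES = ("ca125_fasn", "ca125_gls", "ca125_fasn_gls")


@dataclass(frozen=True)
class CombinedSpec:
    """One panel: the numeric marker and the (marker, cutoff) category terms."""

    numeric_marker: str
    category_markers: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.category_markers:
            raise ValueError("at least one category marker is required")
        names = [m for m, _ in self.category_markers]
        if self.numeric_marker in names:
            raise ValueError("numeric marker cannot also be a category marker")
        if len(set(names)) != len(names):
            raise ValueError("duplicate category marker")
        for _, cut in self.category_markers:
            if not math.isfinite(cut):
                raise ValueError("category cutoffs must be finite")


def dichotomize(value: float, cutoff: float) -> int:
    """Category value: 1 if value <= cutoff, else 2."""
    if not (math.isfinite(value) and math.isfinite(cutoff)):
        raise ValueError("value and cutoff must be finite")
    return 1 if value <= cutoff else 2


def combined_score(numeric_value: float, categories) -> float:
    """numeric_value multiplied by every category factor (each in {1, 2})."""
    if numeric_value < 0:
        raise ValueError("numeric value must be >= 0")
    cats = list(categories)
    if not cats:
        raise ValueError("categories must be nonempty")
    product = 1
    for c in cats:
        if c not in (1, 2):
            raise ValueError(f"category value {c!r} outside {{1, 2}}")
        product *= c
    return float(numeric_value) * product


def build_combined_panel(cohort: Cohort, spec: CombinedSpec) -> pd.Series:
    """Per-patient combined scores, indexed by patient id, in cohort order."""
    numeric = cohort.marker_values(spec.numeric_marker)
    factor = np.ones(len(cohort))
    for marker, cutoff in spec.category_markers:
        levels = cohort.marker_values(marker)
        factor *= np.where(levels > cutoff, 2.0, 1.0)
    return pd.Series(
        numeric * factor, index=cohort.data["patient_id"].to_numpy(), name="score"
    )


def study_panels(cutoffs: dict[str, float]) -> dict[str, CombinedSpec]:
    """The three study panels built from single-marker cutoffs.

    ``cutoffs`` must provide ``ca125`` and ``gls`` (the category markers).
    """
    ca = float(cutoffs["ca125"])
    gl = float(cutoffs["gls"])
    return {
        "ca125_fasn": CombinedSpec("fasn", ((("ca125"), ca),)),
        "ca125_gls": CombinedSpec("gls", ((("ca125"), ca),)),
        "ca125_fasn_gls": CombinedSpec("fasn", (("ca125", ca), ("gls", gl))),
    }


def spec_to_dict(spec: CombinedSpec) -> dict:
    return {
        "numeric_marker": spec.numeric_marker,
        "category_markers": [[m, c] for m, c in spec.category_markers],
    }


def spec_from_dict(d: dict) -> CombinedSpec:
    return CombinedSpec(
        numeric_marker=d["numeric_marker"],
        category_markers=tuple((m, float(c)) for m, c in d["category_markers"]),
    )
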
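"""Patient cohort container and CSV round-trip.

A cohort is a labelled collection of patients, each carrying an outcome label
(``suboptimal`` cytoreduction is the positive class, ``optimal`` the negative)
and three preoperative serum marker levels: CA-125 (U/mL), FASN (ng/mL) and
GLS (ng/mL). Optional covariates (FIGO stage, histopathology) may be present
but never participate in marker-level computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE_LABEL = "suboptimal"
NEGATIVE_LABEL = "optimal"
GROUP_LABELS = (POSITIVE_LABEL, NEGATIVE_LABEL)

MARKERS = ("ca125", "fasn", "gls")
#: CSV column name for each marker, carrying its unit.
MARKER_COLUMNS = {
    "ca125": "ca125_u_ml",
    "fasn": "fasn_ng_ml",
    "gls": "gls_ng_ml",
}
REQUIRED_COLUMNS = ("patient_id", "group") + tuple(MARKER_COLUMNS.values())
OPTIONAL_COLUMNS = ("stage", "histology")


class CohortError(ValueError):
    """Raised when patient data violates the cohort schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: outcome label, three marker levels, optional covariates."""

    id: str
    group: str
    ca125: float
    fasn: float
    gls: float
    stage: str | None = None
    histology: str | None = None


@dataclass(frozen=True)
class Cohort:
    """Validated table of patients, one row each.

    Parameters
    ----------
    data:
        DataFrame with columns ``patient_id, group, ca125_u_ml, fasn_ng_ml,
        gls_ng_ml`` and optionally ``stage, histology``. Group labels must be
        ``suboptimal`` or ``optimal`` (case-insensitive input is normalized
        before construction by :func:`read_cohort_csv`).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise CohortError(f"missing required column {col!r}")
        bad_group = ~df["group"].isin(GROUP_LABELS)
        if bad_group.any():
            row = int(np.flatnonzero(bad_group.to_numpy())[0])
            raise CohortError(
                f"row {row}: unknown group label {df['group'].iloc[row]!r}"
            )
        for col in MARKER_COLUMNS.values():
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
            bad = ~np.isfinite(vals) | (vals < 0)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise CohortError(
                    f"row {row}: invalid {col} value {df[col].iloc[row]!r} "
                    "(must be finite and >= 0)"
                )
        if self.n_pos == 0 or self.n_neg == 0:
            raise CohortError("cohort must contain both outcome groups")

    @property
    def n_pos(self) -> int:
        """Number of suboptimal-cytoreduction (positive) patients."""
        return int((self.data["group"] == POSITIVE_LABEL).sum())

    @property
    def n_neg(self) -> int:
        """Number of optimal-cytoreduction (negative) patients."""
        return int((self.data["group"] == NEGATIVE_LABEL).sum())

    def __len__(self) -> int:
        return len(self.data)

    def marker_values(self, marker: str) -> np.ndarray:
        """Raw levels for one marker, in cohort row order."""
        if marker not in MARKER_COLUMNS:
            raise CohortError(f"unknown marker {marker!r}")
        return self.data[MARKER_COLUMNS[marker]].to_numpy(float)

    @property
    def labels(self) -> np.ndarray:
        return self.data["group"].to_numpy(str)

    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                PatientRecord(
                    id=str(row.patient_id),
                    group=row.group,
                    ca125=float(row.ca125_u_ml),
                    fasn=float(row.fasn_ng_ml),
                    gls=float(row.gls_ng_ml),
                    stage=getattr(row, "stage", None),
                    histology=getattr(row, "histology", None),
                )
            )
        return out


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV, normalizing group-label case.

    Unknown columns are preserved in ``Cohort.data`` but ignored by the
    analysis. Errors name the offending row (0-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "group" in df.columns:
        df["group"] = df["group"].astype(str).str.strip().str.lower()
    return Cohort(df)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write the cohort at full float precision (lossless round-trip)."""
    cohort.data.to_csv(path, index=False, float_format="%.17g")
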
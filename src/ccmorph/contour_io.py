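"""Reading, validation and writing of traced callosal contours and covariates.

A subject's corpus callosum is represented by two manually traced polylines in
the midsagittal plane: the *upper* (dorsal) and *lower* (ventral) boundary.
Coordinates are in millimetres under the package-wide convention that x
increases anterior -> posterior and y increases inferior -> superior, so the
rostral tip is the low-x end of each boundary.

File dialects
-------------
Contour CSV: header ``subject_id,boundary,vertex_index,x_mm,y_mm`` with
``boundary`` in ``{upper, lower}`` and ``vertex_index`` 0-based and contiguous
within each (subject, boundary). The explicit vertex index protects against
re-ordered exports; parsing is invariant to row order.

Covariate CSV: header ``subject_id,diagnosis,sex,age_years,education_years,
tiv_ml,illness_duration_years,cpz_mg_day``. Empty clinical cells mean
*absent*; healthy controls must leave both clinical fields empty.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

DIAGNOSES = ("OCD", "SZ", "BD", "MDD", "HC")
CONTROL_LABEL = "HC"
SEXES = ("M", "F")

CONTOUR_COLUMNS = ["subject_id", "boundary", "vertex_index", "x_mm", "y_mm"]
COVARIATE_COLUMNS = [
    "subject_id",
    "diagnosis",
    "sex",
    "age_years",
    "education_years",
    "tiv_ml",
    "illness_duration_years",
    "cpz_mg_day",
]

#: Default tolerance (mm) within which the anterior (and posterior) endpoints
#: of the upper and lower boundary are expected to coincide. Real tracings
#: meet at the rostral tip and splenium bottom only approximately, so a
#: violation is a warning, never an error.
DEFAULT_ENDPOINT_TOLERANCE_MM = 2.0


class ContourFormatError(ValueError):
    """Malformed contour or covariate file (missing column, bad label...)."""


class IncompleteSubjectError(ContourFormatError):
    """A subject is missing one of its two boundaries."""


class DuplicateVertexError(ContourFormatError):
    """Duplicate (subject, boundary, vertex_index) triple."""


class CovariateError(ValueError):
    """Inconsistent or out-of-domain covariate row."""


@dataclasses.dataclass(frozen=True)
class Polyline:
    """An ordered open polyline, vertices as an (n, 2) float array in mm."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("polyline vertices must be an (n, 2) array")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)


@dataclasses.dataclass(frozen=True)
class ContourPair:
    """A subject's traced upper and lower midsagittal callosal boundaries."""

    subject_id: str
    upper: Polyline
    lower: Polyline


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """Diagnosis and covariates for one subject.

    ``illness_duration`` (years) and ``cpz`` (chlorpromazine-equivalent dose,
    mg/day) are ``None`` when absent; they must be absent for healthy
    controls and may be absent (missing data) for patients.
    """

    subject_id: str
    diagnosis: str
    sex: str
    age: float
    education: float
    tiv: float
    illness_duration: Optional[float] = None
    cpz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise CovariateError(
                f"subject {self.subject_id}: unknown diagnosis "
                f"{self.diagnosis!r} (expected one of {DIAGNOSES})"
            )
        if self.sex not in SEXES:
            raise CovariateError(
                f"subject {self.subject_id}: sex must be M or F, got {self.sex!r}"
            )
        if self.age < 0 or self.education < 0 or self.tiv <= 0:
            raise CovariateError(
                f"subject {self.subject_id}: age/education must be >= 0 and tiv > 0"
            )
        for name, value in (("illness_duration", self.illness_duration),
                            ("cpz", self.cpz)):
            if value is not None and (not math.isfinite(value) or value < 0):
                raise CovariateError(
                    f"subject {self.subject_id}: {name} must be finite and >= 0"
                )
        if self.diagnosis == CONTROL_LABEL and (
            self.illness_duration is not None or self.cpz is not None
        ):
            raise CovariateError(
                f"subject {self.subject_id}: clinical covariates must be absent "
                f"for {CONTROL_LABEL}"
            )


@dataclasses.dataclass
class ValidationReport:
    """Outcome of :func:`validate_contour_pair`: errors and warnings."""

    subject_id: str
    errors: list[str] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def polyline_violations(poly: Polyline) -> list[str]:
    """List invariant violations of a polyline (empty list if valid)."""
    out: list[str] = []
    v = poly.vertices
    if len(v) < 2:
        out.append("fewer than 2 vertices")
        return out
    if not np.all(np.isfinite(v)):
        out.append("non-finite coordinate")
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    if np.any(seg == 0.0):
        idx = int(np.flatnonzero(seg == 0.0)[0])
        out.append(f"zero-length segment at vertex {idx}")
    return out


def validate_contour_pair(
    pair: ContourPair,
    endpoint_tolerance_mm: float = DEFAULT_ENDPOINT_TOLERANCE_MM,
) -> ValidationReport:
    """Report every violated contour-pair invariant without raising.

    Polyline defects (too few vertices, repeated consecutive vertices,
    non-finite coordinates) are errors. Endpoint non-coincidence of the two
    boundaries, and boundaries not stored anterior-first, are warnings:
    downstream geometry handles both.
    """
    report = ValidationReport(subject_id=pair.subject_id)
    for name, poly in (("upper", pair.upper), ("lower", pair.lower)):
        for msg in polyline_violations(poly):
            report.errors.append(f"{name}: {msg}")
    if report.errors:
        return report

    for name, poly in (("upper", pair.upper), ("lower", pair.lower)):
        if poly.vertices[0, 0] > poly.vertices[-1, 0]:
            report.warnings.append(f"{name}: not anterior-first (will be reoriented)")

    u, low = pair.upper.vertices, pair.lower.vertices
    # compare like ends after virtual anterior-first orientation
    u = u if u[0, 0] <= u[-1, 0] else u[::-1]
    low = low if low[0, 0] <= low[-1, 0] else low[::-1]
    for end, iu in (("anterior", 0), ("posterior", -1)):
        gap = float(np.linalg.norm(u[iu] - low[iu]))
        if gap > endpoint_tolerance_mm:
            report.warnings.append(
                f"{end} endpoints of upper and lower are {gap:.2f} mm apart "
                f"(> {endpoint_tolerance_mm:g} mm)"
            )
    return report


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ContourFormatError(f"{path}: missing required column {col!r}")


def read_contours(path) -> list[ContourPair]:
    """Read a contour CSV into a list of :class:`ContourPair`, sorted by id.

    Raises
    ------
    ContourFormatError
        Missing column, unknown boundary label, non-contiguous vertex index.
    IncompleteSubjectError
        A subject with only one of the two boundaries.
    DuplicateVertexError
        Repeated (subject, boundary, vertex_index).
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(df, CONTOUR_COLUMNS, path)
    bad = set(df["boundary"].unique()) - {"upper", "lower"}
    if bad:
        raise ContourFormatError(
            f"{path}: unknown boundary label(s) {sorted(bad)!r}"
        )
    dup = df.duplicated(subset=["subject_id", "boundary", "vertex_index"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise DuplicateVertexError(
            f"{path}: duplicate vertex {row['vertex_index']} for subject "
            f"{row['subject_id']!r} boundary {row['boundary']!r}"
        )

    pairs: list[ContourPair] = []
    for sid, sub in sorted(df.groupby("subject_id", sort=True)):
        boundaries: dict[str, Polyline] = {}
        for bname, rows in sub.groupby("boundary"):
            rows = rows.sort_values("vertex_index")
            idx = rows["vertex_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ContourFormatError(
                    f"{path}: vertex_index not contiguous from 0 for subject "
                    f"{sid!r} boundary {bname!r}"
                )
            boundaries[bname] = Polyline(rows[["x_mm", "y_mm"]].to_numpy(float))
        missing = {"upper", "lower"} - set(boundaries)
        if missing:
            raise IncompleteSubjectError(
                f"{path}: subject {sid!r} is missing boundary "
                f"{sorted(missing)[0]!r}"
            )
        pair = ContourPair(str(sid), boundaries["upper"], boundaries["lower"])
        report = validate_contour_pair(pair)
        if not report.ok:
            raise ContourFormatError(
                f"{path}: subject {sid!r}: " + "; ".join(report.errors)
            )
        pairs.append(pair)
    return pairs


def write_contours(pairs: Iterable[ContourPair], path) -> None:
    """Write contour pairs to CSV; output is re-readable coordinate-exactly."""
    rows = []
    for pair in pairs:
        for bname, poly in (("upper", pair.upper), ("lower", pair.lower)):
            for i, (x, y) in enumerate(poly.vertices):
                rows.append((pair.subject_id, bname, i, x, y))
    df = pd.DataFrame(rows, columns=CONTOUR_COLUMNS)
    # serialize coordinates via repr(): shortest exactly-round-tripping form
    for col in ("x_mm", "y_mm"):
        df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, index=False)


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_covariates(path) -> list[SubjectRecord]:
    """Read the covariate CSV into :class:`SubjectRecord` objects."""
    df = pd.read_csv(path, dtype={"subject_id": str, "diagnosis": str, "sex": str},
                     float_precision="round_trip")
    _require_columns(df, COVARIATE_COLUMNS, path)
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=str(row["diagnosis"]),
                sex=str(row["sex"]),
                age=float(row["age_years"]),
                education=float(row["education_years"]),
                tiv=float(row["tiv_ml"]),
                illness_duration=_opt(row["illness_duration_years"]),
                cpz=_opt(row["cpz_mg_day"]),
            )
        )
    return records


def write_covariates(records: Iterable[SubjectRecord], path) -> None:
    """Write subject records in the covariate CSV dialect (empty = absent)."""
    records_to_frame(records).to_csv(path, index=False)


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records; absent clinical values become NaN."""
    rows = [
        (
            r.subject_id,
            r.diagnosis,
            r.sex,
            r.age,
            r.education,
            r.tiv,
            np.nan if r.illness_duration is None else r.illness_duration,
            np.nan if r.cpz is None else r.cpz,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=COVARIATE_COLUMNS)
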
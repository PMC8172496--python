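"""Thickness-profile geometry: resampling, midline, callosal distance values.

Each traced boundary is resampled to ``n_points`` (default 100) points that
are equidistant along its own arc length, with position 1 at the rostral tip
and position ``n_points`` at the bottom of the splenium. The callosal midline
is the spatial average of the two resampled boundaries, and the callosal
distance value (CDV) at a position is the Euclidean distance from the
boundary point to the midline point there — half the local upper-lower
separation under the default midline mode. Thickness is ``2 * cdv``.

Two midline modes are provided. ``pointwise_average`` (default) averages
corresponding resampled points, so upper-to-midline and lower-to-midline
distances are identical by construction and one CDV per position fully
describes local thickness. ``resampled_average`` additionally re-resamples
the averaged midline to equidistant points along its own arc length before
measuring distances; it exists for sensitivity analyses and reports the mean
of the (now slightly different) upper and lower distances.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .contour_io import ContourPair, Polyline, polyline_violations

MidlineMode = Literal["pointwise_average", "resampled_average"]

DEFAULT_N_POINTS = 100

PROFILE_COLUMNS = [
    "subject_id",
    "position",
    "mid_x_mm",
    "mid_y_mm",
    "cdv_mm",
    "thickness_mm",
]


@dataclasses.dataclass(frozen=True)
class ThicknessProfile:
    """Per-subject pointwise thickness along the callosal midline.

    ``cdv[i]`` is the callosal distance value at position ``i + 1``; positions
    run 1 (rostral tip) .. ``n_points`` (splenium bottom). The resampled
    boundaries are retained so that statistical maps can be projected back
    onto the callosal outline.
    """

    subject_id: str
    midline: np.ndarray       # (n_points, 2)
    cdv: np.ndarray           # (n_points,)
    upper: np.ndarray         # (n_points, 2) resampled, anterior-first
    lower: np.ndarray         # (n_points, 2)

    @property
    def n_points(self) -> int:
        return len(self.cdv)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.n_points + 1)

    @property
    def thickness(self) -> np.ndarray:
        return 2.0 * self.cdv


def arc_length(poly: Polyline) -> float:
    """Total Euclidean length of a polyline, mm."""
    _check(poly)
    return float(np.sum(np.linalg.norm(np.diff(poly.vertices, axis=0), axis=1)))


def orient_anterior_first(poly: Polyline) -> Polyline:
    """Return the polyline with its anterior (smaller-x) endpoint first.

    The package convention has x increasing anterior -> posterior, so the
    rostral tip is the endpoint with the smaller x. Ties leave the polyline
    unchanged; the operation is idempotent.
    """
    v = poly.vertices
    if v[0, 0] > v[-1, 0]:
        return Polyline(v[::-1].copy())
    return poly


def resample_equidistant(poly: Polyline, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Resample a polyline to ``n_points`` points equidistant in arc length.

    Points are linear interpolations along the cumulative arc-length
    parameterization; the first and last points coincide with the polyline's
    endpoints. Returns an (n_points, 2) array.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    _check(poly)
    v = poly.vertices
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_points)
    out = np.column_stack(
        [np.interp(targets, s, v[:, 0]), np.interp(targets, s, v[:, 1])]
    )
    # pin endpoints exactly
    out[0] = v[0]
    out[-1] = v[-1]
    return out


def compute_midline(
    upper: np.ndarray,
    lower: np.ndarray,
    mode: MidlineMode = "pointwise_average",
) -> np.ndarray:
    """Midline as the spatial average of two resampled boundaries.

    ``pointwise_average``: coordinate-wise mean of corresponding points.
    ``resampled_average``: the pointwise mean re-resampled to the same number
    of points equidistant along its own arc length.
    """
    upper = np.asarray(upper, float)
    lower = np.asarray(lower, float)
    if upper.shape != lower.shape:
        raise ValueError(
            f"boundaries must have matching shapes, got {upper.shape} vs {lower.shape}"
        )
    mid = 0.5 * (upper + lower)
    if mode == "pointwise_average":
        return mid
    if mode == "resampled_average":
        return resample_equidistant(Polyline(mid), len(mid))
    raise ValueError(f"unknown midline mode {mode!r}")


def compute_profile(
    pair: ContourPair,
    n_points: int = DEFAULT_N_POINTS,
    midline_mode: MidlineMode = "pointwise_average",
) -> ThicknessProfile:
    """Full thickness profile of one subject's contour pair.

    Both boundaries are oriented anterior-first and independently resampled
    to ``n_points`` equidistant surface points; correspondence between the
    boundaries is index-wise. Under the default midline mode the CDV at each
    position equals both boundary-to-midline distances and half the
    upper-lower inter-point distance.
    """
    upper = resample_equidistant(orient_anterior_first(pair.upper), n_points)
    lower = resample_equidistant(orient_anterior_first(pair.lower), n_points)
    midline = compute_midline(upper, lower, midline_mode)
    du = np.linalg.norm(upper - midline, axis=1)
    if midline_mode == "pointwise_average":
        cdv = du
    else:
        dl = np.linalg.norm(lower - midline, axis=1)
        cdv = 0.5 * (du + dl)
    return ThicknessProfile(
        subject_id=pair.subject_id, midline=midline, cdv=cdv,
        upper=upper, lower=lower,
    )


def profiles_to_cdv(profiles: Iterable[ThicknessProfile]) -> pd.DataFrame:
    """Stack profiles into a subjects x positions CDV table (mm).

    Rows are indexed by subject_id, columns by 1-based position.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    n = {p.n_points for p in profiles}
    if len(n) != 1:
        raise ValueError(f"profiles have mixed n_points: {sorted(n)}")
    return pd.DataFrame(
        np.vstack([p.cdv for p in profiles]),
        index=pd.Index([p.subject_id for p in profiles], name="subject_id"),
        columns=pd.RangeIndex(1, n.pop() + 1, name="position"),
    )


def write_profiles(profiles: Iterable[ThicknessProfile], path) -> None:
    """Write profiles as long CSV: subject_id,position,mid_x_mm,mid_y_mm,cdv_mm,thickness_mm."""
    rows = []
    for p in profiles:
        for i in range(p.n_points):
            rows.append(
                (p.subject_id, i + 1,
                 repr(float(p.midline[i, 0])), repr(float(p.midline[i, 1])),
                 repr(float(p.cdv[i])), repr(2.0 * float(p.cdv[i])))
            )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles_cdv(path) -> pd.DataFrame:
    """Read a profile CSV back into the subjects x positions CDV table."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    for col in PROFILE_COLUMNS[:2] + ["cdv_mm"]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    wide = df.pivot(index="subject_id", columns="position", values="cdv_mm")
    wide = wide.sort_index(axis=1)
    wide.columns.name = "position"
    return wide


def _check(poly: Polyline) -> None:
    problems = polyline_violations(poly)
    if problems:
        raise ValueError("invalid polyline: " + "; ".join(problems))
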
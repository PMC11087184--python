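"""Data model and interchange format for cine contour studies.

A *study* is a directory with one sub-directory per subject.  Each subject
directory holds a ``subject.json`` with demographics and per-slice metadata
(geometry in DICOM ``PixelSpacing`` / ``ImagePositionPatient`` /
``ImageOrientationPatient`` semantics) and one CSV per slice with columns
``phase, border, point_index, u_mm, v_mm``.  All in-plane coordinates are
stored in millimetres; the 3D patient frame is LPS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "HFpEF", "HFmrEF", "HFrEF")
VIEWS = ("LAX_2CH", "LAX_3CH", "LAX_4CH", "SAX_BASAL", "SAX_MID")
LAX_VIEWS = ("LAX_2CH", "LAX_3CH", "LAX_4CH")
SAX_VIEWS = ("SAX_BASAL", "SAX_MID")
BORDERS = ("epi", "endo")

_ORTHO_TOL = 1e-6


class SchemaError(ValueError):
    """Raised when an interchange file is missing or malformed."""


class ValidationError(ValueError):
    """Raised when loaded data violates a type invariant."""


@dataclass
class SliceGeometry:
    """In-plane geometry of one slice: mm scaling and LPS placement.

    ``row_dir``/``col_dir`` follow DICOM ImageOrientationPatient: unit
    vectors of increasing row / column index in the patient LPS frame.
    """

    pixel_spacing: tuple[float, float]
    origin_lps: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray

    def __post_init__(self) -> None:
        self.origin_lps = np.asarray(self.origin_lps, dtype=float)
        self.row_dir = np.asarray(self.row_dir, dtype=float)
        self.col_dir = np.asarray(self.col_dir, dtype=float)
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValidationError("pixel_spacing components must be > 0")
        for name, v in (("row_dir", self.row_dir), ("col_dir", self.col_dir)):
            if v.shape != (3,):
                raise ValidationError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise ValidationError(f"{name} must be unit length")
        if abs(float(np.dot(self.row_dir, self.col_dir))) > _ORTHO_TOL:
            raise ValidationError("row_dir and col_dir must be orthogonal")
        if self.origin_lps.shape != (3,):
            raise ValidationError("origin_lps must be a 3-vector")


def _is_simple_closed(pts: np.ndarray) -> bool:
    """True if the closed polygon has no crossing non-adjacent edges."""
    n = len(pts)
    if n < 4:
        return True
    a = pts
    b = np.roll(pts, -1, axis=0)
    i, j = np.triu_indices(n, k=2)
    adjacent = (i == 0) & (j == n - 1)  # wrap-around neighbours
    i, j = i[~adjacent], j[~adjacent]

    def cross(o, p, q):
        return ((p[:, 0] - o[:, 0]) * (q[:, 1] - o[:, 1])
                - (p[:, 1] - o[:, 1]) * (q[:, 0] - o[:, 0]))

    d1 = cross(a[i], b[i], a[j])
    d2 = cross(a[i], b[i], b[j])
    d3 = cross(a[j], b[j], a[i])
    d4 = cross(a[j], b[j], b[i])
    return not bool(np.any((d1 * d2 < 0) & (d3 * d4 < 0)))


@dataclass
class ContourSeries:
    """One border's ordered point lists per phase, in slice-plane mm."""

    points: list[np.ndarray]  # each (n_points, 2)
    closed: bool

    def __post_init__(self) -> None:
        self.points = [np.asarray(p, dtype=float) for p in self.points]
        if not self.points:
            raise ValidationError("contour series is empty")
        n0 = self.points[0].shape
        for i, p in enumerate(self.points):
            if p.ndim != 2 or p.shape[1] != 2:
                raise ValidationError(f"phase {i}: contour must be (n, 2)")
            if p.shape != n0:
                raise ValidationError(
                    f"phase {i}: point count {p.shape[0]} differs from "
                    f"reference {n0[0]} (point correspondence broken)"
                )
        # simplicity is required at the reference (first) phase only
        if self.closed and not _is_simple_closed(self.points[0]):
            raise ValidationError(
                "closed contour is self-intersecting at the reference phase")

    @property
    def n_phases(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return self.points[0].shape[0]


@dataclass
class CineSlice:
    """One cine slice: view, geometry and epi/endo contour series.

    ``side_polarity`` (long-axis views) flips which side of the LV long
    axis is treated as the first wall of the view's segment mapping;
    ``ref_angle`` (short-axis views) is the polar start angle of the first
    sector, in degrees counterclockwise from the image +u axis.
    """

    slice_id: str
    view: str
    geometry: SliceGeometry
    n_phases: int
    epi: ContourSeries
    endo: ContourSeries
    reference_phase: int = 0
    side_polarity: int = 1
    ref_angle: float = 90.0

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValidationError(f"unknown view {self.view!r}")
        if self.n_phases < 2:
            raise ValidationError("n_phases must be >= 2")
        for name, series in (("epi", self.epi), ("endo", self.endo)):
            if series.n_phases != self.n_phases:
                raise ValidationError(
                    f"slice {self.slice_id}: {name} has {series.n_phases} "
                    f"contours but n_phases={self.n_phases}"
                )
        expect_closed = self.view in SAX_VIEWS
        if self.epi.closed != expect_closed or self.endo.closed != expect_closed:
            raise ValidationError(
                f"slice {self.slice_id}: closed flag inconsistent with view"
            )
        if not 0 <= self.reference_phase < self.n_phases:
            raise ValidationError("reference_phase out of range")
        if self.side_polarity not in (-1, 1):
            raise ValidationError("side_polarity must be +1 or -1")

    @property
    def is_long_axis(self) -> bool:
        return self.view in LAX_VIEWS


@dataclass
class Subject:
    """One study subject: demographics plus cine slices."""

    subject_id: str
    group: str
    sex: str
    height: float | None = None
    weight: float | None = None
    lvef: float | None = None
    nyha: int | None = None
    slices: list[CineSlice] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name, v in (("height", self.height), ("weight", self.weight)):
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.nyha is not None and not 1 <= self.nyha <= 4:
            raise ValidationError("nyha must be in 1..4")
        if self.lvef is not None and self.group != "control":
            lo, hi = {"HFpEF": (55.0, math.inf),
                      "HFmrEF": (40.0, 55.0),
                      "HFrEF": (-math.inf, 40.0)}[self.group]
            ok = {"HFpEF": self.lvef > lo,
                  "HFmrEF": lo <= self.lvef <= hi,
                  "HFrEF": self.lvef < 40.0}[self.group]
            if not ok:
                raise ValidationError(
                    f"subject {self.subject_id}: LVEF {self.lvef} inconsistent "
                    f"with group {self.group}"
                )


# ---------------------------------------------------------------------------
# coordinate transforms


def pixel_to_mm(points: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Scale (row, col) pixel coordinates to mm, component-wise."""
    sr, sc = float(spacing[0]), float(spacing[1])
    if sr <= 0 or sc <= 0:
        raise ValueError("pixel spacing components must be > 0")
    pts = np.asarray(points, dtype=float)
    return pts * np.array([sr, sc])


def slice_to_patient_3d(points_mm: np.ndarray, geom: SliceGeometry) -> np.ndarray:
    """Embed in-plane mm coordinates (u, v) into the 3D LPS patient frame.

    ``x3d = origin + u * row_dir + v * col_dir``; an isometry of the plane.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    return (geom.origin_lps[None, :]
            + pts[:, [0]] * geom.row_dir[None, :]
            + pts[:, [1]] * geom.col_dir[None, :])


# ---------------------------------------------------------------------------
# interchange format


def _geometry_to_json(g: SliceGeometry) -> dict:
    return {
        "pixel_spacing": list(g.pixel_spacing),
        "origin_lps": g.origin_lps.tolist(),
        "row_dir": g.row_dir.tolist(),
        "col_dir": g.col_dir.tolist(),
    }


def _geometry_from_json(d: dict, where: str) -> SliceGeometry:
    for key in ("pixel_spacing", "origin_lps", "row_dir", "col_dir"):
        if key not in d:
            raise SchemaError(f"{where}: geometry missing field {key!r}")
    return SliceGeometry(
        pixel_spacing=tuple(d["pixel_spacing"]),
        origin_lps=np.array(d["origin_lps"], dtype=float),
        row_dir=np.array(d["row_dir"], dtype=float),
        col_dir=np.array(d["col_dir"], dtype=float),
    )


def write_study(subjects: Sequence[Subject], path: str | Path) -> None:
    """Write subjects to the interchange layout under ``path``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for subj in subjects:
        sdir = root / subj.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "sex": subj.sex,
            "height": subj.height,
            "weight": subj.weight,
            "lvef": subj.lvef,
            "nyha": subj.nyha,
            "slices": [],
        }
        for sl in subj.slices:
            csv_name = f"{sl.slice_id}.csv"
            meta["slices"].append({
                "slice_id": sl.slice_id,
                "view": sl.view,
                "n_phases": sl.n_phases,
                "reference_phase": sl.reference_phase,
                "side_polarity": sl.side_polarity,
                "ref_angle": sl.ref_angle,
                "geometry": _geometry_to_json(sl.geometry),
                "contours_csv": csv_name,
            })
            frames = []
            for border, series in (("epi", sl.epi), ("endo", sl.endo)):
                for phase, pts in enumerate(series.points):
                    frames.append(pd.DataFrame({
                        "phase": phase,
                        "border": border,
                        "point_index": np.arange(pts.shape[0]),
                        "u_mm": pts[:, 0],
                        "v_mm": pts[:, 1],
                    }))
            # default float formatting round-trips exactly
            pd.concat(frames, ignore_index=True).to_csv(
                sdir / csv_name, index=False)
        (sdir / "subject.json").write_text(json.dumps(meta, indent=1))


def _load_series(df: pd.DataFrame, border: str, n_phases: int,
                 closed: bool, where: str) -> ContourSeries:
    sub = df[df["border"] == border]
    if sub.empty:
        raise SchemaError(f"{where}: no rows for border {border!r}")
    phases = sorted(sub["phase"].unique())
    if phases != list(range(n_phases)):
        raise ValidationError(
            f"{where}: border {border} has phases {len(phases)} "
            f"but metadata declares n_phases={n_phases}")
    points = []
    for p in range(n_phases):
        rows = sub[sub["phase"] == p].sort_values("point_index")
        points.append(rows[["u_mm", "v_mm"]].to_numpy(dtype=float))
    return ContourSeries(points=points, closed=closed)


def load_study(path: str | Path) -> list[Subject]:
    """Load and validate a study directory; every invariant is enforced."""
    root = Path(path)
    if not root.exists():
        raise SchemaError(f"study path {root} does not exist")
    subjects: list[Subject] = []
    for meta_path in sorted(root.glob("*/subject.json")):
        sdir = meta_path.parent
        meta = json.loads(meta_path.read_text())
        for key in ("subject_id", "group", "sex", "slices"):
            if key not in meta:
                raise SchemaError(f"{meta_path}: missing field {key!r}")
        slices = []
        for sm in meta["slices"]:
            for key in ("slice_id", "view", "n_phases", "geometry",
                        "contours_csv"):
                if key not in sm:
                    raise SchemaError(
                        f"{meta_path}: slice entry missing field {key!r}")
            where = f"{sdir / sm['contours_csv']}"
            df = pd.read_csv(sdir / sm["contours_csv"],
                             float_precision="round_trip")
            closed = sm["view"] in SAX_VIEWS
            n_phases = int(sm["n_phases"])
            slices.append(CineSlice(
                slice_id=sm["slice_id"],
                view=sm["view"],
                geometry=_geometry_from_json(sm["geometry"], where),
                n_phases=n_phases,
                epi=_load_series(df, "epi", n_phases, closed, where),
                endo=_load_series(df, "endo", n_phases, closed, where),
                reference_phase=int(sm.get("reference_phase", 0)),
                side_polarity=int(sm.get("side_polarity", 1)),
                ref_angle=float(sm.get("ref_angle", 90.0)),
            ))
        subjects.append(Subject(
            subject_id=meta["subject_id"],
            group=meta["group"],
            sex=meta["sex"],
            height=meta.get("height"),
            weight=meta.get("weight"),
            lvef=meta.get("lvef"),
            nyha=meta.get("nyha"),
            slices=slices,
        ))
    if not subjects:
        raise SchemaError(f"no subject.json found under {root}")
    return subjects


def subjects_table(subjects: Sequence[Subject]) -> pd.DataFrame:
    """Demographics as a DataFrame (one row per subject)."""
    return pd.DataFrame([{
        "subject_id": s.subject_id, "group": s.group, "sex": s.sex,
        "height": s.height, "weight": s.weight, "lvef": s.lvef,
        "nyha": s.nyha,
    } for s in subjects])
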
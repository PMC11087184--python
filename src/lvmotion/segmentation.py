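"""AHA 17-segment assignment of contour points.

Long-axis views: an automatically defined LV long axis (basal-opening
midpoint to apex) splits the axial coordinate into basal/mid/apical
thirds; the side of the axis selects the wall, and a per-view mapping
table turns (wall, level) into a segment number.  Epicardial points beyond
the endocardial apex extent form the apical cap (segment 17).

Short-axis views: six 60-degree polar sectors about the cavity centroid,
starting at a configurable reference angle, numbered 1-6 (basal) or
7-12 (mid-cavity) in anatomical order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

APICAL_CAP = 17
UNASSIGNED = -1

#: Default wall mapping per long-axis view: (positive side, negative side)
#: each as (basal, mid, apical) segment numbers.  The positive side is the
#: one with positive cross(axis_dir, p - base) after the slice's
#: side-polarity flag is applied.  Overridable via config.
DEFAULT_VIEW_MAPPING: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "LAX_2CH": ((1, 7, 13), (4, 10, 15)),   # anterior / inferior
    "LAX_3CH": ((2, 8, 13), (5, 11, 16)),   # anteroseptal / inferolateral
    "LAX_4CH": ((3, 9, 14), (6, 12, 16)),   # (infero)septal / (antero)lateral
}

#: Anatomical sector order for short-axis slices (offset added for mid).
SAX_BASE_SEGMENT = {"basal": 1, "mid": 7}


@dataclass
class LongAxis:
    """The LV long axis of one long-axis slice at the reference phase."""

    base_point: np.ndarray
    apex_point: np.ndarray
    axis_dir: np.ndarray
    length: float


@dataclass
class SegmentAssignment:
    """Per-point segment labels (1..17) and level names."""

    labels: np.ndarray  # (n,), int
    level: np.ndarray   # (n,), str in {basal, mid, apical, apical_cap}


def define_long_axis(epi_ed: np.ndarray) -> LongAxis:
    """Define the LV long axis from the reference-phase epicardial contour.

    The base point is the midpoint of the open contour's endpoints; the
    apex is the contour point with maximal projection onto the principal
    direction of the point cloud (oriented away from the base).
    """
    pts = np.asarray(epi_ed, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need an open (n>=4, 2) long-axis contour")
    if np.linalg.norm(pts[0] - pts[-1]) < 1e-9 and len(pts) > 8:
        raise ValueError("contour appears closed; long axis needs an "
                         "open long-axis view contour")
    base = 0.5 * (pts[0] + pts[-1])
    centroid = pts.mean(axis=0)
    towards = centroid - base
    centred = pts - centroid
    cov = centred.T @ centred
    _, v = np.linalg.eigh(cov)
    # principal direction: the covariance eigenvector best aligned with the
    # base->centroid direction (the wall-to-wall eigenvector can carry more
    # variance on short, wide ventricles)
    if np.linalg.norm(towards) < 1e-12:
        principal = v[:, -1]
    else:
        align = np.abs(v.T @ towards)
        principal = v[:, int(np.argmax(align))]
    if np.dot(towards, principal) < 0:
        principal = -principal
    proj = (pts - base) @ principal
    apex = pts[int(np.argmax(proj))]
    length = float(np.linalg.norm(apex - base))
    if length <= 0:
        raise ValueError("degenerate long axis: apex coincides with base")
    return LongAxis(base_point=base, apex_point=apex,
                    axis_dir=(apex - base) / length, length=length)


def _levels_from_axial_fraction(frac: np.ndarray) -> np.ndarray:
    """Half-open thirds: basal [0,1/3), mid [1/3,2/3), apical [2/3,1]."""
    level = np.where(frac < 1.0 / 3.0, "basal",
                     np.where(frac < 2.0 / 3.0, "mid", "apical"))
    return level.astype(object)


def assign_long_axis_segments(points: np.ndarray, border: str, axis: LongAxis,
                              view: str, endo_apex_extent: float,
                              side_polarity: int = 1,
                              mapping: dict | None = None) -> SegmentAssignment:
    """Assign long-axis contour points to AHA segments.

    ``endo_apex_extent`` is the maximal axial coordinate of the same
    slice's endocardial reference contour; epicardial points beyond it
    form the apical cap (segment 17), which has no endocardial points.
    """
    if mapping is None:
        mapping = DEFAULT_VIEW_MAPPING
    if view not in mapping:
        raise ValueError(f"unknown long-axis view {view!r}")
    if border not in ("epi", "endo"):
        raise ValueError(f"border must be 'epi' or 'endo', got {border!r}")
    pts = np.asarray(points, dtype=float)
    rel = pts - axis.base_point[None, :]
    a = rel @ axis.axis_dir
    frac = np.clip(a / axis.length, 0.0, 1.0)
    level = _levels_from_axial_fraction(frac)
    cross = axis.axis_dir[0] * rel[:, 1] - axis.axis_dir[1] * rel[:, 0]
    pos_side = (cross * side_polarity) >= 0.0  # points on the axis: first wall
    pos_segs, neg_segs = mapping[view]
    level_idx = {"basal": 0, "mid": 1, "apical": 2}
    labels = np.empty(len(pts), dtype=int)
    for i in range(len(pts)):
        segs = pos_segs if pos_side[i] else neg_segs
        labels[i] = segs[level_idx[level[i]]]
    if border == "epi":
        cap = a > endo_apex_extent
        labels[cap] = APICAL_CAP
        level[cap] = "apical_cap"
    return SegmentAssignment(labels=labels, level=level)


def assign_short_axis_segments(points: np.ndarray, level: str,
                               centroid: np.ndarray,
                               ref_angle: float = 90.0) -> SegmentAssignment:
    """Assign closed short-axis contour points to six 60-degree sectors.

    Polar angle is measured counterclockwise from ``ref_angle`` (degrees
    from the image +u axis).  Sector boundaries belong to the
    lower-numbered sector.
    """
    if level not in SAX_BASE_SEGMENT:
        raise ValueError(f"level must be 'basal' or 'mid', got {level!r}")
    pts = np.asarray(points, dtype=float)
    c = np.asarray(centroid, dtype=float)
    ang = np.degrees(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
    offset = np.mod(ang - ref_angle, 360.0)
    sector = np.floor(offset / 60.0).astype(int)
    # boundary angles belong to the sector below; snap within 1e-9 deg to
    # absorb atan2/mod rounding at exact sector edges
    nearest = np.round(offset / 60.0)
    on_edge = (np.abs(offset - 60.0 * nearest) < 1e-9) & (nearest > 0)
    sector[on_edge] = nearest[on_edge].astype(int) - 1
    sector = np.clip(sector, 0, 5)
    base = SAX_BASE_SEGMENT[level]
    labels = base + sector
    lvl = np.full(len(pts), level, dtype=object)
    return SegmentAssignment(labels=labels, level=lvl)


def endo_apex_extent(endo_ed: np.ndarray, axis: LongAxis) -> float:
    """Maximal axial coordinate of the endocardial reference contour."""
    pts = np.asarray(endo_ed, dtype=float)
    return float(np.max((pts - axis.base_point[None, :]) @ axis.axis_dir))
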
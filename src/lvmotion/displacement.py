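"""Per-point and per-segment displacement maxima over the cardiac cycle.

For each tracked contour point the overall displacement is the maximum
distance between its positions in any two cardiac phases (exact O(P^2)
pair enumeration, P <= 30).  Tangential and normal displacements are the
maximum absolute scalar projections of phase-pair difference vectors onto
the point's unit tangent / outward normal, both evaluated at the
reference (end-diastolic) position and held fixed across phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import SegmentAssignment

_UNIT_TOL = 1e-9


@dataclass
class PointTrajectory:
    """One contour point's positions across phases plus its ED frame."""

    positions: np.ndarray  # (P, 2) mm
    tangent: np.ndarray    # unit 2-vector at reference phase
    normal: np.ndarray     # unit 2-vector at reference phase

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (P, 2)")
        for name, v in (("tangent", self.tangent), ("normal", self.normal)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be unit length")
        if abs(float(np.dot(self.tangent, self.normal))) > 1e-6:
            raise ValueError("tangent and normal must be orthogonal")


def _pair_indices(n_phases: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_phases, k=1)


def max_overall_displacement(traj: PointTrajectory) -> float:
    """Maximum distance between positions of any two cardiac phases."""
    pos = traj.positions
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 phases")
    i, j = _pair_indices(pos.shape[0])
    return float(np.max(np.linalg.norm(pos[j] - pos[i], axis=1)))


def max_projected_displacement(traj: PointTrajectory,
                               direction: np.ndarray) -> float:
    """Maximum |phase-pair difference projected onto ``direction``|."""
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("direction must be unit length")
    pos = traj.positions
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 phases")
    proj = pos @ d
    i, j = _pair_indices(pos.shape[0])
    return float(np.max(np.abs(proj[j] - proj[i])))


def decompose_displacement(traj: PointTrajectory) -> tuple[float, float, float]:
    """(overall, tangential, normal) maximum displacements for one point."""
    overall = max_overall_displacement(traj)
    tang = max_projected_displacement(traj, traj.tangent)
    norm = max_projected_displacement(traj, traj.normal)
    return overall, tang, norm


def decompose_all(positions: np.ndarray, tangents: np.ndarray,
                  normals: np.ndarray) -> np.ndarray:
    """Vectorised decomposition for all points of a slice border.

    ``positions`` is (n_points, P, 2); returns (n_points, 3) columns
    (overall, tangential, normal).  Identical to per-point
    :func:`decompose_displacement` but evaluated in one pass.
    """
    pos = np.asarray(positions, dtype=float)
    n, P, _ = pos.shape
    i, j = _pair_indices(P)
    diff = pos[:, j, :] - pos[:, i, :]              # (n, n_pairs, 2)
    overall = np.max(np.linalg.norm(diff, axis=2), axis=1)
    tang = np.max(np.abs(np.einsum("npk,nk->np", diff, tangents)), axis=1)
    norm = np.max(np.abs(np.einsum("npk,nk->np", diff, normals)), axis=1)
    return np.column_stack([overall, tang, norm])


def motion_trace(traj: PointTrajectory) -> np.ndarray:
    """Signed per-phase (tangential, normal) components relative to ED.

    Under the outward-normal convention, inward (towards-cavity) radial
    motion has a negative normal component.  Row at the reference phase is
    (0, 0) when positions[0] is the reference; callers pass positions
    already ordered with the reference phase first or subtract it.
    """
    pos = traj.positions
    rel = pos - pos[0]
    return np.column_stack([rel @ traj.tangent, rel @ traj.normal])


def segment_mean_displacement(per_point: np.ndarray,
                              assignment: SegmentAssignment) -> pd.DataFrame:
    """Arithmetic per-segment means of decomposed point displacements.

    ``per_point`` is (n_points, 3) with columns overall/tangential/normal.
    Segments with zero points are omitted; ``n_points`` is recorded.
    """
    vals = np.asarray(per_point, dtype=float)
    if vals.shape[0] != assignment.labels.shape[0]:
        raise ValueError("per_point and assignment lengths differ")
    df = pd.DataFrame(vals, columns=["overall", "tangential", "normal"])
    df["segment"] = assignment.labels
    out = (df.groupby("segment")
             .agg(overall=("overall", "mean"),
                  tangential=("tangential", "mean"),
                  normal=("normal", "mean"),
                  n_points=("overall", "size"))
             .reset_index())
    return out


def aggregate_patient_segments(records: pd.DataFrame) -> pd.DataFrame:
    """Combine per-slice segment means into per-patient segment values.

    Rows sharing (subject_id, plane, border, segment) — e.g. the same
    segment seen in two slices — are averaged weighted by ``n_points``.
    """
    def _wmean(g: pd.DataFrame) -> pd.Series:
        w = g["n_points"].to_numpy(dtype=float)
        out = {c: float(np.average(g[c], weights=w))
               for c in ("overall", "tangential", "normal")}
        out["n_points"] = int(w.sum())
        return pd.Series(out)

    keys = ["subject_id", "plane", "border", "segment"]
    return (records.groupby(keys).apply(_wmean, include_groups=False)
            .reset_index())
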
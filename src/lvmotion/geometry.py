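"""Spline resampling of contours and tangent/normal frame computation.

Contours are fitted with cubic splines over a chord-length parameter —
periodic closure for closed (short-axis) contours, natural end conditions
for open (long-axis) contours.  Equal arc-length positions are found by
dense sampling of the spline (>= 50x the output count), a cumulative
chord-length table, and inverse interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

_DENSE_FACTOR = 60


@dataclass
class CurveFrame:
    """Per-point unit tangents/outward normals and cumulative arc length."""

    tangents: np.ndarray      # (n, 2), unit
    normals: np.ndarray       # (n, 2), unit, outward (away from cavity)
    arc_positions: np.ndarray  # (n,), mm, increasing


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Collapse consecutive duplicate points (zero chord segments)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    return pts[keep]


def fit_spline(points: np.ndarray, closed: bool) -> tuple[CubicSpline, np.ndarray]:
    """Fit a cubic spline through ``points`` over chord-length parameter.

    Returns the spline and the knot parameter of each input point.  For
    closed contours the curve is periodic (the duplicate endpoint is
    appended internally); for open contours natural end conditions apply.
    """
    pts = _dedupe(points)
    if closed and np.linalg.norm(pts[-1] - pts[0]) <= 1e-12:
        pts = pts[:-1]
    if len(pts) < 4:
        raise ValueError("need at least 4 distinct points for a cubic spline")
    if closed:
        wrap = np.vstack([pts, pts[:1]])
        t = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(wrap, axis=0), axis=1))])
        spline = CubicSpline(t, wrap, axis=0, bc_type="periodic")
        return spline, t[:-1]
    t = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    spline = CubicSpline(t, pts, axis=0, bc_type="natural")
    return spline, t


def _equal_arc_params(spline: CubicSpline, t_end: float, n_out: int,
                      closed: bool) -> np.ndarray:
    """Parameters at which the spline is equally spaced in arc length."""
    n_dense = max(_DENSE_FACTOR * n_out, 2000)
    td = np.linspace(0.0, t_end, n_dense + 1)
    xy = spline(td)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if closed:
        targets = np.arange(n_out) * total / n_out
    else:
        targets = np.linspace(0.0, total, n_out)
    return np.interp(targets, s, td)


def resample_contour(points: np.ndarray, n_out: int, closed: bool) -> np.ndarray:
    """Resample a contour to ``n_out`` points equally spaced in arc length.

    Closed contours return points on the periodic spline with no duplicate
    endpoint; open contours keep the first and last input points exactly.
    """
    if n_out < 4:
        raise ValueError("n_out must be >= 4")
    spline, t = fit_spline(points, closed)
    t_end = float(spline.x[-1])
    params = _equal_arc_params(spline, t_end, n_out, closed)
    out = spline(params)
    if not closed:
        pts = _dedupe(points)
        out[0] = pts[0]
        out[-1] = pts[-1]
    return out


def resample_params(points: np.ndarray, n_out: int, closed: bool) -> np.ndarray:
    """Equal-arc parameter values on the chord-length parametrisation.

    Used by the pipeline to resample the reference phase and then evaluate
    every other phase's spline at the *same* material parameters, which
    preserves point correspondence across phases.
    """
    spline, _ = fit_spline(points, closed)
    return _equal_arc_params(spline, float(spline.x[-1]), n_out, closed)


def resample_series_points(phase_points: list[np.ndarray], ref_index: int,
                           n_out: int, closed: bool) -> np.ndarray:
    """Material-consistent equal-arc resampling of a tracked contour series.

    Equal arc-length parameters are determined on the reference-phase
    contour; every phase's spline is then built over the *reference*
    chord-length knots (input points correspond materially across phases)
    and evaluated at those same parameters.  Returns ``(n_out, P, 2)``.
    Independently resampling each phase would break point correspondence
    under tangential motion.
    """
    if n_out < 4:
        raise ValueError("n_out must be >= 4")
    ref = np.asarray(phase_points[ref_index], dtype=float)
    keep = np.ones(len(ref), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(ref, axis=0), axis=1) > 1e-12
    if closed and np.linalg.norm(ref[-1] - ref[0]) <= 1e-12:
        keep[-1] = False
    ref_kept = ref[keep]
    if len(ref_kept) < 4:
        raise ValueError("need at least 4 distinct points")
    t = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(ref_kept, axis=0), axis=1))])
    if closed:
        t_wrap = np.append(t, t[-1] + np.linalg.norm(
            ref_kept[0] - ref_kept[-1]))
    out = np.empty((n_out, len(phase_points), 2))
    params = None
    for p, pts in enumerate(phase_points):
        pk = np.asarray(pts, dtype=float)[keep]
        if closed:
            spline = CubicSpline(t_wrap, np.vstack([pk, pk[:1]]), axis=0,
                                 bc_type="periodic")
        else:
            spline = CubicSpline(t, pk, axis=0, bc_type="natural")
        if params is None:
            # equal-arc parameters from the reference phase only
            ref_spline = spline if p == ref_index else None
            if ref_spline is None:
                if closed:
                    ref_spline = CubicSpline(
                        t_wrap, np.vstack([ref_kept, ref_kept[:1]]),
                        axis=0, bc_type="periodic")
                else:
                    ref_spline = CubicSpline(t, ref_kept, axis=0,
                                             bc_type="natural")
            params = _equal_arc_params(
                ref_spline, float(ref_spline.x[-1]), n_out, closed)
        out[:, p, :] = spline(params)
    return out


def frame_vectors(points: np.ndarray, closed: bool,
                  interior_hint: np.ndarray) -> CurveFrame:
    """Unit tangents and outward normals along a (resampled) contour.

    Tangents are normalised spline derivatives; each normal is the tangent
    rotated 90 deg with its sign chosen to point away from
    ``interior_hint`` (the cavity side).
    """
    spline, t = fit_spline(points, closed)
    pts = _dedupe(points)
    if closed and np.linalg.norm(pts[-1] - pts[0]) <= 1e-12:
        pts = pts[:-1]
    deriv = spline.derivative()(t)
    speed = np.linalg.norm(deriv, axis=1)
    if np.any(speed < 1e-12):
        raise ValueError("degenerate spline: zero-length derivative")
    tangents = deriv / speed[:, None]
    # 90 deg counterclockwise rotation of the tangent
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    hint = np.asarray(interior_hint, dtype=float)
    outward = pts - hint[None, :]
    flip = np.sum(normals * outward, axis=1) < 0
    normals[flip] *= -1.0
    if closed:
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    else:
        arc = t - t[0]
    return CurveFrame(tangents=tangents, normals=normals, arc_positions=arc)
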
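"""Synthetic LV cine phantom with known ground-truth motion.

Short-axis slices are concentric circles (120 points/border) whose radii
contract by a prescribed amplitude, optionally rotating (twist) and
translating.  Long-axis slices are open U-shaped (capsule-offset)
contours (500 points/border) whose wall points move towards the central
axis by the radial amplitude and towards the apex by a longitudinal
amplitude that is constant over the basal third and tapers linearly to
zero at the apex.  All motion follows a raised-cosine activation
``s(t) = (1 - cos 2*pi*t)/2`` sampled at ``t = p/(n_phases - 1)``, so the
peak (s = 1) is attained exactly for odd phase counts and prescribed
amplitudes equal the expected maximum pairwise displacements.

A cohort generator emulates the four LV-function groups via
group-dependent amplitude scales with lognormal inter-patient
variability; each subject's LVEF is computed from a prolate-ellipsoid
volume proxy and guaranteed to fall in the group's range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CineSlice, ContourSeries, SliceGeometry, Subject
from .segmentation import (assign_long_axis_segments,
                           assign_short_axis_segments, define_long_axis,
                           endo_apex_extent)

N_LONG = 500
N_SHORT = 120


@dataclass
class PhantomParams:
    """Geometry and motion amplitudes of one synthetic LV."""

    epi_radius_ed: float = 33.0
    endo_radius_ed: float = 25.0
    radial_amp_epi: float = 4.5
    radial_amp_endo: float = 9.0
    long_axis_length_ed: float = 90.0
    longitudinal_amp_base: float = 8.0
    twist_deg: float = 0.0
    translation_amp: tuple[float, float] = (0.0, 0.0)
    n_phases: int = 25

    def __post_init__(self) -> None:
        if self.endo_radius_ed >= self.epi_radius_ed:
            raise ValueError("endo_radius_ed must be < epi_radius_ed")
        if min(self.radial_amp_epi, self.radial_amp_endo,
               self.longitudinal_amp_base) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.radial_amp_endo < self.radial_amp_epi:
            raise ValueError("radial_amp_endo must be >= radial_amp_epi "
                             "(endocardium moves more)")
        if self.radial_amp_endo >= self.endo_radius_ed:
            raise ValueError("radial amplitude exceeds cavity radius")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.long_axis_length_ed <= self.epi_radius_ed:
            raise ValueError("long axis must be longer than the epi radius")


def activation(n_phases: int) -> np.ndarray:
    """Raised-cosine activation sampled over one full cycle."""
    t = np.arange(n_phases) / (n_phases - 1)
    return 0.5 * (1.0 - np.cos(2.0 * math.pi * t))


def longitudinal_factor(axial_fraction: np.ndarray) -> np.ndarray:
    """Base-amplitude multiplier along the axis.

    Constant 1 over the basal third, linear taper to 0 at the apex.
    """
    f = np.clip(np.asarray(axial_fraction, dtype=float), 0.0, 1.0)
    return np.where(f <= 1.0 / 3.0, 1.0, (1.0 - f) * 1.5)


_SAX_GEOMETRY = {
    "basal": SliceGeometry((1.0, 1.0), np.array([0.0, 0.0, 30.0]),
                           np.array([1.0, 0.0, 0.0]),
                           np.array([0.0, 1.0, 0.0])),
    "mid": SliceGeometry((1.0, 1.0), np.array([0.0, 0.0, 60.0]),
                         np.array([1.0, 0.0, 0.0]),
                         np.array([0.0, 1.0, 0.0])),
}

_LAX_GEOMETRY = {
    "LAX_2CH": SliceGeometry((1.0, 1.0), np.zeros(3),
                             np.array([1.0, 0.0, 0.0]),
                             np.array([0.0, 0.0, -1.0])),
    "LAX_3CH": SliceGeometry((1.0, 1.0), np.zeros(3),
                             np.array([math.sqrt(0.5), math.sqrt(0.5), 0.0]),
                             np.array([0.0, 0.0, -1.0])),
    "LAX_4CH": SliceGeometry((1.0, 1.0), np.zeros(3),
                             np.array([0.0, 1.0, 0.0]),
                             np.array([0.0, 0.0, -1.0])),
}

_SAX_CENTER = np.array([60.0, 60.0])
_LAX_BASE = np.array([60.0, 30.0])  # basal opening midpoint in slice mm


def make_short_axis_slice(params: PhantomParams, level: str,
                          seed: int | None = None) -> CineSlice:
    """Closed concentric-circle phantom slice (120 points per border)."""
    if level not in ("basal", "mid"):
        raise ValueError("level must be 'basal' or 'mid'")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * math.pi) if seed is not None else 0.0
    s = activation(params.n_phases)
    phi = math.radians(params.twist_deg)
    d = np.asarray(params.translation_amp, dtype=float)
    theta = theta0 + 2.0 * math.pi * np.arange(N_SHORT) / N_SHORT
    series = {}
    for border, r0, amp in (("epi", params.epi_radius_ed, params.radial_amp_epi),
                            ("endo", params.endo_radius_ed,
                             params.radial_amp_endo)):
        phases = []
        for sp in s:
            ang = theta + phi * sp
            r = r0 - amp * sp
            center = _SAX_CENTER + d * sp
            phases.append(np.column_stack([center[0] + r * np.cos(ang),
                                           center[1] + r * np.sin(ang)]))
        series[border] = ContourSeries(points=phases, closed=True)
    return CineSlice(
        slice_id=f"sax_{level}", view=f"SAX_{level.upper()}",
        geometry=_SAX_GEOMETRY[level], n_phases=params.n_phases,
        epi=series["epi"], endo=series["endo"])


def _capsule(n: int, half_width: float, arc_depth: float,
             base: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Open U contour: two walls plus an apex semicircle.

    Returns (points, outward normals, axial depth a) ordered from the
    (-u) basal endpoint around the apex to the (+u) basal endpoint.
    ``a`` is the depth below the basal opening (0 at base).
    """
    w, lc = half_width, arc_depth
    total = 2.0 * lc + math.pi * w
    arc = np.linspace(0.0, total, n)
    pts = np.empty((n, 2))
    nrm = np.empty((n, 2))
    a = np.empty(n)
    left = arc <= lc
    pts[left, 0] = -w
    pts[left, 1] = -arc[left]
    nrm[left] = (-1.0, 0.0)
    a[left] = arc[left]
    on_arc = (arc > lc) & (arc < lc + math.pi * w)
    ang = math.pi + (arc[on_arc] - lc) / w  # 180 deg -> 360 deg
    pts[on_arc, 0] = w * np.cos(ang)
    pts[on_arc, 1] = -lc + w * np.sin(ang)
    nrm[on_arc, 0] = np.cos(ang)
    nrm[on_arc, 1] = np.sin(ang)
    a[on_arc] = lc - w * np.sin(ang)
    right = arc >= lc + math.pi * w
    pts[right, 0] = w
    pts[right, 1] = -(total - arc[right])
    nrm[right] = (1.0, 0.0)
    a[right] = total - arc[right]
    pts += base[None, :]
    return pts, nrm, a


def _lax_border_params(params: PhantomParams) -> dict:
    """Per-border capsule half-width, arc depth and radial amplitude."""
    wall = params.epi_radius_ed - params.endo_radius_ed
    epi_depth = params.long_axis_length_ed
    endo_depth = epi_depth - wall
    return {
        "epi": (params.epi_radius_ed, epi_depth - params.epi_radius_ed,
                params.radial_amp_epi),
        "endo": (params.endo_radius_ed, endo_depth - params.endo_radius_ed,
                 params.radial_amp_endo),
    }


def _lax_displacement_field(params: PhantomParams, border: str
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                       np.ndarray]:
    """(ED points, per-point displacement at s=1, outward normals, a)."""
    w, lc, amp = _lax_border_params(params)[border]
    pts, nrm, a = _capsule(N_LONG, w, lc, _LAX_BASE)
    frac = a / params.long_axis_length_ed
    g = longitudinal_factor(frac)
    disp = (-amp * nrm
            + np.column_stack([np.zeros(N_LONG),
                               -params.longitudinal_amp_base * g])
            + np.asarray(params.translation_amp, dtype=float)[None, :])
    return pts, disp, nrm, a


def make_long_axis_slice(params: PhantomParams, view: str,
                         seed: int | None = None) -> CineSlice:
    """Open U-shaped phantom slice (500 points per border).

    The epicardial contour extends beyond the endocardial apex so the
    apical cap (segment 17) is populated.
    """
    if view not in _LAX_GEOMETRY:
        raise ValueError(f"view must be a long-axis view, got {view!r}")
    s = activation(params.n_phases)
    series = {}
    for border in ("epi", "endo"):
        pts, disp, _, _ = _lax_displacement_field(params, border)
        phases = [pts + sp * disp for sp in s]
        series[border] = ContourSeries(points=phases, closed=False)
    return CineSlice(
        slice_id=view.lower(), view=view, geometry=_LAX_GEOMETRY[view],
        n_phases=params.n_phases, epi=series["epi"], endo=series["endo"])


def long_axis_ground_truth(params: PhantomParams, view: str) -> pd.DataFrame:
    """Analytic per-segment expected displacement means for a LAX phantom.

    Uses the exact displacement field and exact contour frames (walls:
    axis-parallel tangents; apex arc: polar frames) with the same segment
    assignment rule as the pipeline.  Columns: border, segment, overall,
    tangential, normal.
    """
    epi_pts, _, _, _ = _lax_displacement_field(params, "epi")
    axis = define_long_axis(epi_pts)
    endo_pts, _, _, _ = _lax_displacement_field(params, "endo")
    apex_extent = endo_apex_extent(endo_pts, axis)
    rows = []
    for border in ("epi", "endo"):
        pts, disp, nrm, _ = _lax_displacement_field(params, border)
        tang = np.column_stack([-nrm[:, 1], nrm[:, 0]])  # 90 deg rotation
        assign = assign_long_axis_segments(pts, border, axis, view,
                                           apex_extent)
        overall = np.linalg.norm(disp, axis=1)
        t_comp = np.abs(np.sum(disp * tang, axis=1))
        n_comp = np.abs(np.sum(disp * nrm, axis=1))
        df = pd.DataFrame({"segment": assign.labels, "overall": overall,
                           "tangential": t_comp, "normal": n_comp})
        agg = df.groupby("segment").mean().reset_index()
        agg.insert(0, "border", border)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class GroupSpec:
    """Per-group amplitude scale, cavity geometry and LVEF range."""

    scale: float
    endo_radius: float
    epi_radius: float
    lvef_range: tuple[float, float]
    height: tuple[float, float]  # mean, sd (cm)
    weight: tuple[float, float]  # mean, sd (kg)


DEFAULT_GROUP_SPECS: dict[str, GroupSpec] = {
    # Control: normal cavity, full contraction.
    "control": GroupSpec(1.0, 25.0, 33.0, (55.0, 80.0),
                         (170.0, 10.7), (79.3, 15.8)),
    # HFpEF: reduced displacement but preserved EF via a smaller
    # (hypertrophic) cavity.
    "HFpEF": GroupSpec(0.8, 22.0, 33.0, (55.0, 80.0),
                       (167.5, 10.4), (87.9, 18.6)),
    "HFmrEF": GroupSpec(0.75, 25.0, 33.0, (40.0, 55.0),
                        (168.5, 9.4), (82.5, 17.9)),
    # HFrEF: dilated thin-walled cavity, weakest contraction.
    "HFrEF": GroupSpec(0.6, 30.0, 36.0, (15.0, 40.0),
                       (172.1, 10.2), (86.6, 20.8)),
}


@dataclass
class CohortRecipe:
    """Recipe for a synthetic four-group cohort."""

    n_per_group: int = 50
    seed: int = 0
    amp_sigma: float = 0.2          # lognormal sd on amplitudes
    n_phases: int = 25
    base_radial_amp_endo: float = 9.0
    base_longitudinal_amp: float = 8.0
    epi_radial_fraction: float = 0.5  # epi amplitude / endo amplitude
    twist_deg: float = 3.0
    translation_amp: tuple[float, float] = (0.5, 0.3)
    group_specs: dict[str, GroupSpec] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SPECS))
    max_tries: int = 200

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g, spec in self.group_specs.items():
            lo, hi = spec.lvef_range
            ok = {"control": True,
                  "HFpEF": lo >= 55.0,
                  "HFmrEF": lo >= 40.0 and hi <= 55.0,
                  "HFrEF": hi <= 40.0}.get(g, True)
            if not ok:
                raise ValueError(
                    f"group {g}: LVEF range {spec.lvef_range} violates the "
                    "HFpEF>55 / HFmrEF 40-55 / HFrEF<40 cutoffs")


def lvef_proxy(radial_amp_endo: float, longitudinal_amp: float,
               endo_radius: float, long_axis_length: float) -> float:
    """Prolate-ellipsoid ejection-fraction proxy (percent).

    ED and peak-contraction cavity volumes are modelled as ellipsoids of
    revolution about the long axis; monotone increasing in the endocardial
    radial amplitude.
    """
    r_es = endo_radius - radial_amp_endo
    l_es = long_axis_length - longitudinal_amp
    if r_es <= 0 or l_es <= 0:
        raise ValueError("contraction amplitudes exceed cavity dimensions")
    return 100.0 * (1.0 - (l_es / long_axis_length)
                    * (r_es / endo_radius) ** 2)


def _lvef_in_range(group: str, lvef: float, rng_lo: float,
                   rng_hi: float) -> bool:
    if group == "HFpEF":
        return 55.0 < lvef <= rng_hi
    if group == "HFmrEF":
        return 40.0 <= lvef <= 55.0 and rng_lo <= lvef <= rng_hi
    if group == "HFrEF":
        return rng_lo <= lvef < 40.0
    return rng_lo <= lvef <= rng_hi


def _subject_params(recipe: CohortRecipe, group: str,
                    rng: np.random.Generator) -> tuple[PhantomParams, float]:
    spec = recipe.group_specs[group]
    sigma = recipe.amp_sigma
    for _ in range(recipe.max_tries):
        noise_r = rng.lognormal(-0.5 * sigma ** 2, sigma)
        noise_l = rng.lognormal(-0.5 * sigma ** 2, sigma)
        a_endo = recipe.base_radial_amp_endo * spec.scale * noise_r
        a_long = recipe.base_longitudinal_amp * spec.scale * noise_l
        r_endo = spec.endo_radius * (1.0 + 0.04 * rng.normal())
        r_epi = max(spec.epi_radius * (1.0 + 0.04 * rng.normal()),
                    r_endo + 2.0)
        length = 90.0 * (1.0 + 0.05 * rng.normal())
        if a_endo >= r_endo or a_long >= length:
            continue
        # check the rounded value so the stored (1-decimal) LVEF still
        # satisfies the group cutoffs
        lvef = round(lvef_proxy(a_endo, a_long, r_endo, length), 1)
        if not _lvef_in_range(group, lvef, *spec.lvef_range):
            continue
        params = PhantomParams(
            epi_radius_ed=r_epi, endo_radius_ed=r_endo,
            radial_amp_epi=recipe.epi_radial_fraction * a_endo,
            radial_amp_endo=a_endo,
            long_axis_length_ed=length, longitudinal_amp_base=a_long,
            twist_deg=recipe.twist_deg,
            translation_amp=recipe.translation_amp,
            n_phases=recipe.n_phases)
        return params, lvef
    raise RuntimeError(
        f"could not draw LVEF in range {spec.lvef_range} for group {group} "
        f"after {recipe.max_tries} tries; amplitude scale {spec.scale} and "
        f"cavity geometry are inconsistent with the target range")


def generate_cohort(recipe: CohortRecipe) -> list[Subject]:
    """Deterministically generate a four-group synthetic cohort.

    Each subject receives 2-/3-/4-chamber long-axis and basal/mid
    short-axis slices.  All randomness derives from ``recipe.seed`` via a
    spawned per-subject seed sequence.
    """
    root_ss = np.random.SeedSequence(recipe.seed)
    subjects: list[Subject] = []
    groups = list(recipe.group_specs)
    child_ss = root_ss.spawn(len(groups) * recipe.n_per_group)
    idx = 0
    for group in groups:
        n = recipe.n_per_group
        n_male = round(0.64 * n) if group == "HFrEF" else n // 2
        for k in range(n):
            rng = np.random.default_rng(child_ss[idx])
            idx += 1
            params, lvef = _subject_params(recipe, group, rng)
            spec = recipe.group_specs[group]
            height = max(float(rng.normal(*spec.height)), 120.0)
            weight = max(float(rng.normal(*spec.weight)), 35.0)
            nyha = int(rng.integers(1, 4)) if group != "control" else None
            slices = [
                make_long_axis_slice(params, "LAX_2CH"),
                make_long_axis_slice(params, "LAX_3CH"),
                make_long_axis_slice(params, "LAX_4CH"),
                make_short_axis_slice(params, "basal",
                                      seed=int(rng.integers(2 ** 31))),
                make_short_axis_slice(params, "mid",
                                      seed=int(rng.integers(2 ** 31))),
            ]
            subjects.append(Subject(
                subject_id=f"{group}_{k:03d}", group=group,
                sex="M" if k < n_male else "F",
                height=round(height, 1), weight=round(weight, 1),
                lvef=lvef, nyha=nyha, slices=slices))
    return subjects
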
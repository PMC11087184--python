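"""Model/Results interface for regional LV motion analysis.

:class:`RegionalMotionModel` is built from a list of validated
:class:`~lvmotion.io.Subject` objects (or a study directory) and a small
amount of configuration; ``fit()`` runs the full pipeline — material
resampling, frame computation, AHA segmentation, displacement
decomposition and per-patient aggregation — one slice at a time, and
returns a :class:`RegionalMotionResults` carrying the per-patient
segment displacements, group statistics, margin constructors and motion
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from . import margins as _margins
from . import reference as _reference
from . import stats as _stats
from .displacement import (aggregate_patient_segments, decompose_all,
                           segment_mean_displacement)
from .geometry import frame_vectors, resample_series_points
from .segmentation import (DEFAULT_VIEW_MAPPING, assign_long_axis_segments,
                           assign_short_axis_segments, define_long_axis,
                           endo_apex_extent)

N_LONG_DEFAULT = 500
N_SHORT_DEFAULT = 120


@dataclass
class AnalysisConfig:
    """Knobs of the motion analysis; defaults match the study protocol."""

    n_long: int = N_LONG_DEFAULT       # resampled points, long-axis borders
    n_short: int = N_SHORT_DEFAULT     # resampled points, short-axis borders
    alpha: float = 0.05
    pairwise: str = "welch"            # post-hoc pairwise test family
    view_mapping: dict = field(
        default_factory=lambda: dict(DEFAULT_VIEW_MAPPING))

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _interior_hint(sl: _io.CineSlice, border: str,
                   ref_points: dict[str, np.ndarray]) -> np.ndarray:
    """Cavity-side hint: endo centroid (SAX) or basal midpoint (LAX)."""
    if sl.is_long_axis:
        pts = ref_points[border]
        return 0.5 * (pts[0] + pts[-1])
    return ref_points["endo"].mean(axis=0)


def analyze_slice(sl: _io.CineSlice, config: AnalysisConfig | None = None
                  ) -> pd.DataFrame:
    """Per-segment mean displacements for one slice (both borders).

    Returns rows with plane, border, segment, overall/tangential/normal
    (mm) and n_points.
    """
    config = config or AnalysisConfig()
    n_out = config.n_long if sl.is_long_axis else config.n_short
    closed = not sl.is_long_axis
    plane = "long_axis" if sl.is_long_axis else "short_axis"

    positions = {}
    for border, series in (("epi", sl.epi), ("endo", sl.endo)):
        positions[border] = resample_series_points(
            series.points, sl.reference_phase, n_out, closed)
    ref_points = {b: positions[b][:, sl.reference_phase, :]
                  for b in ("epi", "endo")}

    if sl.is_long_axis:
        axis = define_long_axis(ref_points["epi"])
        apex_extent = endo_apex_extent(ref_points["endo"], axis)
    else:
        centroid = ref_points["endo"].mean(axis=0)
        level = "basal" if sl.view == "SAX_BASAL" else "mid"

    rows = []
    for border in ("epi", "endo"):
        ref = ref_points[border]
        frame = frame_vectors(ref, closed, _interior_hint(sl, border,
                                                          ref_points))
        if sl.is_long_axis:
            assign = assign_long_axis_segments(
                ref, border, axis, sl.view, apex_extent,
                side_polarity=sl.side_polarity, mapping=config.view_mapping)
        else:
            assign = assign_short_axis_segments(ref, level, centroid,
                                                ref_angle=sl.ref_angle)
        per_point = decompose_all(positions[border], frame.tangents,
                                  frame.normals)
        seg = segment_mean_displacement(per_point, assign)
        seg.insert(0, "border", border)
        seg.insert(0, "plane", plane)
        seg.insert(0, "slice_id", sl.slice_id)
        rows.append(seg)
    return pd.concat(rows, ignore_index=True)


def slice_motion_traces(sl: _io.CineSlice,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-phase signed (tangential, normal) traces of segment midpoints.

    For each border and segment, the trace of the arc-wise middle point
    of that segment is reported relative to the reference phase.
    """
    config = config or AnalysisConfig()
    n_out = config.n_long if sl.is_long_axis else config.n_short
    closed = not sl.is_long_axis

    positions = {}
    for border, series in (("epi", sl.epi), ("endo", sl.endo)):
        positions[border] = resample_series_points(
            series.points, sl.reference_phase, n_out, closed)
    ref_points = {b: positions[b][:, sl.reference_phase, :]
                  for b in ("epi", "endo")}

    if sl.is_long_axis:
        axis = define_long_axis(ref_points["epi"])
        apex_extent = endo_apex_extent(ref_points["endo"], axis)
    else:
        centroid = ref_points["endo"].mean(axis=0)
        level = "basal" if sl.view == "SAX_BASAL" else "mid"

    out = []
    for border in ("epi", "endo"):
        ref = ref_points[border]
        frame = frame_vectors(ref, closed, _interior_hint(sl, border,
                                                          ref_points))
        if sl.is_long_axis:
            assign = assign_long_axis_segments(
                ref, border, axis, sl.view, apex_extent,
                side_polarity=sl.side_polarity, mapping=config.view_mapping)
        else:
            assign = assign_short_axis_segments(ref, level, centroid,
                                                ref_angle=sl.ref_angle)
        for seg in np.unique(assign.labels):
            idx = np.flatnonzero(assign.labels == seg)
            mid = int(idx[len(idx) // 2])
            rel = positions[border][mid] - ref[mid]
            out.append(pd.DataFrame({
                "slice_id": sl.slice_id, "border": border, "segment": seg,
                "phase": np.arange(sl.n_phases),
                "tang_mm": rel @ frame.tangents[mid],
                "norm_mm": rel @ frame.normals[mid],
            }))
    return pd.concat(out, ignore_index=True)


class RegionalMotionModel:
    """Regional LV myocardial motion analysis over a cohort.

    Parameters
    ----------
    subjects : sequence of Subject
        Validated subjects with tracked cine contours.
    config : AnalysisConfig, optional
        Resampling counts, significance level, post-hoc test family and
        segment mapping overrides.
    """

    def __init__(self, subjects: Sequence[_io.Subject],
                 config: AnalysisConfig | None = None):
        if not subjects:
            raise ValueError("no subjects supplied")
        self.subjects = list(subjects)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_directory(cls, path: str | Path,
                       config: AnalysisConfig | None = None
                       ) -> "RegionalMotionModel":
        """Build the model from an interchange-format study directory."""
        return cls(_io.load_study(path), config=config)

    def fit(self) -> "RegionalMotionResults":
        """Run the motion analysis for every subject, one slice at a time."""
        slice_rows = []
        for subj in self.subjects:
            for sl in subj.slices:
                df = analyze_slice(sl, self.config)
                df.insert(0, "subject_id", subj.subject_id)
                slice_rows.append(df)
        slice_disp = pd.concat(slice_rows, ignore_index=True)
        per_patient = aggregate_patient_segments(slice_disp)
        return RegionalMotionResults(self, slice_disp, per_patient)


class RegionalMotionResults:
    """Fitted per-patient segment displacements and cohort statistics."""

    def __init__(self, model: RegionalMotionModel,
                 slice_displacements: pd.DataFrame,
                 displacements: pd.DataFrame):
        self.model = model
        #: per-slice segment means (subject_id, slice_id, plane, border, ...)
        self.slice_displacements = slice_displacements
        #: per-patient segment means, multi-slice segments n_points-weighted
        self.displacements = displacements
        self.subjects = _io.subjects_table(model.subjects)
        self._group_tables: pd.DataFrame | None = None

    @property
    def group_tables(self) -> pd.DataFrame:
        """Group mean/SD/ANOVA/post-hoc table per segment cell."""
        if self._group_tables is None:
            self._group_tables = _stats.build_group_tables(
                self.displacements, self.subjects,
                alpha=self.model.config.alpha,
                pairwise=self.model.config.pairwise)
        return self._group_tables

    def group_table(self, plane: str = "long_axis", border: str = "epi",
                    component: str = "overall") -> pd.DataFrame:
        """One study-style formatted table ('mean ± sd' plus p-value)."""
        return _stats.format_group_table(self.group_tables, plane, border,
                                         component)

    def segment_displacement_means(self, group: str, segment: int,
                                   plane: str = "long_axis") -> dict:
        """Fitted {border: (tangential, normal)} group means for a segment.

        On long-axis slices the tangential component is the longitudinal
        displacement and the normal component the radial one — the inputs
        the ITV margin constructors expect.
        """
        tab = self.group_tables
        out = {}
        for border in ("epi", "endo"):
            sel = tab[(tab["plane"] == plane) & (tab["border"] == border)
                      & (tab["segment"] == segment)]
            comp = {}
            for name in ("tangential", "normal"):
                row = sel[sel["component"] == name]
                if row.empty:
                    raise ValueError(
                        f"no fitted data for segment {segment} ({border})")
                comp[name] = float(row[f"{group}_mean"].iloc[0])
            out[border] = (comp["tangential"], comp["normal"])
        return out

    def itv_margins(self, group: str, segment: int, strategy: str,
                    source: str = "fitted") -> _margins.MarginSpec:
        """ITV margin spec for one group/segment under a matching strategy.

        ``source='fitted'`` uses this cohort's fitted long-axis group
        means; ``source='reference'`` uses the bundled published table.
        """
        if source == "fitted":
            disp = self.segment_displacement_means(group, segment)
        elif source == "reference":
            disp = _reference.segment_means(group, segment)
        else:
            raise ValueError("source must be 'fitted' or 'reference'")
        if strategy == "whole_lv_match":
            return _margins.itv_whole_lv_match(disp)
        if strategy == "target_centered":
            return _margins.itv_target_centered(disp)
        raise ValueError(f"unknown strategy {strategy!r}")

    def motion_traces(self, subject_id: str,
                      slice_id: str | None = None) -> pd.DataFrame:
        """Segment-midpoint motion traces for one subject."""
        subj = next((s for s in self.model.subjects
                     if s.subject_id == subject_id), None)
        if subj is None:
            raise KeyError(f"unknown subject {subject_id!r}")
        frames = []
        for sl in subj.slices:
            if slice_id is not None and sl.slice_id != slice_id:
                continue
            df = slice_motion_traces(sl, self.model.config)
            df.insert(0, "subject_id", subject_id)
            frames.append(df)
        if not frames:
            raise KeyError(f"no slice {slice_id!r} for subject {subject_id}")
        return pd.concat(frames, ignore_index=True)

    def plot_traces(self, subject_id: str, slice_id: str, ax=None):
        """Plot segment-midpoint motion traces of one slice."""
        import matplotlib.pyplot as plt

        traces = self.motion_traces(subject_id, slice_id)
        if ax is None:
            _, ax = plt.subplots()
        for (border, seg), g in traces.groupby(["border", "segment"]):
            ax.plot(g["tang_mm"], g["norm_mm"],
                    label=f"{border} seg {seg}", lw=0.8)
        ax.set_xlabel("tangential (mm)")
        ax.set_ylabel("normal (mm)")
        ax.set_title(f"{subject_id} / {slice_id}")
        return ax

    def summary(self, plane: str = "long_axis",
                component: str = "overall") -> str:
        """Readable cohort summary with one formatted table per border."""
        lines = [
            "Regional LV myocardial motion analysis",
            "=" * 54,
            f"subjects: {len(self.subjects)}  groups: "
            f"{ {k: int(v) for k, v in self.subjects['group'].value_counts().items()} }",
            f"plane: {plane}  component: {component}  "
            f"alpha: {self.model.config.alpha}",
        ]
        for border in ("epi", "endo"):
            tab = self.group_table(plane, border, component)
            if tab.empty:
                continue
            name = "Epicardium" if border == "epi" else "Endocardium"
            lines += ["", f"{name} ({component}, mm, mean ± SD; "
                          "marks: a vs control, b vs HFpEF, c vs HFmrEF)",
                      tab.to_string(index=False)]
        return "\n".join(lines)
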
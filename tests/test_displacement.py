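"""Displacement maxima, decomposition identities and segment means."""

import numpy as np
import pandas as pd
import pytest

from lvmotion.displacement import (PointTrajectory, decompose_all,
                                   decompose_displacement,
                                   aggregate_patient_segments,
                                   max_overall_displacement,
                                   max_projected_displacement, motion_trace,
                                   segment_mean_displacement)
from lvmotion.segmentation import SegmentAssignment

EX = np.array([1.0, 0.0])
EY = np.array([0.0, 1.0])


def _traj(positions, tangent=EX, normal=EY) -> PointTrajectory:
    return PointTrajectory(np.asarray(positions, dtype=float), tangent, normal)


def brute_force_max_pair(positions: np.ndarray) -> float:
    """Independent O(P^2) loop oracle."""
    best = 0.0
    P = len(positions)
    for i in range(P):
        for j in range(i + 1, P):
            best = max(best, float(np.linalg.norm(positions[j] - positions[i])))
    return best


class TestMaxima:
    def test_constant_trajectory_is_zero(self):
        assert max_overall_displacement(_traj(np.zeros((10, 2)))) == 0.0

    def test_two_phase_distance(self):
        t = _traj([[0, 0], [4.5, 6.0]])
        assert max_overall_displacement(t) == pytest.approx(7.5)

    def test_circle_trajectory_diameter(self):
        ang = 2 * np.pi * np.arange(30) / 30
        pos = 3.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        t = _traj(pos)
        got = max_overall_displacement(t)
        assert got == pytest.approx(brute_force_max_pair(pos), abs=1e-12)
        assert got == pytest.approx(6.0, rel=1e-2)  # near-diameter chord

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            max_overall_displacement(_traj([[0, 0]]))

    def test_projection_orthogonal_motion_zero(self):
        pos = np.column_stack([np.zeros(10), np.linspace(0, 5, 10)])
        assert max_projected_displacement(_traj(pos), EX) == 0.0

    def test_projection_monotone_translation(self):
        pos = np.column_stack([np.linspace(0, 4.2, 25), np.zeros(25)])
        assert max_projected_displacement(_traj(pos), EX) == pytest.approx(4.2)

    def test_projection_raised_cosine_amplitude(self):
        s = 0.5 * (1 - np.cos(2 * np.pi * np.arange(25) / 24))
        pos = np.column_stack([3.7 * s, np.zeros(25)])
        assert max_projected_displacement(_traj(pos), EX) == pytest.approx(3.7)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            max_projected_displacement(_traj(np.zeros((3, 2))),
                                       np.array([1.0, 1.0]))


class TestDecompose:
    def test_pure_radial_contraction(self):
        # point on a circle moving radially inward by 2 mm
        p0 = np.array([5.0, 0.0])
        s = 0.5 * (1 - np.cos(2 * np.pi * np.arange(25) / 24))
        pos = p0[None, :] * (1 - 0.4 * s)[:, None]  # radius 5 -> 3
        t = PointTrajectory(pos, tangent=EY, normal=EX)
        overall, tang, norm = decompose_displacement(t)
        assert tang < 1e-6
        assert overall == pytest.approx(2.0) and norm == pytest.approx(2.0)

    def test_rigid_translation_projection_identity(self, rng):
        d = rng.normal(size=2) * 4
        theta = rng.uniform(0, 2 * np.pi)
        tangent = np.array([np.cos(theta), np.sin(theta)])
        normal = np.array([-np.sin(theta), np.cos(theta)])
        pos = np.zeros((12, 2)) + np.linspace(0, 1, 12)[:, None] * d
        overall, tang, norm = decompose_displacement(
            PointTrajectory(pos, tangent, normal))
        assert overall == pytest.approx(np.linalg.norm(d))
        assert tang == pytest.approx(abs(d @ tangent))
        assert norm == pytest.approx(abs(d @ normal))
        assert tang**2 + norm**2 == pytest.approx(np.linalg.norm(d)**2,
                                                  abs=1e-9)

    def test_rotation_chord_closed_form(self):
        # point on a circle (radius R) rotating by theta about the centre
        R, theta = 10.0, np.radians(40.0)
        s = 0.5 * (1 - np.cos(2 * np.pi * np.arange(25) / 24))
        ang = theta * s
        pos = R * np.column_stack([np.cos(ang), np.sin(ang)])
        t = PointTrajectory(pos, tangent=EY, normal=EX)
        overall, tang, norm = decompose_displacement(t)
        chord = 2 * R * np.sin(theta / 2)
        assert overall == pytest.approx(chord, rel=1e-9)
        assert tang == pytest.approx(chord * np.cos(theta / 2), rel=1e-9)
        assert norm == pytest.approx(chord * np.sin(theta / 2), rel=1e-9)

    def test_ordering_invariant(self, rng):
        for _ in range(50):
            pos = rng.normal(size=(12, 2)) * 3
            overall, tang, norm = decompose_displacement(_traj(pos))
            assert max(tang, norm) <= overall + 1e-12
            assert overall <= np.hypot(tang, norm) + 1e-12

    def test_vectorised_matches_scalar(self, rng):
        pos = rng.normal(size=(40, 15, 2)) * 5
        theta = rng.uniform(0, 2 * np.pi, size=40)
        tangents = np.column_stack([np.cos(theta), np.sin(theta)])
        normals = np.column_stack([-np.sin(theta), np.cos(theta)])
        block = decompose_all(pos, tangents, normals)
        for k in range(40):
            exp = decompose_displacement(
                PointTrajectory(pos[k], tangents[k], normals[k]))
            np.testing.assert_allclose(block[k], exp, atol=1e-12)

    def test_rigid_rotation_of_slice_invariance(self, rng):
        # rotating the whole slice (motion and frames together) leaves
        # every reported displacement unchanged
        pos = rng.normal(size=(20, 10, 2)) * 4
        theta = rng.uniform(0, 2 * np.pi, size=20)
        tangents = np.column_stack([np.cos(theta), np.sin(theta)])
        normals = np.column_stack([-np.sin(theta), np.cos(theta)])
        base = decompose_all(pos, tangents, normals)
        c, s = np.cos(0.77), np.sin(0.77)
        rot = np.array([[c, -s], [s, c]])
        rotated = decompose_all(pos @ rot.T, tangents @ rot.T,
                                normals @ rot.T)
        np.testing.assert_allclose(rotated, base, atol=1e-9)


class TestTraces:
    def test_reference_phase_is_origin(self, rng):
        pos = rng.normal(size=(8, 2))
        tr = motion_trace(_traj(pos))
        np.testing.assert_array_equal(tr[0], [0.0, 0.0])

    def test_inward_motion_negative_radial(self):
        # outward normal EX; motion towards the cavity (negative x)
        pos = np.column_stack([np.linspace(0, -3, 10), np.zeros(10)])
        tr = motion_trace(PointTrajectory(pos, tangent=EY, normal=EX))
        assert np.all(tr[1:, 1] < 0)

    def test_trace_magnitude_bounded_by_overall(self, rng):
        for _ in range(20):
            pos = rng.normal(size=(15, 2)) * 2
            t = _traj(pos)
            tr = motion_trace(t)
            assert np.hypot(tr[:, 0], tr[:, 1]).max() \
                <= max_overall_displacement(t) + 1e-12


class TestSegmentMeans:
    def test_mean_of_constants(self):
        vals = np.tile([5.0, 3.0, 4.0], (7, 1))
        asn = SegmentAssignment(labels=np.full(7, 2),
                                level=np.array(["basal"] * 7, dtype=object))
        out = segment_mean_displacement(vals, asn)
        assert out.loc[0, ["overall", "tangential", "normal"]].tolist() \
            == [5.0, 3.0, 4.0]
        assert out.loc[0, "n_points"] == 7

    def test_two_point_mean(self):
        vals = np.array([[2.0, 1.0, 1.0], [4.0, 3.0, 3.0]])
        asn = SegmentAssignment(labels=np.array([4, 4]),
                                level=np.array(["basal"] * 2, dtype=object))
        out = segment_mean_displacement(vals, asn)
        assert out.loc[0, ["overall", "tangential", "normal"]].tolist() \
            == [3.0, 2.0, 2.0]

    def test_matches_independent_accumulation(self, rng):
        vals = rng.uniform(0, 10, size=(200, 3))
        labels = rng.integers(1, 7, size=200)
        asn = SegmentAssignment(labels=labels,
                                level=np.array(["basal"] * 200, dtype=object))
        out = segment_mean_displacement(vals, asn).set_index("segment")
        # independent accumulation loop
        sums: dict = {}
        counts: dict = {}
        for row, lab in zip(vals, labels):
            sums[lab] = sums.get(lab, np.zeros(3)) + row
            counts[lab] = counts.get(lab, 0) + 1
        for lab in sums:
            np.testing.assert_allclose(
                out.loc[lab, ["overall", "tangential", "normal"]],
                sums[lab] / counts[lab], atol=1e-12)
            assert out.loc[lab, "n_points"] == counts[lab]

    def test_length_mismatch_rejected(self):
        asn = SegmentAssignment(labels=np.array([1, 2]),
                                level=np.array(["basal"] * 2, dtype=object))
        with pytest.raises(ValueError, match="length"):
            segment_mean_displacement(np.zeros((3, 3)), asn)

    def test_multi_slice_weighted_aggregation(self):
        rec = pd.DataFrame({
            "subject_id": ["a"] * 2, "plane": ["long_axis"] * 2,
            "border": ["epi"] * 2, "segment": [13, 13],
            "overall": [4.0, 6.0], "tangential": [2.0, 4.0],
            "normal": [3.0, 5.0], "n_points": [10, 30],
        })
        out = aggregate_patient_segments(rec)
        assert len(out) == 1
        assert out.loc[0, "overall"] == pytest.approx(5.5)  # 0.25*4 + 0.75*6
        assert out.loc[0, "n_points"] == 40
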
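"""Spindle-frame construction and per-frame kinematics.

Oracles: rigid transforms applied to all inputs must leave every scalar
output unchanged; the point-plane distance is cross-checked against dense
sampling of the plane; angles against high-precision arccos.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from congresskit.errors import (
    DegenerateSpindleError,
    EmptyOverlapError,
    UndefinedAngleError,
    UndefinedFrameError,
)
from congresskit.geometry import (
    SisterPairTrack,
    Trajectory,
    build_spindle_frames,
    compute_pair_kinematics,
    distance_to_equatorial_plane,
    distance_to_nearest_pole,
    interkinetochore_distance,
    pair_center,
    pair_orientation_angle,
    positional_angle,
)


def _static_traj(oid, otype, point, n=5):
    f = np.arange(n)
    return Trajectory(oid, otype, f, f.astype(float), np.tile(point, (n, 1)))


def _frames(pa_point, pb_point, n=5, mode="3d"):
    pa = _static_traj("A", "pole", pa_point, n)
    pb = _static_traj("B", "pole", pb_point, n)
    return build_spindle_frames(pa, pb, mode=mode)


def _rigid(rng):
    """Random rotation + translation as a callable on (3,) points."""
    R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
    tvec = rng.uniform(-5, 5, 3)
    return lambda p: R @ np.asarray(p, float) + tvec


class TestBuildSpindleFrames:
    def test_axis_aligned(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        g = fr.at(0)
        assert np.allclose(g.midpoint, [5, 0, 0])
        assert np.allclose(g.axis, [1, 0, 0])
        assert g.separation == pytest.approx(10.0)

    def test_rotated_translated_matches_transform_oracle(self):
        # same spindle rotated 30 deg about z and shifted by (3, -2, 0)
        th = np.deg2rad(30)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        shift = np.array([3.0, -2.0, 0.0])
        fr = _frames(R @ [0, 0, 0] + shift, R @ [10, 0, 0] + shift)
        g = fr.at(0)
        assert np.allclose(g.axis, R @ [1, 0, 0], atol=1e-12)
        assert g.separation == pytest.approx(10.0, abs=1e-12)
        assert np.allclose(g.midpoint, R @ [5, 0, 0] + shift, atol=1e-12)

    def test_coincident_poles_degenerate(self):
        with pytest.raises(DegenerateSpindleError):
            _frames([1, 1, 0], [1, 1, 0])

    def test_no_overlap(self):
        pa = Trajectory("A", "pole", [0, 1], [0.0, 1.0], np.zeros((2, 3)))
        pb = Trajectory(
            "B", "pole", [10, 11], [10.0, 11.0], np.tile([10.0, 0, 0], (2, 1))
        )
        with pytest.raises(EmptyOverlapError):
            build_spindle_frames(pa, pb)

    def test_midpoint_is_exact_average(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
        fr = _frames(a, b)
        assert np.array_equal(fr.at(0).midpoint, 0.5 * (a + b))

    def test_axis_is_unit(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
            if np.linalg.norm(a - b) <= 1.0:
                continue
            assert np.linalg.norm(_frames(a, b).at(0).axis) == pytest.approx(
                1.0, abs=1e-9
            )


class TestPointOps:
    def test_pair_center_examples(self):
        assert np.allclose(pair_center([0, 0, 0], [2, 0, 0]), [1, 0, 0])
        assert np.allclose(pair_center([1, 2, 3], [1, 2, 3]), [1, 2, 3])

    def test_pair_center_equidistant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p1, p2 = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
            c = pair_center(p1, p2)
            assert abs(
                np.linalg.norm(c - p1) - np.linalg.norm(c - p2)
            ) < 1e-12

    def test_interkt_distance(self):
        assert interkinetochore_distance([0, 0, 0], [0, 1.1, 0]) == pytest.approx(1.1)
        assert interkinetochore_distance([3, 4, 5], [3, 4, 5]) == 0.0

    def test_interkt_rigid_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p1, p2 = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
            T = _rigid(rng)
            assert interkinetochore_distance(T(p1), T(p2)) == pytest.approx(
                interkinetochore_distance(p1, p2), abs=1e-9
            )


class TestDistanceToPlane:
    def test_examples(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        assert distance_to_equatorial_plane([7, 3, 0], fr, 0) == pytest.approx(2.0)
        assert distance_to_equatorial_plane(fr.at(0).midpoint, fr, 0) == 0.0

    def test_undefined_frame(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        with pytest.raises(UndefinedFrameError):
            distance_to_equatorial_plane([0, 0, 0], fr, 99)

    def test_brute_force_plane_sampling(self):
        from oracles import brute_force_plane_distance

        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.uniform(-8, 8, 3), rng.uniform(-8, 8, 3)
            if np.linalg.norm(a - b) <= 1.5:
                continue
            fr = _frames(a, b)
            g = fr.at(0)
            p = rng.uniform(-8, 8, 3)
            brute = brute_force_plane_distance(p, g.midpoint, g.axis)
            assert distance_to_equatorial_plane(p, fr, 0) == pytest.approx(
                brute, abs=1e-3
            )


class TestNearestPole:
    def test_examples_and_tie_break(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        assert distance_to_nearest_pole([1, 0, 0], fr, 0) == (1.0, "A")
        assert distance_to_nearest_pole([5, 0, 0], fr, 0) == (5.0, "A")
        assert distance_to_nearest_pole([9, 0, 0], fr, 0) == (1.0, "B")

    def test_exhaustive_two_candidate(self):
        rng = np.random.default_rng(3)
        fr = _frames([0, 0, 0], [10, 0, 0])
        for _ in range(50):
            p = rng.uniform(-5, 15, 3)
            d, lab = distance_to_nearest_pole(p, fr, 0)
            da = np.linalg.norm(p - [0, 0, 0])
            db = np.linalg.norm(p - [10, 0, 0])
            assert d == pytest.approx(min(da, db))
            assert lab == ("A" if da <= db else "B")


class TestAngles:
    def test_positional_angle_45(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        assert positional_angle([2, 2, 0], fr, 0) == pytest.approx(45.0)

    def test_positional_angle_on_axis(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        assert positional_angle([2, 0, 0], fr, 0) == pytest.approx(0.0)

    def test_positional_angle_coincident_raises(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        with pytest.raises(UndefinedAngleError):
            positional_angle([0, 0, 0], fr, 0)

    def test_orientation_parallel_and_perpendicular(self):
        fr = _frames([0, 0, 0], [10, 0, 0])
        assert pair_orientation_angle([4, 0, 0], [6, 0, 0], fr, 0) == pytest.approx(0.0)
        assert pair_orientation_angle([5, -1, 0], [5, 1, 0], fr, 0) == pytest.approx(
            90.0
        )
        with pytest.raises(UndefinedAngleError):
            pair_orientation_angle([5, 0, 0], [5, 0, 0], fr, 0)

    def test_angles_match_high_precision_oracle(self):
        import math

        rng = np.random.default_rng(4)
        fr = _frames([0, 0, 0], [10, 0, 0])
        for _ in range(50):
            c = rng.uniform(-3, 13, 3)
            d, lab = distance_to_nearest_pole(c, fr, 0)
            pole = np.array([0, 0, 0]) if lab == "A" else np.array([10, 0, 0])
            v = c - pole
            cosang = abs(v[0]) / math.sqrt(sum(x * x for x in v))
            expected = math.degrees(math.acos(min(cosang, 1.0)))
            assert positional_angle(c, fr, 0) == pytest.approx(expected, abs=1e-9)

    def test_angles_in_acute_range(self):
        rng = np.random.default_rng(5)
        fr = _frames([0, 0, 0], [10, 0, 0])
        for _ in range(50):
            p1, p2 = rng.uniform(-3, 13, 3), rng.uniform(-3, 13, 3)
            ang = pair_orientation_angle(p1, p2, fr, 0)
            assert 0.0 <= ang <= 90.0


class TestRigidInvarianceAndSymmetry:
    def _pair_scalar_outputs(self, a, b, p1, p2):
        fr = _frames(a, b)
        c = pair_center(p1, p2)
        return np.array(
            [
                distance_to_equatorial_plane(c, fr, 0),
                distance_to_nearest_pole(c, fr, 0)[0],
                interkinetochore_distance(p1, p2),
                positional_angle(c, fr, 0),
                pair_orientation_angle(p1, p2, fr, 0),
            ]
        )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            a, b = rng.uniform(-8, 8, 3), rng.uniform(-8, 8, 3)
            if np.linalg.norm(a - b) <= 1.5:
                continue
            p1, p2 = rng.uniform(-8, 8, 3), rng.uniform(-8, 8, 3)
            if np.linalg.norm(p1 - p2) < 1e-3:
                continue
            base = self._pair_scalar_outputs(a, b, p1, p2)
            T = _rigid(rng)
            moved = self._pair_scalar_outputs(T(a), T(b), T(p1), T(p2))
            assert np.allclose(base, moved, atol=1e-9)

    def test_pole_label_reflection(self):
        rng = np.random.default_rng(9)
        a, b = np.array([0.0, 0, 0]), np.array([10.0, 2, 0])
        for _ in range(20):
            p = rng.uniform(-3, 13, 3)
            fa, fb = _frames(a, b), _frames(b, a)
            assert distance_to_equatorial_plane(p, fa, 0) == pytest.approx(
                distance_to_equatorial_plane(p, fb, 0), abs=1e-12
            )
            d1, l1 = distance_to_nearest_pole(p, fa, 0)
            d2, l2 = distance_to_nearest_pole(p, fb, 0)
            assert d1 == pytest.approx(d2)
            if np.linalg.norm(p - a) != np.linalg.norm(p - b):
                # winning physical pole is the same; its label flips with A/B
                assert l1 != l2


class TestPairKinematics:
    def _pair(self, s1_xyz, s2_xyz, frames_idx=None, t=None):
        n = len(s1_xyz)
        f1 = np.arange(n) if frames_idx is None else np.asarray(frames_idx)
        t1 = f1.astype(float) if t is None else np.asarray(t)
        s1 = Trajectory("p_s1", "kinetochore", f1, t1, s1_xyz)
        s2 = Trajectory("p_s2", "kinetochore", f1, t1, s2_xyz)
        return SisterPairTrack("p", "cell", s1, s2)

    def test_constant_configuration(self, straight_frames):
        s1 = np.tile([2.0, 0.5, 0.0], (5, 1))
        s2 = np.tile([2.0, -0.5, 0.0], (5, 1))
        kin = compute_pair_kinematics(self._pair(s1, s2), straight_frames)
        assert len(kin) == 5
        assert kin["d_plane"].nunique() == 1
        assert kin["d_plane"].iloc[0] == pytest.approx(3.0)
        assert kin["d_kt"].iloc[0] == pytest.approx(1.0)
        assert kin["theta_orient"].iloc[0] == pytest.approx(90.0)

    def test_single_frame_gap_interpolated_linearly(self, straight_frames):
        # sister positions move linearly; the missing frame 2 must equal the
        # midpoint of its neighbours
        frames_idx = [0, 1, 3, 4]
        xs = np.array([0.0, 1.0, 3.0, 4.0])
        s1 = np.column_stack([xs, np.zeros(4), np.zeros(4)])
        s2 = np.column_stack([xs, np.ones(4), np.zeros(4)])
        kin = compute_pair_kinematics(
            self._pair(s1, s2, frames_idx, np.array(frames_idx, float)),
            straight_frames,
        )
        row = kin.loc[kin["frame"] == 2].iloc[0]
        assert row["cx"] == pytest.approx(2.0)  # midpoint of 1.0 and 3.0

    def test_long_gap_left_undefined(self, straight_frames):
        frames_idx = [0, 1, 6, 7]
        s = np.tile([2.0, 0.0, 0.0], (4, 1))
        kin = compute_pair_kinematics(
            self._pair(s, s + [0, 1, 0], frames_idx, np.array(frames_idx, float)),
            straight_frames,
            max_gap=2,
        )
        assert set(kin["frame"]) == {0, 1, 6, 7}

    def test_plane_projection_identity(self, straight_frames):
        rng = np.random.default_rng(11)
        s1 = rng.uniform(0, 10, (5, 3))
        s1[:, 2] = 0
        s2 = s1 + [0.4, 0.4, 0]
        kin = compute_pair_kinematics(self._pair(s1, s2), straight_frames)
        c = kin[["cx", "cy", "cz"]].to_numpy()
        m = straight_frames.midpoint[:5]
        u = straight_frames.axis[:5]
        ident = np.abs(np.einsum("ij,ij->i", c - m, u))
        assert np.allclose(kin["d_plane"], ident, atol=1e-9)

    def test_2d_mode_ignores_z(self, straight_frames):
        s1 = np.tile([2.0, 0.5, 7.0], (5, 1))
        s2 = np.tile([2.0, -0.5, -4.0], (5, 1))
        kin = compute_pair_kinematics(self._pair(s1, s2), straight_frames, mode="2d")
        assert kin["d_kt"].iloc[0] == pytest.approx(1.0)
        assert (kin["cz"] == 0).all()


finite_coord = st.floats(-50.0, 50.0, allow_nan=False, allow_infinity=False)
point = st.tuples(finite_coord, finite_coord, finite_coord).map(np.array)


class TestHypothesisProperties:
    @settings(derandomize=True, max_examples=100)
    @given(p1=point, p2=point)
    def test_center_equidistant_and_distance_symmetric(self, p1, p2):
        c = pair_center(p1, p2)
        assert abs(np.linalg.norm(c - p1) - np.linalg.norm(c - p2)) < 1e-9
        assert interkinetochore_distance(p1, p2) == pytest.approx(
            interkinetochore_distance(p2, p1), abs=1e-12
        )

    @settings(derandomize=True, max_examples=100)
    @given(p=point, shift=finite_coord)
    def test_plane_distance_nonnegative_and_translation_along_axis(
        self, p, shift
    ):
        fr = _frames([0, 0, 0], [10, 0, 0])
        d = distance_to_equatorial_plane(p, fr, 0)
        assert d >= 0.0
        # moving along the axis changes the distance by exactly the shift
        moved = distance_to_equatorial_plane(p + np.array([shift, 0, 0]), fr, 0)
        assert moved == pytest.approx(abs((p[0] - 5.0) + shift), abs=1e-9)
        assert d == pytest.approx(abs(p[0] - 5.0), abs=1e-9)
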
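"""Kinematics: inverse/forward consistency, rotation structure, muscle paths."""

import numpy as np
import pytest

from cbreach.kinematics import (
    ArmPose,
    ReachabilityError,
    forward_hand_position,
    ik_angles,
    muscle_jacobian,
    muscle_lengths,
    muscle_path_length,
    shoulder_quaternion,
    shoulder_rotation_matrix,
    target_lengths,
)
from conftest import random_reachable_targets


def rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


class TestShoulderRotation:
    def test_identity_at_zero(self):
        assert np.allclose(shoulder_rotation_matrix(0, 0, 0), np.eye(3))

    def test_matches_elementary_zxz_product(self, rng):
        # independent oracle: explicit product of elementary intrinsic rotations
        for _ in range(50):
            a, b, g = rng.uniform(-np.pi, np.pi, 3)
            expected = rot_z(a) @ rot_x(b) @ rot_z(g)
            assert np.allclose(shoulder_rotation_matrix(a, b, g), expected, atol=1e-14)

    def test_proper_rotation(self, rng):
        for _ in range(50):
            r = shoulder_rotation_matrix(*rng.uniform(-np.pi, np.pi, 3))
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(r), 1.0, atol=1e-12)

    def test_quaternion_matches_matrix(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(25):
            a, b, g = rng.uniform(-np.pi, np.pi, 3)
            q = shoulder_quaternion(a, b, g)  # (w, x, y, z)
            r = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
            assert np.allclose(r, shoulder_rotation_matrix(a, b, g), atol=1e-12)


class TestInverseKinematics:
    def test_full_extension_gives_zero_elbow(self, geometry):
        t = np.array([0.0, 0.0, -geometry.reach])
        pose = ik_angles(t, geometry)
        assert pose.delta == pytest.approx(0.0, abs=1e-7)

    def test_right_angle_elbow(self, geometry):
        # |t|^2 = l_arm^2 + l_farm^2  ->  interior angle pi/2, delta = pi/2
        d = np.hypot(geometry.l_arm, geometry.l_farm)
        pose = ik_angles(np.array([0.0, 0.1, -np.sqrt(d * d - 0.01)]), geometry)
        assert pose.delta == pytest.approx(np.pi / 2, abs=1e-10)

    def test_gamma_always_zero_and_delta_range(self, geometry, rng):
        for t in random_reachable_targets(geometry, rng, 50, anterior=False):
            pose = ik_angles(t, geometry)
            assert pose.gamma == 0.0
            assert 0.0 <= pose.delta < np.pi

    def test_round_trip_1000_targets(self, geometry, rng):
        ts = random_reachable_targets(geometry, rng, 1000, anterior=False)
        errs = [
            np.linalg.norm(forward_hand_position(ik_angles(t, geometry), geometry) - t)
            for t in ts
        ]
        assert max(errs) < 1e-6

    def test_unreachable_raises(self, geometry):
        with pytest.raises(ReachabilityError):
            ik_angles(np.array([0.0, 0.9, 0.0]), geometry)
        with pytest.raises(ReachabilityError):
            ik_angles(np.array([0.0, 0.01, 0.0]), geometry)

    def test_singular_axis_alpha_zero(self, geometry):
        pose = ik_angles(np.array([0.0, 0.0, -0.5]), geometry)
        assert pose.alpha == 0.0
        hand = forward_hand_position(pose, geometry)
        assert np.allclose(hand, [0, 0, -0.5], atol=1e-9)

    def test_printed_arcsin_branch_agrees_anteriorly(self, geometry, rng):
        # for y > 0 the atan2 form reduces to asin(-x / hypot(x, y))
        for t in random_reachable_targets(geometry, rng, 100, anterior=True):
            pose = ik_angles(t, geometry)
            assert pose.alpha == pytest.approx(
                np.arcsin(-t[0] / np.hypot(t[0], t[1])), abs=1e-12
            )


class TestForwardKinematics:
    def test_table1_target1_round_trip(self, geometry, targets):
        # first standard test target, printed as (-10, 20, -30) cm
        t1 = targets[0]
        assert np.allclose(t1, [-0.10, 0.20, -0.30])
        hand = forward_hand_position(ik_angles(t1, geometry), geometry)
        assert np.allclose(hand, t1, atol=1e-9)

    def test_straight_arm_reach(self, geometry, rng):
        for _ in range(10):
            a, b = rng.uniform(-1, 1, 2)
            hand = forward_hand_position(ArmPose(a, b, 0.0, 0.0), geometry)
            assert np.linalg.norm(hand) == pytest.approx(geometry.reach, abs=1e-12)

    def test_matches_homogeneous_chain(self, geometry, rng):
        # oracle: elbow rotation applied first, then the shoulder rotation
        for _ in range(50):
            a, b, g, d = rng.uniform([-np.pi, -1, -np.pi, 0], [np.pi, 2.5, np.pi, 3])
            rs = rot_z(a) @ rot_x(b) @ rot_z(g)
            expected = rs @ (
                np.array([0, 0, -geometry.l_arm])
                + rot_x(d) @ np.array([0, 0, -geometry.l_farm])
            )
            hand = forward_hand_position(ArmPose(a, b, g, d), geometry)
            assert np.allclose(hand, expected, atol=1e-12)


class TestMusclePaths:
    def test_no_bending_line_is_euclidean(self, rng):
        p1, p2 = rng.normal(size=3), rng.normal(size=3)
        length, via = muscle_path_length(p1, p2)
        assert length == pytest.approx(np.linalg.norm(p1 - p2))
        assert via is None

    def test_degenerate_bending_line_rejected(self):
        with pytest.raises(ValueError):
            muscle_path_length(
                np.zeros(3) + [1, 0, 0],
                np.array([0.0, 1, 0]),
                bending_line=np.array([[0.0, 0, 0], [0.0, 0, 0]]),
                wrap_normal=np.array([0.0, 0, 1]),
            )

    def test_wrapped_length_matches_grid_search(self, rng):
        # oracle: dense 1-D search of min |p1-v| + |v-p2| over the segment
        hits = 0
        for _ in range(200):
            p1 = rng.normal(size=3)
            p2 = rng.normal(size=3)
            a = rng.normal(size=3)
            b = a + rng.normal(size=3)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            length, via = muscle_path_length(p1, p2, np.array([a, b]), n)
            if via is None:
                continue
            hits += 1
            s = np.linspace(0, 1, 200001)[:, None]
            pts = a + s * (b - a)
            sums = np.linalg.norm(pts - p1, axis=1) + np.linalg.norm(pts - p2, axis=1)
            assert length == pytest.approx(sums.min(), abs=1e-8)
            assert length >= np.linalg.norm(p1 - p2) - 1e-12
        assert hits > 20  # the random ensemble must exercise wrapping

    def test_collinear_via_point_adds_nothing(self):
        p1 = np.array([-1.0, 0.0, 0.0])
        p2 = np.array([1.0, 0.0, 0.0])
        bl = np.array([[0.0, -1.0, 0.0], [0.0, 1.0, 0.0]])  # crosses at origin
        length, via = muscle_path_length(p1, p2, bl, np.array([0.0, 0.0, 1.0]))
        if via is not None:
            assert length == pytest.approx(2.0, abs=1e-12)


class TestTargetLengths:
    def test_self_consistency_at_current_pose(self, geometry, targets):
        pose = ik_angles(targets[6], geometry)
        lam = target_lengths(targets[6], geometry)
        assert np.allclose(lam, muscle_lengths(pose.as_array(), geometry), atol=1e-9)

    def test_all_standard_targets_reachable(self, geometry, targets):
        for t in targets:
            lam = target_lengths(t, geometry)
            assert lam.shape == (11,)
            assert np.all(np.isfinite(lam)) and np.all(lam > 0)

    def test_matches_bruteforce_geometry(self, geometry, rng):
        # oracle: per-muscle world coordinates + muscle_path_length calls
        from cbreach.kinematics import _elbow_rotation

        for t in random_reachable_targets(geometry, rng, 20):
            pose = ik_angles(t, geometry)
            rs = shoulder_rotation_matrix(pose.alpha, pose.beta, pose.gamma)
            re = _elbow_rotation(pose.delta)

            def world(p, frame):
                p = np.asarray(p)
                if frame == "world":
                    return p
                if frame == "upper":
                    return rs @ p
                return rs @ (np.array([0, 0, -geometry.l_arm]) + re @ p)

            expected = []
            for m in geometry.muscles:
                p1 = world(m.origin, m.origin_frame)
                p2 = world(m.insertion, m.insertion_frame)
                bl = None
                wn = None
                if m.bending_line is not None:
                    bl = np.array(
                        [world(m.bending_line[0], m.bending_frame),
                         world(m.bending_line[1], m.bending_frame)]
                    )
                    if m.bending_frame == "world":
                        wn = m.wrap_normal
                    elif m.bending_frame == "upper":
                        wn = rs @ m.wrap_normal
                    else:
                        wn = rs @ re @ m.wrap_normal
                expected.append(muscle_path_length(p1, p2, bl, wn)[0])
            assert np.allclose(target_lengths(t, geometry), expected, atol=1e-10)

    def test_lengths_continuous_in_target(self, geometry, rng):
        for t in random_reachable_targets(geometry, rng, 10):
            lam = target_lengths(t, geometry)
            for _ in range(5):
                eps = rng.normal(size=3)
                eps *= 1e-5 / np.linalg.norm(eps)
                lam2 = target_lengths(t + eps, geometry)
                assert np.max(np.abs(lam2 - lam)) < 1e-3  # O(eps) with slack


class TestJacobian:
    def test_velocity_chain_rule(self, geometry, rng):
        # v = J qd agrees with finite-difference time derivative of lengths
        q = rng.uniform([-1, 0.1, -1, 0.2], [1, 2, 1, 2.5])
        qd = rng.normal(size=4)
        l0, jac = muscle_jacobian(q, geometry)
        dt = 1e-7
        l1 = muscle_lengths(q + qd * dt, geometry)
        assert np.allclose(jac @ qd, (l1 - l0) / dt, atol=1e-4)


class TestPathProperties:
    def test_wrapped_path_never_shorter_than_straight(self):
        from hypothesis import given, settings, strategies as st
        import hypothesis.extra.numpy as hnp

        pts = hnp.arrays(np.float64, 3,
                         elements=st.floats(-1, 1, allow_nan=False))

        @settings(max_examples=100, deadline=None, derandomize=True)
        @given(p1=pts, p2=pts, a=pts, b=pts, n=pts)
        def check(p1, p2, a, b, n):
            if np.allclose(p1, p2) or np.allclose(a, b) or np.linalg.norm(n) < 1e-6:
                return
            length, via = muscle_path_length(p1, p2, np.array([a, b]), n)
            straight = np.linalg.norm(p1 - p2)
            assert length >= straight - 1e-12
            if via is None:
                assert length == pytest.approx(straight)

        check()
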
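"""Quaternion algebra, swing-twist, Euler and SLERP contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation, Slerp

from squatval import kinematics as K


def _random_unit_quats(rng, n):
    return K.quat_normalize(rng.normal(size=(n, 4)))


def _scipy(q):
    return Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=-1))


unit_quats = st.builds(
    lambda seed: K.quat_normalize(np.random.default_rng(seed).normal(size=4)),
    st.integers(0, 2**31 - 1),
)


class TestQuatAlgebra:
    def test_identity_is_neutral(self, rng):
        q = _random_unit_quats(rng, 10)
        assert np.allclose(K.quat_multiply(q, K.IDENTITY), q)
        assert np.allclose(K.quat_multiply(np.broadcast_to(K.IDENTITY, (10, 4)), q), q)

    def test_same_axis_angles_add(self):
        q90 = K.quat_from_axis_angle([0, 0, 1], np.pi / 2)
        q180 = K.quat_multiply(q90, q90)
        assert np.allclose(q180, K.quat_from_axis_angle([0, 0, 1], np.pi), atol=1e-12)

    def test_multiplication_matches_rotation_matrix_composition(self, rng):
        q1, q2 = _random_unit_quats(rng, 50), _random_unit_quats(rng, 50)
        lhs = K.quat_to_matrix(K.quat_multiply(q1, q2))
        rhs = K.quat_to_matrix(q1) @ K.quat_to_matrix(q2)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_conjugate_inverts(self, rng):
        q = _random_unit_quats(rng, 100)
        prod = K.quat_canonical(K.quat_multiply(q, K.quat_conjugate(q)))
        assert np.allclose(prod, K.IDENTITY, atol=1e-12)

    def test_axis_angle_round_trip(self, rng):
        axis = np.array([1.0, 2.0, -0.5])
        axis /= np.linalg.norm(axis)
        for angle in rng.uniform(-np.pi + 0.01, np.pi - 0.01, 20):
            q = K.quat_from_axis_angle(axis, angle)
            assert np.isclose(K.quat_angle_deg(q), np.degrees(abs(angle)), atol=1e-9)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError, match="zero quaternion"):
            K.quat_normalize(np.zeros(4))

    def test_matrix_quaternion_round_trip_matches_scipy(self, rng):
        q = _random_unit_quats(rng, 200)
        m = _scipy(q).as_matrix()
        back = K.quat_from_matrix(m)
        assert np.allclose(K.quat_to_matrix(back), m, atol=1e-12)


class TestRelativeOrientationAndCalibration:
    def test_equal_orientations_give_identity(self, rng):
        q = _random_unit_quats(rng, 5)
        rel = K.quat_canonical(K.relative_orientation(q, q))
        assert np.allclose(rel, K.IDENTITY, atol=1e-12)

    def test_identity_primary_passes_secondary_through(self):
        q = K.quat_from_axis_angle([0, 0, 1], np.radians(30))
        assert np.allclose(K.relative_orientation(K.IDENTITY, q), q)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(unit_quats, unit_quats, unit_quats)
    def test_left_invariance_under_world_rotation(self, qw, qp, qs):
        rel = K.relative_orientation(qp, qs)
        rel2 = K.relative_orientation(K.quat_multiply(qw, qp), K.quat_multiply(qw, qs))
        assert np.allclose(K.quat_canonical(rel), K.quat_canonical(rel2), atol=1e-9)

    def test_calibrate_zeroes_the_reference_pose(self, rng):
        q = _random_unit_quats(rng, 5)
        assert np.allclose(K.quat_canonical(K.calibrate(q, q)), K.IDENTITY, atol=1e-12)
        q0 = _random_unit_quats(rng, 1)[0]
        assert np.allclose(K.calibrate(q0, K.IDENTITY), q0)


class TestSwingTwist:
    def test_identity_decomposes_trivially(self):
        sw, tw, flag = K.swing_twist_decompose(K.IDENTITY, [0, 0, 1])
        assert np.allclose(sw, K.IDENTITY) and np.allclose(tw, K.IDENTITY)
        assert not flag

    def test_pure_twist_has_identity_swing(self):
        q = K.quat_from_axis_angle([0, 0, 1], np.pi / 2)
        sw, tw, _ = K.swing_twist_decompose(q, [0, 0, 1])
        assert np.allclose(K.quat_canonical(sw), K.IDENTITY, atol=1e-12)
        assert np.allclose(tw, q)

    def test_worked_half_turn_example(self):
        # (w,x,y,z) = (.5,.5,.5,.5) about z: twist 90 deg about z, swing 90 about y
        q = np.array([0.5, 0.5, 0.5, 0.5])
        sw, tw, _ = K.swing_twist_decompose(q, [0, 0, 1])
        s2 = np.sqrt(0.5)
        assert np.allclose(tw, [s2, 0, 0, s2], atol=1e-12)
        assert np.allclose(sw, [s2, 0, s2, 0], atol=1e-12)
        assert np.allclose(K.quat_multiply(sw, tw), q, atol=1e-12)

    def test_recomposition_and_axis_orthogonality_bulk(self, rng):
        """10^4 random rotations: swing x twist == +/-q to 1e-9; axes as specified."""
        q = _random_unit_quats(rng, 10_000)
        axes = rng.normal(size=(10_000, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        # full set against the longitudinal-style fixed axis, then a looped
        # subset with arbitrary per-case axes
        sw, tw, flag = K.swing_twist_decompose(q, np.array([0.0, 0.0, 1.0]))
        rec = K.quat_canonical(K.quat_multiply(sw, tw))
        assert np.allclose(rec, K.quat_canonical(q), atol=1e-9)
        assert np.allclose(tw[:, 1:3], 0.0, atol=1e-12)  # twist axis parallel to z
        assert np.allclose(sw[:, 3], 0.0, atol=1e-9)  # swing axis orthogonal to z
        idx = rng.choice(10_000, 200, replace=False)
        for i in idx:
            sw_i, tw_i, _ = K.swing_twist_decompose(q[i], axes[i])
            rec = K.quat_canonical(K.quat_multiply(sw_i, tw_i))
            assert np.allclose(rec, K.quat_canonical(q[i]), atol=1e-9)
            assert np.allclose(np.cross(tw_i[1:], axes[i]), 0.0, atol=1e-9)
            assert abs(np.dot(sw_i[1:], axes[i])) < 1e-9

    def test_singular_perpendicular_half_turn_flagged(self):
        q = K.quat_from_axis_angle([1, 0, 0], np.pi)  # 180 deg perpendicular to z
        sw, tw, flag = K.swing_twist_decompose(q, [0, 0, 1])
        assert flag
        assert np.allclose(tw, K.IDENTITY)


class TestTiltSwayTwist:
    def test_identity_gives_zero(self):
        t = K.tilt_sway_twist(K.IDENTITY)
        assert t.tilt == t.sway == t.twist == t.swing == 0.0

    def test_pure_sagittal_rotation(self):
        q = K.compose_sagittal_frontal_transverse(30.0)
        t = K.tilt_sway_twist(q)
        assert np.allclose([t.tilt, t.sway, t.twist, t.swing], [30, 0, 0, 30], atol=1e-9)

    def test_matches_numeric_projection_oracle(self, rng):
        """Tilt/sway agree with brute-force projections of the rotated axis."""
        q = _random_unit_quats(rng, 300)
        t = K.tilt_sway_twist(q)
        v = K.quat_to_matrix(q) @ K.LONGITUDINAL
        tilt_o = np.degrees(np.arctan2(v @ K.ANTERIOR, v @ K.LONGITUDINAL))
        sway_o = np.degrees(
            np.arctan2(v @ K.LATERAL, np.hypot(v @ K.ANTERIOR, v @ K.LONGITUDINAL))
        )
        swing_o = np.degrees(np.arccos(np.clip(v @ K.LONGITUDINAL, -1, 1)))
        assert np.allclose(t.tilt, tilt_o, atol=1e-6)
        assert np.allclose(t.sway, sway_o, atol=1e-6)
        assert np.allclose(t.swing, swing_o, atol=1e-6)
        assert np.all(t.swing >= 0)

    def test_swing_degenerates_to_planar_components(self):
        t = K.tilt_sway_twist(K.compose_sagittal_frontal_transverse(-40.0))
        assert np.isclose(t.swing, abs(t.tilt), atol=1e-9) and np.isclose(t.sway, 0, atol=1e-9)
        t = K.tilt_sway_twist(K.compose_sagittal_frontal_transverse(0.0, 25.0))
        assert np.isclose(t.swing, abs(t.sway), atol=1e-9) and np.isclose(t.tilt, 0, atol=1e-9)

    def test_composed_two_plane_rotation_recovered(self):
        q = K.compose_sagittal_frontal_transverse(20.0, 10.0)
        t = K.tilt_sway_twist(q)
        assert np.isclose(t.tilt, 20.0, atol=1e-6)
        assert np.isclose(t.sway, 10.0, atol=1e-6)

    def test_sign_convention_flips_frontal_for_left_side(self):
        q = K.compose_sagittal_frontal_transverse(20.0, 10.0)
        right = K.tilt_sway_twist(q, signs=K.sign_convention("spine", "right"))
        left = K.tilt_sway_twist(q, signs=K.sign_convention("spine", "left"))
        assert np.isclose(right.sway, -left.sway)
        assert np.isclose(right.tilt, left.tilt)

    def test_continuous_through_gimbal_region(self):
        """Tilt/sway/twist stay finite and continuous where Euler warns.

        The path dips deep into the gimbal-warning band (|frontal| > 89) and
        back without crossing the lateral pole, where the sagittal azimuth is
        intrinsically undefined for any parametrization.
        """
        frontal = np.concatenate([np.linspace(85.0, 89.9, 100), np.linspace(89.9, 85.0, 100)])
        q = np.stack([K.compose_sagittal_frontal_transverse(25.0, f, 5.0) for f in frontal])
        e = K.euler_sagittal_frontal_transverse(q)
        assert e.gimbal_warning.any()
        t = K.tilt_sway_twist(q)
        for arr in (t.tilt, t.sway, t.twist, t.swing):
            assert np.all(np.isfinite(arr))
            assert np.abs(np.diff(arr)).max() < 1.0  # no jumps along the fine path

    def test_finite_across_the_lateral_pole(self):
        """Crossing frontal = 90 exactly keeps every output finite."""
        q = np.stack([K.compose_sagittal_frontal_transverse(25.0, f, 5.0)
                      for f in np.linspace(88.0, 92.0, 81)])
        t = K.tilt_sway_twist(q)
        for arr in (t.tilt, t.sway, t.twist, t.swing):
            assert np.all(np.isfinite(arr))


class TestEulerSequence:
    def test_identity_gives_zero(self):
        e = K.euler_sagittal_frontal_transverse(K.IDENTITY)
        assert e.sagittal == e.frontal == e.transverse == 0.0
        assert not e.gimbal_warning

    def test_round_trip_of_known_triple(self):
        q = K.compose_sagittal_frontal_transverse(40.0, 10.0, 5.0)
        e = K.euler_sagittal_frontal_transverse(q)
        assert np.allclose([e.sagittal, e.frontal, e.transverse], [40, 10, 5], atol=1e-9)

    def test_random_triples_round_trip(self, rng):
        sag = rng.uniform(-170, 170, 200)
        fro = rng.uniform(-85, 85, 200)
        tra = rng.uniform(-170, 170, 200)
        q = np.stack([K.compose_sagittal_frontal_transverse(s, f, t)
                      for s, f, t in zip(sag, fro, tra)])
        e = K.euler_sagittal_frontal_transverse(q)
        assert np.allclose(e.sagittal, sag, atol=1e-8)
        assert np.allclose(e.frontal, fro, atol=1e-8)
        assert np.allclose(e.transverse, tra, atol=1e-8)

    def test_decomposition_matches_scipy_zxy(self, rng):
        """Independent oracle: intrinsic ZXY decomposition in the segment basis."""
        q = _random_unit_quats(rng, 100)
        e = K.euler_sagittal_frontal_transverse(q)
        a, b, c = np.degrees(_scipy(q).as_euler("ZXY")).T
        ok = np.abs(b) < 85
        assert np.allclose(e.sagittal[ok], -a[ok], atol=1e-7)
        assert np.allclose(e.frontal[ok], b[ok], atol=1e-7)
        assert np.allclose(e.transverse[ok], -c[ok], atol=1e-7)

    def test_gimbal_warning_near_90_frontal(self):
        e = K.euler_sagittal_frontal_transverse(
            K.compose_sagittal_frontal_transverse(10.0, 89.5, 0.0)
        )
        assert e.gimbal_warning
        assert not K.euler_sagittal_frontal_transverse(
            K.compose_sagittal_frontal_transverse(10.0, 88.0, 0.0)
        ).gimbal_warning

    def test_planar_equivalence_with_tilt_sway(self, rng):
        for sag in rng.uniform(-150, 150, 20):
            q = K.compose_sagittal_frontal_transverse(sag)
            assert np.isclose(
                K.tilt_sway_twist(q).tilt,
                K.euler_sagittal_frontal_transverse(q).sagittal,
                atol=1e-9,
            )
        for fro in rng.uniform(-85, 85, 20):
            q = K.compose_sagittal_frontal_transverse(0.0, fro)
            assert np.isclose(
                K.tilt_sway_twist(q).sway,
                K.euler_sagittal_frontal_transverse(q).frontal,
                atol=1e-9,
            )


class TestSlerp:
    def test_endpoints(self, rng):
        q0, q1 = _random_unit_quats(rng, 2)
        assert np.allclose(K.slerp(q0, q1, 0.0), q0, atol=1e-12)
        d = abs(np.dot(K.slerp(q0, q1, 1.0), q1))
        assert np.isclose(d, 1.0, atol=1e-12)  # up to sign

    def test_half_arc_midpoint(self):
        q1 = K.quat_from_axis_angle([0, 0, 1], np.pi / 2)
        mid = K.slerp(K.IDENTITY, q1, 0.5)
        assert np.allclose(mid, K.quat_from_axis_angle([0, 0, 1], np.pi / 4), atol=1e-12)

    def test_angle_grows_linearly_in_t(self, rng):
        q0, q1 = _random_unit_quats(rng, 2)
        total = K.quat_angle_deg(K.quat_multiply(K.quat_conjugate(q0), q1))
        total = min(total, 360 - total)
        ts = np.linspace(0, 1, 11)
        angles = [
            K.quat_angle_deg(K.quat_multiply(K.quat_conjugate(q0), K.slerp(q0, q1, t)))
            for t in ts
        ]
        assert np.allclose(angles, ts * total, atol=1e-8)

    def test_matches_scipy_slerp(self, rng):
        q0, q1 = _random_unit_quats(rng, 2)
        ts = np.linspace(0, 1, 7)
        ours = np.stack([K.slerp(q0, q1, t) for t in ts])
        ref = Slerp([0, 1], _scipy(np.stack([q0, q1])))(ts).as_quat()
        ref = np.roll(ref, 1, axis=-1)
        sign = np.sign(np.sum(ours * ref, axis=1, keepdims=True))
        assert np.allclose(ours, ref * sign, atol=1e-9)

    def test_t_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="t must lie"):
            K.slerp(K.IDENTITY, K.IDENTITY, 1.5)

    def test_antipodal_falls_back_to_nlerp(self):
        q0 = K.IDENTITY
        q1 = K.quat_from_axis_angle([1, 0, 0], np.pi)  # dot(q0, q1) == 0
        out = K.slerp(q0, q1, 0.3)
        assert np.isfinite(out).all()
        assert np.isclose(np.linalg.norm(out), 1.0)
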
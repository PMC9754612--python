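"""Unit and property tests of the quaternion algebra.

The independent oracle for axis-angle and matrix conversions is
scipy.spatial.transform.Rotation (scalar-last convention, reordered here);
the implementation itself never touches scipy.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from quatgeo import quatcore as qc

SQ2 = np.sqrt(2) / 2


def scipy_quat(q):
    """Our scalar-first quaternion as a scipy Rotation."""
    return Rotation.from_quat([q[1], q[2], q[3], q[0]])


class TestConstruction:
    @pytest.mark.parametrize(
        "axis, angle, expected",
        [
            ([1, 0, 0], np.pi / 2, [SQ2, SQ2, 0, 0]),
            ([0, 1, 0], 0.0, [1, 0, 0, 0]),
            ([0, 0, 1], np.pi, [0, 0, 0, 1]),
        ],
    )
    def test_from_axis_angle(self, axis, angle, expected):
        np.testing.assert_allclose(qc.from_axis_angle(axis, angle), expected, atol=1e-12)

    def test_zero_axis_with_angle_rejected(self):
        with pytest.raises(qc.InvalidAxisError):
            qc.from_axis_angle([0, 0, 0], 0.3)

    def test_axis_normalized_internally(self):
        q1 = qc.from_axis_angle([0, 0, 10.0], 0.7)
        q2 = qc.from_axis_angle([0, 0, 1.0], 0.7)
        np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_matches_rotation_oracle(self, rng):
        for _ in range(50):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-np.pi + 1e-3, np.pi)
            ours = qc.to_rotation_matrix(qc.from_axis_angle(axis, angle))
            ref = Rotation.from_rotvec(axis * angle).as_matrix()
            np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestProduct:
    def test_identity_element(self, rng):
        q = qc.random_quaternion(rng)
        np.testing.assert_allclose(qc.multiply(q, qc.IDENTITY), q, atol=1e-12)

    def test_ij_equals_k(self):
        np.testing.assert_allclose(qc.multiply([0, 1, 0, 0], [0, 0, 1, 0]), [0, 0, 0, 1], atol=1e-15)

    def test_ji_equals_minus_k(self):
        np.testing.assert_allclose(qc.multiply([0, 0, 1, 0], [0, 1, 0, 0]), [0, 0, 0, -1], atol=1e-15)

    def test_unit_norm_preserved(self, rng):
        a = qc.random_quaternion(rng, 200)
        b = qc.random_quaternion(rng, 200)
        norms = np.linalg.norm(qc.multiply(a, b), axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_conjugate_is_inverse(self, rng):
        q = qc.random_quaternion(rng, 100)
        prod = qc.multiply(q, qc.conjugate(q))
        assert np.max(qc.quat_distance(prod, qc.IDENTITY)) < 1e-9

    def test_conjugate_flips_vector_part(self):
        np.testing.assert_allclose(qc.conjugate([SQ2, SQ2, 0, 0]), [SQ2, -SQ2, 0, 0])


class TestRotateVector:
    def test_identity(self, rng):
        p = rng.standard_normal(3)
        np.testing.assert_allclose(qc.rotate_vector(qc.IDENTITY, p), p)

    def test_quarter_turn_about_z(self):
        q = qc.from_axis_angle([0, 0, 1], np.pi / 2)
        np.testing.assert_allclose(qc.rotate_vector(q, [1, 0, 0]), [0, 1, 0], atol=1e-12)

    def test_double_cover_and_norm(self, rng):
        q = qc.random_quaternion(rng, 100)
        p = rng.standard_normal((100, 3))
        r1 = qc.rotate_vector(q, p)
        r2 = qc.rotate_vector(-q, p)
        np.testing.assert_allclose(r1, r2, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(r1, axis=-1), np.linalg.norm(p, axis=-1), atol=1e-9)

    def test_matches_oracle(self, rng):
        q = qc.random_quaternion(rng)
        p = rng.standard_normal(3)
        np.testing.assert_allclose(qc.rotate_vector(q, p), scipy_quat(q).apply(p), atol=1e-12)


class TestDistance:
    def test_self_distance_zero(self, rng):
        q = qc.random_quaternion(rng, 20)
        assert np.max(qc.quat_distance(q, q)) == 0.0

    def test_sign_invariance(self, rng):
        q = qc.random_quaternion(rng, 20)
        assert np.max(qc.quat_distance(q, -q)) == 0.0

    def test_recovers_construction_angle(self, rng):
        for _ in range(50):
            axis = rng.standard_normal(3)
            theta = rng.uniform(-np.pi + 1e-6, np.pi)
            d = qc.quat_distance(qc.IDENTITY, qc.from_axis_angle(axis, theta))
            assert abs(d - abs(theta)) < 1e-9

    def test_symmetry_and_triangle_inequality(self, rng):
        a, b, c = (qc.random_quaternion(rng, 300) for _ in range(3))
        dab = qc.quat_distance(a, b)
        np.testing.assert_allclose(dab, qc.quat_distance(b, a), atol=1e-12)
        assert np.all(qc.quat_distance(a, c) <= dab + qc.quat_distance(b, c) + 1e-9)

    def test_bounded_by_pi(self, rng):
        d = qc.quat_distance(qc.random_quaternion(rng, 500), qc.random_quaternion(rng, 500))
        assert np.all((d >= 0) & (d <= np.pi))


class TestGeodesic:
    def test_endpoints(self, rng):
        q1, qN = qc.random_quaternion(rng), qc.random_quaternion(rng)
        assert qc.quat_distance(qc.geodesic(q1, qN, 0.0), q1) < 1e-9
        assert qc.quat_distance(qc.geodesic(q1, qN, 1.0), qN) < 1e-9

    def test_midpoint_halves_the_angle(self):
        qN = qc.from_axis_angle([0, 0, 1], np.deg2rad(50))
        mid = qc.geodesic(qc.IDENTITY, qN, 0.5)
        axis, angle = qc.to_axis_angle(mid)
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-12)
        assert abs(angle - np.deg2rad(25)) < 1e-12

    def test_rotation_invariance(self, rng):
        """Pre-rotating both endpoints pre-rotates the whole arc (Eq 8 identity)."""
        h = np.linspace(0, 1, 11)
        for _ in range(100):
            q1, qN = qc.random_quaternion(rng), qc.random_quaternion(rng)
            direct = qc.geodesic(q1, qN, h)
            rel = qc.geodesic(qc.IDENTITY, qc.multiply(qc.conjugate(q1), qN), h)
            composed = qc.multiply(q1, rel)
            assert np.max(qc.quat_distance(direct, composed)) < 1e-9

    def test_antipodal_rejected(self):
        q = qc.from_axis_angle([1, 0, 0], 0.4)
        anti = qc.multiply(qc.from_axis_angle([1, 0, 0], np.pi), q)
        with pytest.raises(qc.UndefinedGeodesicError):
            qc.geodesic(q, anti, 0.5)


class TestTransition:
    def test_identity_transition(self, rng):
        q = qc.random_quaternion(rng)
        for frame in ("extrinsic", "intrinsic"):
            tr = qc.transition(q, q, frame)
            assert qc.quat_distance(tr.value, qc.IDENTITY) < 1e-9

    def test_reconstructs_successor(self, rng):
        qi = qc.random_quaternion(rng, 50)
        qn = qc.random_quaternion(rng, 50)
        ext = qc.transition(qi, qn, "extrinsic").value
        intr = qc.transition(qi, qn, "intrinsic").value
        assert np.max(qc.quat_distance(qc.multiply(ext, qi), qn)) < 1e-9
        assert np.max(qc.quat_distance(qc.multiply(qi, intr), qn)) < 1e-9
        # both frames share the rotation angle
        np.testing.assert_allclose(
            qc.to_axis_angle(ext).angle, qc.to_axis_angle(intr).angle, atol=1e-9
        )

    def test_uniform_geodesic_steps_are_constant(self):
        qN = qc.from_axis_angle([0, 1, 0], np.deg2rad(60))
        h = np.linspace(0, 1, 21)
        q = qc.geodesic(qc.IDENTITY, qN, h)
        tr = qc.transition(q[:-1], q[1:], "extrinsic")
        axis, angle = qc.to_axis_angle(tr.value)
        np.testing.assert_allclose(axis, np.tile([0, 1, 0], (20, 1)), atol=1e-9)
        np.testing.assert_allclose(angle, np.deg2rad(60) / 20, atol=1e-12)


class TestMatrixConversion:
    def test_identity(self):
        np.testing.assert_allclose(qc.from_rotation_matrix(np.eye(3)), qc.IDENTITY)

    def test_quarter_turn_about_x(self):
        R = Rotation.from_rotvec([np.pi / 2, 0, 0]).as_matrix()
        np.testing.assert_allclose(qc.from_rotation_matrix(R), [SQ2, SQ2, 0, 0], atol=1e-12)

    def test_round_trip_random(self, rng):
        q = qc.random_quaternion(rng, 200)
        R = qc.to_rotation_matrix(q)
        R2 = qc.to_rotation_matrix(qc.from_rotation_matrix(R))
        assert np.max(np.abs(R - R2)) < 1e-8

    def test_near_half_turn_stability(self, rng):
        for _ in range(50):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            q = qc.from_axis_angle(axis, np.pi - 1e-7)
            R = qc.to_rotation_matrix(q)
            assert qc.quat_distance(qc.from_rotation_matrix(R), q) < 1e-6

    def test_agrees_with_oracle(self, rng):
        mats = Rotation.random(100, rng=np.random.default_rng(1)).as_matrix()
        ours = qc.from_rotation_matrix(mats)
        ref = Rotation.from_matrix(mats).as_quat()  # xyzw
        ref = np.column_stack([ref[:, 3], ref[:, 0], ref[:, 1], ref[:, 2]])
        ref *= np.where(ref[:, 0] < 0, -1.0, 1.0)[:, None]
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_rejects_improper_matrices(self):
        with pytest.raises(qc.InvalidRotationError):
            qc.from_rotation_matrix(np.eye(3) * 1.01)
        reflect = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(qc.InvalidRotationError):
            qc.from_rotation_matrix(reflect)


class TestContinuity:
    def test_single_flip_removed(self, rng):
        q = qc.geodesic(qc.IDENTITY, qc.random_quaternion(rng), np.linspace(0, 1, 10))
        flipped = q.copy()
        flipped[4:] *= -1  # one hemisphere hop
        np.testing.assert_allclose(qc.enforce_continuity(flipped), q, atol=1e-12)

    def test_constant_sequence_unchanged(self):
        q = np.tile(qc.from_axis_angle([0, 1, 0], 0.3), (5, 1))
        np.testing.assert_allclose(qc.enforce_continuity(q), q)

    def test_random_sign_pattern_restored(self, rng):
        q = qc.geodesic(qc.IDENTITY, qc.random_quaternion(rng), np.linspace(0, 1, 30))
        signs = rng.choice([-1.0, 1.0], size=30)
        signs[0] = 1.0
        restored = qc.enforce_continuity(q * signs[:, None])
        np.testing.assert_allclose(restored, q, atol=1e-12)

    def test_distances_unchanged(self, rng):
        q = qc.random_quaternion(rng, 20)
        fixed = qc.enforce_continuity(q)
        np.testing.assert_allclose(
            qc.quat_distance(q[:-1], q[1:]), qc.quat_distance(fixed[:-1], fixed[1:]), atol=1e-12
        )


finite4 = st.lists(st.floats(-10, 10), min_size=4, max_size=4).filter(
    lambda v: np.linalg.norm(v) > 1e-3
)


class TestAlgebraProperties:
    @settings(derandomize=True, max_examples=200)
    @given(a=finite4, b=finite4)
    def test_product_stays_on_sphere_and_distance_is_symmetric(self, a, b):
        qa, qb = qc.normalize(a), qc.normalize(b)
        prod = qc.multiply(qa, qb)
        assert abs(np.linalg.norm(prod) - 1.0) < 1e-9
        d = qc.quat_distance(qa, qb)
        assert 0.0 <= d <= np.pi
        assert abs(d - qc.quat_distance(qb, qa)) < 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(a=finite4, h=st.floats(0, 1))
    def test_power_interpolates_the_rotation_angle(self, a, h):
        qa = qc.normalize(a)
        full = qc.quat_distance(qc.IDENTITY, qa)
        part = qc.quat_distance(qc.IDENTITY, qc.power(qa, h))
        assert abs(part - h * full) < 1e-8


class TestPower:
    def test_small_angle_series_branch(self):
        q = qc.from_axis_angle([0, 0, 1], 1e-10)
        out = qc.power(q, 0.5)
        assert abs(np.linalg.norm(out) - 1.0) < 1e-12
        assert qc.quat_distance(out, qc.from_axis_angle([0, 0, 1], 0.5e-10)) < 1e-12

    def test_double_cover_invariance(self, rng):
        """Distance, geodesics and transitions ignore the sign of any input."""
        q1, q2 = qc.random_quaternion(rng), qc.random_quaternion(rng)
        assert abs(qc.quat_distance(q1, q2) - qc.quat_distance(-q1, q2)) < 1e-12
        h = np.linspace(0, 1, 7)
        assert np.max(qc.quat_distance(qc.geodesic(q1, q2, h), qc.geodesic(-q1, -q2, h))) < 1e-9
        t1 = qc.transition(q1, q2, "extrinsic").value
        t2 = qc.transition(-q1, q2, "extrinsic").value
        assert qc.quat_distance(t1, t2) < 1e-9
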
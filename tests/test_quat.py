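"""Quaternion and vector primitives against rotation-matrix oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from armfusion.quat import (
    IDENTITY,
    angle_between,
    cross_matrix,
    heading_angle,
    heading_quat,
    normalize_vec,
    quat_canonical,
    quat_conj,
    quat_log,
    quat_multiply,
    rotate,
    wrap_angle,
)
from conftest import random_unit_quat


def scipy_quat(q):
    """Scalar-first -> scipy's scalar-last Rotation (independent oracle)."""
    return Rotation.from_quat([q[1], q[2], q[3], q[0]])


class TestMultiply:
    def test_identity_and_inverse(self, rng):
        q = random_unit_quat(rng)
        assert np.allclose(quat_multiply(IDENTITY, q), q)
        assert np.allclose(quat_multiply(q, quat_conj(q)), IDENTITY, atol=1e-12)

    def test_matches_rotation_composition(self):
        qa = heading_quat(np.deg2rad(30.0))
        qb = heading_quat(np.deg2rad(60.0))
        expected = heading_quat(np.deg2rad(90.0))
        assert np.allclose(quat_canonical(quat_multiply(qa, qb)), expected, atol=1e-12)

    def test_matches_matrix_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            a, b = random_unit_quat(rng), random_unit_quat(rng)
            ours = scipy_quat(quat_multiply(a, b)).as_matrix()
            oracle = scipy_quat(a).as_matrix() @ scipy_quat(b).as_matrix()
            assert np.allclose(ours, oracle, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_associative(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = (random_unit_quat(r) for _ in range(3))
        lhs = quat_multiply(quat_multiply(a, b), c)
        rhs = quat_multiply(a, quat_multiply(b, c))
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestRotate:
    def test_identity_leaves_vector(self):
        assert np.allclose(rotate(IDENTITY, [1.0, 2.0, 3.0]), [1, 2, 3])

    def test_quarter_turn_about_z(self):
        assert np.allclose(
            rotate(heading_quat(np.pi / 2), [1.0, 0.0, 0.0]), [0, 1, 0], atol=1e-12
        )

    def test_matches_matrix_oracle(self, rng):
        for _ in range(100):
            q = random_unit_quat(rng)
            v = rng.standard_normal(3)
            assert np.allclose(rotate(q, v), scipy_quat(q).apply(v), atol=1e-9)

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError):
            rotate(np.array([2.0, 0.0, 0.0, 0.0]), [1.0, 0.0, 0.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_preserves_norm(self, seed):
        r = np.random.default_rng(seed)
        q = random_unit_quat(r)
        v = r.standard_normal(3) * 10
        assert np.isclose(np.linalg.norm(rotate(q, v)), np.linalg.norm(v), atol=1e-9)


class TestHeadingQuat:
    def test_zero_is_identity(self):
        assert np.allclose(heading_quat(0.0), IDENTITY)

    def test_half_turn(self):
        assert np.allclose(heading_quat(np.pi), [0, 0, 0, 1], atol=1e-12)

    def test_planar_rotation_of_x_axis(self):
        # Rz(40°) x̂ = [cos 40°, sin 40°, 0]
        d = np.deg2rad(40.0)
        assert np.allclose(
            rotate(heading_quat(d), [1.0, 0.0, 0.0]),
            [np.cos(d), np.sin(d), 0.0],
            atol=1e-12,
        )

    def test_additive_up_to_sign_on_grid(self):
        grid = np.deg2rad(np.arange(0.0, 360.0, 5.0))
        for a in grid[::7]:
            for b in grid[::7]:
                lhs = quat_canonical(quat_multiply(heading_quat(a), heading_quat(b)))
                rhs = quat_canonical(heading_quat(a + b))
                assert np.allclose(lhs, rhs, atol=1e-9)

    def test_heading_angle_inverts(self):
        for d in np.deg2rad([-170.0, -40.0, 0.0, 25.0, 179.0]):
            assert np.isclose(heading_angle(heading_quat(d)), d, atol=1e-12)


class TestCrossMatrix:
    def test_z_cross_x(self):
        assert np.allclose(cross_matrix([0, 0, 1]) @ [1, 0, 0], [0, 1, 0])

    def test_self_cross_vanishes(self, rng):
        v = rng.standard_normal(3)
        assert np.allclose(cross_matrix(v) @ v, 0.0, atol=1e-12)

    def test_squared_equals_triple_product_identity(self, rng):
        # ([ω]×)² p = ω (ω·p) − |ω|² p
        w = rng.standard_normal(3)
        p = rng.standard_normal(3)
        lhs = cross_matrix(w) @ (cross_matrix(w) @ p)
        rhs = w * (w @ p) - (w @ w) * p
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_skew_symmetric(self, rng):
        m = cross_matrix(rng.standard_normal(3))
        assert np.allclose(m, -m.T)


class TestVecOps:
    @pytest.mark.parametrize(
        "v,expected",
        [
            ([0.0, 3.0, 0.0], [0.0, 1.0, 0.0]),
            ([2.0, 0.0, 0.0], [1.0, 0.0, 0.0]),
            ([1.0, 1.0, 1.0], [1 / np.sqrt(3)] * 3),
        ],
    )
    def test_normalize(self, v, expected):
        assert np.allclose(normalize_vec(v), expected)

    def test_normalize_zero_raises(self):
        with pytest.raises(ValueError):
            normalize_vec([0.0, 0.0, 0.0])

    @pytest.mark.parametrize(
        "deg,expected",
        [(355.0, -5.0), (-180.0, 180.0), (720.0, 0.0), (180.0, 180.0), (10.0, 10.0)],
    )
    def test_wrap_angle(self, deg, expected):
        assert np.isclose(np.rad2deg(wrap_angle(np.deg2rad(deg))), expected, atol=1e-9)

    def test_angle_between_is_safe_near_degenerate(self):
        assert np.isclose(angle_between([1, 0, 0], [1, 1e-9, 0]), 1e-9, rtol=1e-3)
        assert np.isclose(angle_between([1, 0, 0], [-1, 1e-9, 0]), np.pi - 1e-9, rtol=1e-3)


def test_quat_log_recovers_rotation_vector(rng):
    for _ in range(20):
        axis = normalize_vec(rng.standard_normal(3))
        angle = rng.uniform(0.01, 3.0)
        q = np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])
        assert np.allclose(quat_log(q), axis * angle, atol=1e-9)
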
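"""Heading-offset estimation: disagreement, cost, grids, gate, convergence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from armfusion.heading import (
    HeadingState,
    coarse_grid,
    cost,
    disagreement,
    gyro_derivative,
    joint_specific_force,
    motion_gate,
    optdelta,
    refine_grid,
    robot_joint_accel,
    smooth_for_disagreement,
    update_heading,
)
from armfusion.quat import heading_quat, wrap_angle

DEG = np.deg2rad


def rz(deg):
    """Independent rotation oracle about z."""
    return Rotation.from_euler("z", deg, degrees=True)


def informative_window(rng, m=60, scale=2.0):
    """Accelerations with varied, non-collinear horizontal components."""
    return scale * rng.standard_normal((m, 3))


class TestJointSpecificForce:
    def test_no_rotation_passes_acc_through(self, rng):
        acc = rng.standard_normal(3)
        out = joint_specific_force(acc, np.zeros(3), np.zeros(3), [0.15, 0, 0])
        assert np.allclose(out, acc)

    def test_radial_term(self):
        out = joint_specific_force(
            [0, 0, 9.81], [0, 0, 2.0], np.zeros(3), [0.15, 0, 0]
        )
        assert np.allclose(out, [-0.6, 0.0, 9.81])

    def test_tangential_term(self):
        alpha, r = 3.0, 0.2
        out = joint_specific_force(np.zeros(3), np.zeros(3), [0, 0, alpha], [r, 0, 0])
        assert np.allclose(out, [0.0, alpha * r, 0.0])

    def test_matches_finite_difference_oracle_for_rotating_point(self):
        """A point at radius r on a uniformly rotating disc: the lever-arm
        terms must reproduce its centripetal acceleration."""
        w, r, fs = 1.7, 0.15, 100.0
        t = np.arange(0, 4, 1 / fs)
        # joint at origin; IMU at radius r; body x-axis points IMU -> joint
        p_joint_world = np.zeros((len(t), 3))
        p_imu_world = -r * np.stack([np.cos(w * t), np.sin(w * t), 0 * t], -1)
        acc_imu_world = np.gradient(np.gradient(p_imu_world, 1 / fs, axis=0), 1 / fs, axis=0)
        # body frame: rotates with the disc, x from IMU toward joint
        q = heading_quat(w * t)
        from armfusion.quat import quat_conj, rotate

        acc_body = rotate(quat_conj(q), acc_imu_world)
        sf_joint = joint_specific_force(
            acc_body, np.tile([0, 0, w], (len(t), 1)), np.zeros((len(t), 3)), [r, 0, 0]
        )
        a_joint = rotate(q, sf_joint)
        interior = slice(5, -5)
        assert np.allclose(a_joint[interior], p_joint_world[interior], atol=1e-3)


class TestDerivatives:
    def test_constant_gyro_derivative_vanishes(self):
        t = np.arange(0, 10, 0.01)
        gyro = np.tile([0.3, -0.2, 0.1], (len(t), 1))
        d = gyro_derivative(t, gyro)
        assert np.max(np.abs(d[len(t) // 2 :])) < 1e-6

    def test_slow_sine_derivative_amplitude(self):
        t = np.arange(0, 30, 0.01)
        f = 0.2  # well below the 2.5 Hz cutoff
        gyro = np.stack([np.sin(2 * np.pi * f * t), 0 * t, 0 * t], -1)
        d = gyro_derivative(t, gyro)
        amp = np.max(np.abs(d[len(t) // 2 :, 0]))
        assert np.isclose(amp, 2 * np.pi * f, rtol=0.05)

    def test_fast_sine_strongly_attenuated(self):
        t = np.arange(0, 10, 0.01)
        f = 10.0  # far above cutoff
        gyro = np.stack([np.sin(2 * np.pi * f * t), 0 * t, 0 * t], -1)
        d = gyro_derivative(t, gyro)
        amp = np.max(np.abs(d[len(t) // 2 :, 0]))
        assert amp < 0.1 * 2 * np.pi * f

    def test_short_stream_flagged(self):
        with pytest.raises(ValueError, match="warm-up"):
            gyro_derivative(np.arange(5) * 0.01, np.zeros((5, 3)))

    def test_robot_accel_constant_and_quadratic(self):
        t = np.arange(0, 4, 0.04)
        assert np.allclose(robot_joint_accel(t, np.ones((len(t), 3))), 0.0)
        a = 1.3
        p = np.stack([0 * t, 0.5 * a * t**2, 0 * t], -1)
        acc = robot_joint_accel(t, p)
        assert np.allclose(acc[2:-2, 1], a, atol=1e-9)  # exact on the interior

    def test_robot_accel_sine_amplitude(self):
        t = np.arange(0, 60, 0.04)
        f, amp = 0.3, 0.1
        p = np.stack([amp * np.sin(2 * np.pi * f * t), 0 * t, 0 * t], -1)
        acc = robot_joint_accel(t, p)
        got = np.max(np.abs(acc[100:-100, 0]))
        assert np.isclose(got, amp * (2 * np.pi * f) ** 2, rtol=0.02)

    @pytest.mark.parametrize(
        "freq,fs,check",
        [
            (0.1, 25.0, lambda a: a > 0.9),    # passband: < 10% attenuation
            (5.0, 25.0, lambda a: a < 0.01),   # stopband: > 99% attenuation
        ],
    )
    def test_disagreement_lowpass_response(self, freq, fs, check):
        t = np.arange(0, 80, 1 / fs)
        x = np.stack([np.sin(2 * np.pi * freq * t), 0 * t, 0 * t], -1)
        y = smooth_for_disagreement(x, fs)
        amp = np.max(np.abs(y[len(t) // 2 :, 0]))
        assert check(amp)

    def test_dc_passes_unchanged(self):
        t = np.arange(0, 60, 0.04)
        x = np.tile([1.0, -2.0, 0.5], (len(t), 1))
        y = smooth_for_disagreement(x, 25.0)
        assert np.allclose(y[-1], x[-1], atol=1e-6)


class TestDisagreementAndCost:
    def test_zero_when_frames_agree(self, rng):
        a = rng.standard_normal(3)
        assert np.allclose(disagreement(0.0, a, a), 0.0)

    def test_quarter_turn_alignment(self):
        assert np.allclose(disagreement(DEG(90), [1, 0, 0], [0, 1, 0]), 0.0, atol=1e-12)
        assert np.allclose(disagreement(DEG(90), [1, 0, 0], [1, 0, 0]), [-1, 1, 0], atol=1e-12)

    def test_cost_hand_computed_single_pair(self):
        a, b = np.array([[1.0, 0, 0]]), np.array([[0.0, 1, 0]])
        assert np.isclose(cost(0.0, a, b), 2.0)
        assert np.isclose(cost(DEG(90), a, b), 0.0, atol=1e-12)

    def test_cost_is_periodic(self, rng):
        a = informative_window(rng)
        b = informative_window(rng)
        d = rng.uniform(0, 2 * np.pi, 10)
        assert np.allclose(cost(d, a, b), cost(d + 2 * np.pi, a, b), rtol=1e-10)

    def test_cost_matches_direct_sum_oracle(self, rng):
        """Closed-form cost equals the literal sum of squared disagreements
        computed with the scipy rotation oracle."""
        a = informative_window(rng, m=30)
        b = informative_window(rng, m=30)
        for deg in (0.0, 17.0, 120.0, 301.0):
            direct = sum(
                np.sum((rz(deg).apply(ai) - bi) ** 2) for ai, bi in zip(a, b)
            )
            assert np.isclose(cost(DEG(deg), a, b), direct, rtol=1e-10)

    def test_vertical_only_acceleration_leaves_cost_flat(self, rng):
        """Purely vertical joint acceleration makes the heading unobservable:
        the cost must not depend on delta."""
        az = rng.standard_normal((50, 1))
        a = np.concatenate([np.zeros((50, 2)), az], axis=1)
        c = cost(coarse_grid(), a, a)
        assert np.ptp(c) < 1e-9 * max(1.0, np.max(c))


class TestOptdelta:
    def test_equals_brute_force_on_random_windows(self, rng):
        grid = DEG(np.arange(0.0, 360.0))
        for _ in range(100):
            a = informative_window(rng, m=20)
            b = informative_window(rng, m=20)
            brute = min(
                grid, key=lambda d: float(np.sum((rz(np.rad2deg(d)).apply(a) - b) ** 2))
            )
            assert np.isclose(optdelta(grid, a, b), brute, atol=1e-12)

    def test_noise_free_recovery_on_coarse_grid(self, rng):
        a = informative_window(rng)
        b = rz(40.0).apply(a)
        assert np.isclose(np.rad2deg(optdelta(coarse_grid(), a, b)), 40.0)

    def test_two_step_refinement_recovers_off_grid_offset(self, rng):
        a = informative_window(rng)
        b = rz(42.0).apply(a)
        coarse = optdelta(coarse_grid(), a, b)
        assert np.isclose(np.rad2deg(coarse), 40.0)
        fine = optdelta(refine_grid(coarse), a, b)
        assert np.isclose(np.rad2deg(fine), 42.0)

    def test_degenerate_window_ties_break_to_smallest_wrapped_angle(self):
        a = np.zeros((10, 3))
        assert optdelta(coarse_grid(), a, a) == 0.0

    def test_empty_grid_rejected(self, rng):
        a = informative_window(rng, m=5)
        with pytest.raises(ValueError):
            optdelta(np.array([]), a, a)


class TestMotionGate:
    def make_stream(self, moving_subwindows, fs=25.0, amp=0.2):
        t = np.arange(0, 20 + 1 / fs, 1 / fs)
        x = np.zeros_like(t)
        for k in moving_subwindows:
            sel = (t >= 4 * k) & (t <= 4 * (k + 1))
            # smooth bump returning to the rest point at the sub-window edges
            x[sel] = amp * np.sin(np.pi * (t[sel] - 4 * k) / 4.0) ** 2
        return t, np.stack([x, 0 * t, 0 * t], -1)

    def test_constant_position_gates_off(self):
        t, p = self.make_stream([])
        assert motion_gate(t, p) is False

    def test_motion_everywhere_gates_on(self):
        t, p = self.make_stream([0, 1, 2, 3, 4])
        assert motion_gate(t, p) is True

    @pytest.mark.parametrize("n_moving,expected", [(2, False), (3, True)])
    def test_three_of_five_boundary(self, n_moving, expected):
        t, p = self.make_stream(list(range(n_moving)))
        assert motion_gate(t, p) is expected

    def test_sub_threshold_motion_does_not_count(self):
        t, p = self.make_stream([0, 1, 2, 3, 4], amp=0.09)  # within the 10 cm sphere
        assert motion_gate(t, p) is False

    def test_short_window_rejected(self):
        t = np.arange(0, 10, 0.04)
        with pytest.raises(ValueError):
            motion_gate(t, np.zeros((len(t), 3)))


class TestUpdateHeading:
    def run_updates(self, rng, delta_deg, n_updates, state=None, gated=True):
        state = state or HeadingState()
        deltas = np.broadcast_to(np.atleast_1d(delta_deg), (n_updates,))
        for i, d in enumerate(deltas):
            a = informative_window(rng)
            b = rz(d).apply(a)
            update_heading(state, a, b, gated, t=20.0 + 5.0 * i)
        return state

    def test_noise_free_two_step_convergence_at_fifth_update(self, rng):
        state = self.run_updates(rng, 73.0, 5)
        assert state.converged
        assert len(state.history) == 5
        est = np.rad2deg([h[1] for h in state.history])
        assert np.allclose(est, 73.0, atol=1.0)

    def test_convergence_rule_on_given_sequence(self):
        """Estimates 100,103,101,98,100: every consecutive change <= 5°."""
        state = HeadingState()
        state.history = [(5.0 * i, DEG(v)) for i, v in enumerate([100, 103, 101, 98, 100])]
        from armfusion.heading import _streak_converged

        assert _streak_converged(state.history, 5, DEG(5.0))
        state.history[-1] = (20.0, DEG(107.0))  # 98 -> 107 jumps 9°
        assert not _streak_converged(state.history, 5, DEG(5.0))

    def test_ungated_update_holds_estimate(self, rng):
        state = self.run_updates(rng, 50.0, 5)
        before = (state.delta_hat, len(state.history))
        a = informative_window(rng)
        update_heading(state, a, rz(120.0).apply(a), gated=False, t=60.0)
        assert (state.delta_hat, len(state.history)) == before

    def test_one_step_tracks_drifting_offset(self, rng):
        """δ drifting at 0.3 deg/s with 5 s updates (1.5°/update < 5° grid
        half-width): the one-step update follows within 1°."""
        state = self.run_updates(rng, 30.0, 5)
        assert state.converged
        for i in range(20):
            true = 30.0 + 0.3 * 5.0 * (i + 1)
            a = informative_window(rng)
            update_heading(state, a, rz(true).apply(a), True, t=45.0 + 5.0 * i)
            err = abs(wrap_angle(state.delta_hat - DEG(true)))
            assert np.rad2deg(err) <= 1.0
        assert state.edge_hits == 0

    def test_exact_recovery_across_offset_circle(self, rng):
        """Noise-free recovery within 1° for true offsets on a 7° grid."""
        for delta0 in np.arange(0.0, 360.0, 7.0):
            state = self.run_updates(rng, delta0, 5)
            err = abs(wrap_angle(state.delta_hat - DEG(delta0)))
            assert np.rad2deg(err) <= 1.0, f"failed at delta0={delta0}"

    def test_equivariance_under_robot_frame_rotation(self, rng):
        """Rotating all robot-frame inputs by α shifts the estimate by α."""
        windows = [informative_window(rng) for _ in range(5)]
        alpha = 25.0

        def estimate(extra):
            state = HeadingState()
            for i, a in enumerate(windows):
                b = rz(130.0 + extra).apply(a)
                update_heading(state, a, b, True, t=20.0 + 5.0 * i)
            return state.delta_hat

        d0, d1 = estimate(0.0), estimate(alpha)
        assert np.rad2deg(abs(wrap_angle(d1 - d0 - DEG(alpha)))) <= 1.0
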
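"""Magnetometer-free strapdown orientation estimation.

Estimates the orientation ``q_IA`` of the IMU/segment frame A relative to an
inertial reference frame I whose z-axis is vertical but whose heading is
arbitrary and drifts slowly with the integrated gyroscope bias.  The filter
is a complementary accelerometer-corrected strapdown integrator:

1. strapdown step — the quaternion is advanced by the exact quaternion
   exponential of ``ω · dt`` (body-frame angular rate);
2. inclination correction — the measured specific-force direction, rotated
   into I, is pulled toward the vertical by a small rotation about a
   *horizontal* axis, at an angular rate ``gain · tilt_error``.

Because the correction axis is always horizontal, the heading component is
never touched: it remains unobservable without a magnetometer and is free to
drift, exactly the contract the downstream heading estimator relies on.

No magnetometer, no initial rest phase and no gyroscope bias calibration are
used.  The initial orientation is taken from the first accelerometer sample
(tilt) with heading zero; any other choice would simply be absorbed into the
heading offset δ between frames I and R.
"""

from __future__ import annotations

import math

import numpy as np

from .quat import quat_conj, quat_from_axis_angle, rotate

__all__ = ["OrientationFilter", "tilt_from_accel", "run_orientation_filter"]

#: Default inclination-correction gain in 1/s.  The steady-state tilt error
#: under a constant horizontal gyro-bias component b is ~ b / gain, so the
#: gain must be large enough to reject realistic MEMS biases (tenths of a
#: deg/s) while staying slow enough that motion-induced specific force does
#: not leak into the inclination.  0.2 1/s (5 s time constant) keeps both
#: error sources well below 1° for the motions considered here.
DEFAULT_GAIN = 0.2

_GRAVITY = 9.81
#: Specific-force norms below this fraction of g skip the correction
#: (free-fall guard: no usable vertical reference).
_FREEFALL_FRACTION = 0.1


def tilt_from_accel(acc: np.ndarray) -> np.ndarray:
    """Initial orientation from one accelerometer sample: tilt only, heading 0.

    Returns the shortest-arc quaternion mapping the measured specific-force
    direction (body frame) onto the world vertical ``[0, 0, 1]``.  The
    rotation axis is horizontal, so the heading of the result is zero by
    construction.
    """
    a = np.asarray(acc, dtype=float)
    n = np.linalg.norm(a)
    if n < 1e-9:
        raise ValueError("cannot initialize orientation from a zero accelerometer sample")
    u = a / n
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    angle = math.atan2(s, float(u @ z))
    if s < 1e-12:
        # aligned or anti-aligned with the vertical
        if u[2] > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180° about x
    return quat_from_axis_angle(axis / s, angle)


class OrientationFilter:
    """Complementary accelerometer-corrected strapdown filter (no magnetometer).

    Parameters
    ----------
    gain : float
        Inclination-correction gain in 1/s.
    gravity : float
        Gravitational acceleration magnitude in m/s².

    Attributes
    ----------
    q : ndarray shape (4,)
        Current estimate of ``q_IA`` (unit, scalar-first).
    t_last : float or None
        Timestamp of the last processed sample.
    """

    def __init__(self, gain: float = DEFAULT_GAIN, gravity: float = _GRAVITY):
        self.gain = float(gain)
        self.gravity = float(gravity)
        self.q: np.ndarray | None = None
        self.t_last: float | None = None

    def initialize(self, t: float, acc: np.ndarray) -> None:
        self.q = tilt_from_accel(acc)
        self.t_last = float(t)

    def update(self, t: float, gyro: np.ndarray, acc: np.ndarray) -> np.ndarray:
        """Advance the estimate to time ``t`` and return ``q_IA``.

        The first call initializes from the accelerometer.  Timestamps must
        be strictly increasing.
        """
        if self.q is None:
            self.initialize(t, acc)
            return self.q
        t = float(t)
        if t <= self.t_last:
            raise ValueError(
                f"non-monotone timestamps in IMU stream: {t} after {self.t_last}"
            )
        dt = t - self.t_last
        self.t_last = t

        # --- strapdown: exact quaternion exponential of ω dt ---------------
        gx, gy, gz = (float(g) for g in gyro)
        w = math.sqrt(gx * gx + gy * gy + gz * gz)
        qw, qx, qy, qz = self.q
        if w > 1e-12:
            half = 0.5 * w * dt
            c, s = math.cos(half), math.sin(half) / w
            dw, dx, dy, dz = c, gx * s, gy * s, gz * s
            qw, qx, qy, qz = (
                qw * dw - qx * dx - qy * dy - qz * dz,
                qw * dx + qx * dw + qy * dz - qz * dy,
                qw * dy - qx * dz + qy * dw + qz * dx,
                qw * dz + qx * dy - qy * dx + qz * dw,
            )

        # --- inclination correction (horizontal axis only) ------------------
        ax, ay, az = (float(a) for a in acc)
        an = math.sqrt(ax * ax + ay * ay + az * az)
        if an > _FREEFALL_FRACTION * self.gravity:
            ax, ay, az = ax / an, ay / an, az / an
            # v = rotate(q, a_unit): measured "up" in frame I
            tx = 2.0 * (qy * az - qz * ay)
            ty = 2.0 * (qz * ax - qx * az)
            tz = 2.0 * (qx * ay - qy * ax)
            vx = ax + qw * tx + (qy * tz - qz * ty)
            vy = ay + qw * ty + (qz * tx - qx * tz)
            vz = az + qw * tz + (qx * ty - qy * tx)
            # axis = v × z (horizontal), tilt error angle = atan2(‖axis‖, vz)
            ex, ey = vy, -vx
            en = math.sqrt(ex * ex + ey * ey)
            if en > 1e-12:
                tilt = math.atan2(en, vz)
                ang = min(self.gain * dt, 1.0) * tilt
                half = 0.5 * ang
                c, s = math.cos(half), math.sin(half) / en
                cw, cx, cy = c, ex * s, ey * s
                # q <- correction ⊗ q (world-frame rotation, cz = 0)
                qw, qx, qy, qz = (
                    cw * qw - cx * qx - cy * qy,
                    cw * qx + cx * qw + cy * qz,
                    cw * qy - cx * qz + cy * qw,
                    cw * qz + cx * qy - cy * qx,
                )

        n = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        self.q = np.array([qw / n, qx / n, qy / n, qz / n])
        return self.q


def run_orientation_filter(
    t: np.ndarray,
    gyro: np.ndarray,
    acc: np.ndarray,
    gain: float = DEFAULT_GAIN,
    gravity: float = _GRAVITY,
) -> np.ndarray:
    """Run the filter over a whole stream; returns quaternions, shape (n, 4)."""
    t = np.asarray(t, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    acc = np.asarray(acc, dtype=float)
    filt = OrientationFilter(gain=gain, gravity=gravity)
    out = np.empty((len(t), 4))
    for i in range(len(t)):
        out[i] = filt.update(t[i], gyro[i], acc[i])
    return out


def inclination_error(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Tilt angle (rad) between the body z-axes implied by two orientations.

    Heading-independent measure of inclination agreement: the angle between
    ``rotate(q_est, ẑ)`` and ``rotate(q_true, ẑ)`` after both are expressed
    in their (possibly differently-headed) world frames is not meaningful,
    so instead compare the world vertical seen from the body frame:
    ``rotate(q*, ẑ)`` — identical headings cancel.
    """
    z = np.array([0.0, 0.0, 1.0])
    b_est = rotate(quat_conj(np.asarray(q_est)), z)
    b_true = rotate(quat_conj(np.asarray(q_true)), z)
    dot = np.clip(np.sum(b_est * b_true, axis=-1), -1.0, 1.0)
    return np.arccos(dot)
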
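"""Estimation of the drifting heading offset δ between frames I and R.

The orientation filter provides the segment orientation relative to an
inertial frame I whose heading is arbitrary and drifts with the integrated
gyroscope bias.  The robot measures the position of the inter-segment joint
(elbow) in its own workspace frame R.  Both frames share the vertical axis,
so they differ by a single slowly drifting rotation δ(t) about z.

δ is inferred by comparing two independent measurements of the same physical
quantity — the acceleration of the joint:

* IMU route: the specific force is shifted from the sensor location to the
  joint using the rigid-body terms (radial ``([ω]×)² p`` and tangential
  ``[ω̇]× p``), rotated into frame I with the estimated orientation, and
  gravity is removed.
* robot route: the second numerical time derivative of the measured joint
  position.

Both signals are low-pass filtered with identical causal 5th-order
Butterworth filters (0.5 Hz cutoff) so their group delays cancel in the
disagreement.  The squared disagreement, summed over a moving window, is a
cost whose minimizer over a heading grid is the estimate: a coarse 5° grid
followed by a ±5° refinement at 1° spacing while unconverged, and a single
±5° / 1° step around the previous estimate once five consecutive estimates
agree within 5°.  Updates run every 5 s and only when the joint actually
moved (at least three of five 4-s sub-windows leave a 10 cm-diameter
sphere); without motion the heading is unobservable and the estimate is
held.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.distance import pdist

from .quat import heading_quat, rotate, wrap_angle

__all__ = [
    "GeometryConfig",
    "HeadingState",
    "joint_specific_force",
    "butter_lowpass",
    "gyro_derivative",
    "joint_acceleration_inertial",
    "robot_joint_accel",
    "smooth_for_disagreement",
    "disagreement",
    "cost",
    "optdelta",
    "motion_gate",
    "coarse_grid",
    "refine_grid",
    "update_heading",
]

logger = logging.getLogger(__name__)

_GRAVITY_VEC = np.array([0.0, 0.0, 9.81])


@dataclass
class GeometryConfig:
    """Segment geometry linking the IMU, the joint and the free endpoint.

    Attributes
    ----------
    p_imu_to_joint : ndarray (3,)
        Vector from the IMU to the joint in the segment frame A, meters
        (``ApE``).  The A-frame x-axis points along the segment toward the
        joint, so for a sensor mounted 15 cm proximal of the elbow this is
        ``[0.15, 0, 0]``.
    l_a : float
        Length of the adjacent segment (upper arm), meters.
    l_p : float
        Distance from the proximal forearm cuff to the elbow, meters.
    """

    p_imu_to_joint: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.0, 0.0])
    )
    l_a: float = 0.30
    l_p: float = 0.08

    def __post_init__(self) -> None:
        self.p_imu_to_joint = np.asarray(self.p_imu_to_joint, dtype=float)
        if np.linalg.norm(self.p_imu_to_joint) <= 0:
            raise ValueError("p_imu_to_joint must be non-zero")
        if self.l_a <= 0:
            raise ValueError("segment length l_a must be positive")
        if self.l_p < 0:
            raise ValueError("cuff distance l_p must be non-negative")


@dataclass
class HeadingState:
    """State of the heading-offset estimator.

    ``delta_hat`` is the current estimate in radians, wrapped to [0, 2π), or
    ``None`` before the first gated update.  ``history`` keeps one entry per
    *gated* update (non-gated windows neither update nor reset the
    convergence streak).
    """

    delta_hat: float | None = None
    converged: bool = False
    history: list[tuple[float, float]] = field(default_factory=list)  # (t, δ̂)
    delta_tilde: float | None = None  # last coarse two-step result
    edge_hits: int = 0  # refined-grid-edge warnings (diagnostic)


# --------------------------------------------------------------------------
# signal-level operations
# --------------------------------------------------------------------------

def joint_specific_force(
    acc: np.ndarray,
    gyro: np.ndarray,
    gyro_dot: np.ndarray,
    p_imu_to_joint: np.ndarray,
) -> np.ndarray:
    """Shift the measured specific force from the IMU to the joint (frame A).

    ``a~_E = a~_A + ([ω]×)² p + [ω̇]× p`` — the radial and tangential
    acceleration terms of the rotation about the joint.  All arguments may be
    batched with shape (n, 3).
    """
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    gyro_dot = np.asarray(gyro_dot, dtype=float)
    p = np.asarray(p_imu_to_joint, dtype=float)
    # ([ω]×)² p = ω (ω·p) − |ω|² p
    radial = gyro * np.sum(gyro * p, axis=-1, keepdims=True) - (
        np.sum(gyro * gyro, axis=-1, keepdims=True) * p
    )
    tangential = np.cross(gyro_dot, p)
    return acc + radial + tangential


def butter_lowpass(
    x: np.ndarray, cutoff_hz: float, fs: float, order: int = 5
) -> np.ndarray:
    """Causal (forward-only) Butterworth low-pass along axis 0.

    Causality matters: the method runs in real time, and applying the *same*
    causal filter to both sides of the disagreement cancels the group delay.
    The filter state is warm-started at the first sample value to suppress
    the step transient.
    """
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    x2 = np.atleast_2d(x.T).T
    out = np.empty_like(x2)
    for j in range(x2.shape[1]):
        zi = signal.sosfilt_zi(sos) * x2[0, j]
        out[:, j], _ = signal.sosfilt(sos, x2[:, j], zi=zi)
    return out.reshape(x.shape)


def gyro_derivative(
    t: np.ndarray,
    gyro: np.ndarray,
    cutoff_hz: float = 2.5,
    order: int = 5,
    compensate_delay: bool = True,
) -> np.ndarray:
    """Angular acceleration ``ω̇`` by differentiating the low-passed rate.

    The angular rate is filtered per axis with a causal Butterworth
    (default 5th order, 2.5 Hz) and then differentiated with central
    differences.  Requires a uniformly sampled stream long enough for the
    filter to settle.

    With ``compensate_delay`` the result is advanced by the filter's
    passband group delay (≈ 0.19 s at these defaults), re-aligning ``ω̇``
    with the *unfiltered* terms it is combined with in the joint-shift
    equation.  Without this, the delayed tangential term rotates the
    disagreement optimum by a few degrees.  The compensation only uses
    samples that already exist, so the windowed heading update — which runs
    retrospectively every few seconds — remains real-time feasible; the
    trailing ``delay`` samples simply hold the last aligned value.
    """
    t = np.asarray(t, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if len(t) < 15:
        raise ValueError("gyro stream shorter than the filter warm-up (need >= 15 samples)")
    dt = float(np.median(np.diff(t)))
    fs = 1.0 / dt
    filtered = butter_lowpass(gyro, cutoff_hz, fs, order=order)
    deriv = np.gradient(filtered, dt, axis=0)
    if compensate_delay:
        sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
        _, gd = signal.group_delay(signal.sos2tf(sos), w=[0.0], fs=fs)
        shift = int(round(float(gd[0])))
        if 0 < shift < len(deriv):
            deriv = np.concatenate([deriv[shift:], np.repeat(deriv[-1:], shift, axis=0)])
    return deriv


def joint_acceleration_inertial(
    sf_joint: np.ndarray, q: np.ndarray, gravity: float = 9.81
) -> np.ndarray:
    """Joint acceleration in frame I: rotate the specific force, drop gravity.

    ``a_E^I = q ⊗ a~_E ⊗ q* − [0, 0, g]``.  Batched when ``sf_joint`` and
    ``q`` have matching leading axes.
    """
    g = np.array([0.0, 0.0, float(gravity)])
    return rotate(q, np.asarray(sf_joint, dtype=float)) - g


def robot_joint_accel(t: np.ndarray, p_e: np.ndarray) -> np.ndarray:
    """Second time derivative of the measured joint position (frame R).

    Central differences per axis; exact for quadratic trajectories on the
    interior.  The result is meant to be smoothed by
    :func:`smooth_for_disagreement` before entering the cost.
    """
    t = np.asarray(t, dtype=float)
    p_e = np.asarray(p_e, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to differentiate twice")
    dt = float(np.median(np.diff(t)))
    return np.gradient(np.gradient(p_e, dt, axis=0), dt, axis=0)


def smooth_for_disagreement(
    x: np.ndarray, fs: float, cutoff_hz: float = 0.5, order: int = 5
) -> np.ndarray:
    """The shared 0.5 Hz causal Butterworth applied to both acceleration routes."""
    return butter_lowpass(x, cutoff_hz, fs, order=order)


# --------------------------------------------------------------------------
# disagreement, cost and grid optimization
# --------------------------------------------------------------------------

def disagreement(delta: float, a_i: np.ndarray, pdd_r: np.ndarray) -> np.ndarray:
    """``d(δ) = Rz(δ) ⊗ a_I ⊗ Rz(δ)* − p̈_R`` for one time-aligned pair."""
    return rotate(heading_quat(delta), np.asarray(a_i, dtype=float)) - np.asarray(
        pdd_r, dtype=float
    )


def cost(delta: float | np.ndarray, a_i: np.ndarray, pdd_r: np.ndarray) -> float | np.ndarray:
    """Windowed cost ``c(δ) = Σ_k ‖d(δ, a_I[k], p̈_R[k])‖²``.

    ``a_i`` and ``pdd_r`` are the filtered, time-aligned window arrays of
    shape (m, 3); ``delta`` may be a scalar or a grid of angles (rad).
    """
    a_i = np.atleast_2d(np.asarray(a_i, dtype=float))
    pdd_r = np.atleast_2d(np.asarray(pdd_r, dtype=float))
    if a_i.shape != pdd_r.shape or a_i.shape[0] == 0:
        raise ValueError("cost() requires equal-length, non-empty window arrays")
    delta_arr = np.atleast_1d(np.asarray(delta, dtype=float))
    c, s = np.cos(delta_arr), np.sin(delta_arr)
    ax, ay, az = a_i[:, 0], a_i[:, 1], a_i[:, 2]
    bx, by, bz = pdd_r[:, 0], pdd_r[:, 1], pdd_r[:, 2]
    # ‖Rz(δ) a − b‖² summed over the window, expanded in cos δ / sin δ
    const = float(np.sum(a_i * a_i) + np.sum(pdd_r * pdd_r) - 2.0 * np.sum(az * bz))
    p = float(np.sum(ax * bx + ay * by))
    q = float(np.sum(ax * by - ay * bx))
    out = const - 2.0 * (p * c + q * s)
    out = np.maximum(out, 0.0)  # clip the tiny negative round-off
    if np.isscalar(delta) or np.ndim(delta) == 0:
        return float(out[0])
    return out


def optdelta(grid: np.ndarray, a_i: np.ndarray, pdd_r: np.ndarray) -> float:
    """Grid argmin of the windowed cost; returns the minimizing angle (rad).

    Ties (within 1e-12 relative) are broken toward the smallest wrapped
    angle, which makes degenerate (motion-free) windows deterministic.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("optdelta() requires a non-empty grid")
    c = np.asarray(cost(grid, a_i, pdd_r))
    cmin = c.min()
    tol = 1e-12 * max(1.0, abs(cmin))
    candidates = grid[c <= cmin + tol]
    return float(candidates[np.argmin(np.abs(wrap_angle(candidates)))])


# --------------------------------------------------------------------------
# motion gate and the update rule
# --------------------------------------------------------------------------

def motion_gate(
    t: np.ndarray,
    p_e: np.ndarray,
    window_s: float = 20.0,
    n_subwindows: int = 5,
    sphere_diameter_m: float = 0.10,
    min_moving: int = 3,
) -> bool:
    """Decide whether the last ``window_s`` of joint motion suffices.

    The window is split into ``n_subwindows`` equal sub-windows; a sub-window
    contains *considerable motion* when the joint position does not stay
    inside a sphere of ``sphere_diameter_m`` diameter, i.e. its maximum
    pairwise point distance exceeds the diameter.  The gate opens when at
    least ``min_moving`` sub-windows move.
    """
    t = np.asarray(t, dtype=float)
    p_e = np.asarray(p_e, dtype=float)
    if len(t) < 2 or (t[-1] - t[0]) < window_s - 1e-6:
        raise ValueError(f"motion gate requires {window_s} s of joint positions")
    t_end = t[-1]
    edges = t_end - window_s + np.linspace(0.0, window_s, n_subwindows + 1)
    moving = 0
    for k in range(n_subwindows):
        sel = (t >= edges[k] - 1e-9) & (t <= edges[k + 1] + 1e-9)
        pts = p_e[sel]
        if len(pts) >= 2 and pdist(pts).max() > sphere_diameter_m:
            moving += 1
    return moving >= min_moving


def coarse_grid(step_deg: float = 5.0) -> np.ndarray:
    """The full-circle coarse grid {0°, step, …, 360°−step} in radians."""
    return np.deg2rad(np.arange(0.0, 360.0, step_deg))


def refine_grid(
    center: float, halfwidth_deg: float = 5.0, step_deg: float = 1.0
) -> np.ndarray:
    """Refinement grid {center−hw, …, center+hw} at ``step_deg`` spacing (rad)."""
    offsets = np.deg2rad(
        np.arange(-halfwidth_deg, halfwidth_deg + 0.5 * step_deg, step_deg)
    )
    return center + offsets


def _streak_converged(history: list[tuple[float, float]], n: int, tol: float) -> bool:
    """True when the last ``n`` estimates each changed by at most ``tol`` (wrapped)."""
    if len(history) < n:
        return False
    vals = [h[1] for h in history[-n:]]
    diffs = [abs(wrap_angle(b - a)) for a, b in zip(vals, vals[1:])]
    return all(d <= tol + 1e-12 for d in diffs)


def update_heading(
    state: HeadingState,
    a_i: np.ndarray,
    pdd_r: np.ndarray,
    gated: bool,
    t: float,
    coarse_step_deg: float = 5.0,
    refine_halfwidth_deg: float = 5.0,
    refine_step_deg: float = 1.0,
    convergence_len: int = 5,
    convergence_tol_deg: float = 5.0,
) -> HeadingState:
    """One periodic heading update (runs every 5 s of stream time).

    Without enough motion the estimate is held unchanged (heading is
    unobservable from a resting joint).  While unconverged, a two-step
    update runs: coarse full-circle grid, then ±5° refinement at 1°.  Once
    five consecutive gated estimates agree within 5°, the estimator is
    converged and subsequent updates search only ±5° around the previous
    estimate.  Mutates and returns ``state``.
    """
    if not gated:
        return state
    tol = np.deg2rad(convergence_tol_deg)
    if not state.converged:
        delta_tilde = optdelta(coarse_grid(coarse_step_deg), a_i, pdd_r)
        delta_hat = optdelta(
            refine_grid(delta_tilde, refine_halfwidth_deg, refine_step_deg), a_i, pdd_r
        )
        state.delta_tilde = float(np.mod(delta_tilde, 2.0 * np.pi))
    else:
        grid = refine_grid(state.delta_hat, refine_halfwidth_deg, refine_step_deg)
        delta_hat = optdelta(grid, a_i, pdd_r)
        if min(abs(delta_hat - grid[0]), abs(delta_hat - grid[-1])) < 1e-9:
            state.edge_hits += 1
            logger.warning(
                "heading update at t=%.1f s hit the edge of the ±%g° refinement grid",
                t,
                refine_halfwidth_deg,
            )
        state.delta_tilde = None
    state.delta_hat = float(np.mod(delta_hat, 2.0 * np.pi))
    state.history.append((float(t), state.delta_hat))
    if not state.converged and _streak_converged(state.history, convergence_len, tol):
        state.converged = True
        logger.info("heading estimator converged at t=%.1f s (δ̂=%.1f°)",
                    t, np.rad2deg(state.delta_hat))
    return state
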
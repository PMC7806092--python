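"""End-to-end hybrid tracking: streams in, robot-frame poses out.

Wires the orientation filter, the heading estimator and the pose
reconstruction into one batch pipeline operating on recorded (or simulated)
IMU and robot streams.  All filters are causal, so the batch result is
sample-for-sample what a real-time implementation would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .heading import (
    GeometryConfig,
    HeadingState,
    cost,
    gyro_derivative,
    joint_acceleration_inertial,
    joint_specific_force,
    motion_gate,
    robot_joint_accel,
    smooth_for_disagreement,
    update_heading,
)
from .orientation import run_orientation_filter
from .pose import X_AXIS, elbow_from_cuffs
from .quat import heading_quat, quat_multiply, rotate

__all__ = ["TrackResult", "track_streams", "track_trial"]

_EPS = 1e-9


@dataclass
class TrackResult:
    """Everything the tracker produced for one pair of streams.

    ``pose`` holds one row per IMU sample and method
    (hybrid/conventional) with columns ``t, qw, qx, qy, qz, elbow_deg,
    psx, psy, psz, valid, method``; ``heading_log`` one row per periodic
    update.  ``q_ia`` and ``delta`` expose the raw inertial orientation and
    the held heading offset (rad, NaN while undefined) for evaluation.
    """

    pose: pd.DataFrame
    heading_log: pd.DataFrame
    q_ia: np.ndarray
    delta: np.ndarray
    valid: np.ndarray
    converged_t: float | None
    heading_state: HeadingState = field(repr=False, default=None)


def _nearest_indices(t_ref: np.ndarray, t_query: np.ndarray) -> np.ndarray:
    """Index of the nearest ``t_ref`` timestamp for each query time."""
    idx = np.searchsorted(t_ref, t_query)
    idx = np.clip(idx, 1, len(t_ref) - 1)
    left = t_query - t_ref[idx - 1]
    right = t_ref[idx] - t_query
    return np.where(left <= right, idx - 1, idx)


def _interp_vec(t_out: np.ndarray, t_in: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Linear per-axis interpolation of a (n, 3) series onto new timestamps."""
    return np.stack([np.interp(t_out, t_in, v[:, j]) for j in range(v.shape[1])], axis=-1)


def _angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized ∠(u, v) in degrees via atan2(‖cross‖, dot)."""
    c = np.linalg.norm(np.cross(u, v), axis=-1)
    d = np.sum(u * v, axis=-1)
    return np.rad2deg(np.arctan2(c, d))


def track_streams(
    t_imu: np.ndarray,
    gyro: np.ndarray,
    acc: np.ndarray,
    t_robot: np.ndarray,
    p_e_robot: np.ndarray | None,
    geometry: GeometryConfig,
    p_s_nom: np.ndarray,
    cfg: RunConfig | None = None,
    p_w_cuff: np.ndarray | None = None,
    p_p_cuff: np.ndarray | None = None,
    method: str = "both",
) -> TrackResult:
    """Run the full hybrid tracker on a pair of measurement streams.

    Parameters
    ----------
    t_imu, gyro, acc
        IMU stream: timestamps (s), angular rates (rad/s) and specific
        forces (m/s²) in the segment frame A, uniformly sampled.
    t_robot, p_e_robot
        Robot stream timestamps and elbow positions (m, frame R).  When
        ``p_e_robot`` is None, the elbow is extrapolated from the two cuff
        positions.
    geometry, p_s_nom, cfg
        Segment geometry, nominal shoulder position, and method constants.
    p_w_cuff, p_p_cuff
        Optional forearm-cuff positions; they define the connected-segment
        axis for the elbow angle (NaN when absent).
    method
        "hybrid", "conventional" or "both".
    """
    cfg = cfg or RunConfig()
    t_imu = np.asarray(t_imu, dtype=float)
    t_robot = np.asarray(t_robot, dtype=float)
    for name, ts in (("IMU", t_imu), ("robot", t_robot)):
        if np.any(np.diff(ts) <= 0):
            raise ValueError(f"non-monotone timestamps in {name} stream")
    gyro = np.asarray(gyro, dtype=float)
    acc = np.asarray(acc, dtype=float)
    if p_e_robot is None:
        if p_w_cuff is None or p_p_cuff is None:
            raise ValueError("need either the elbow position or both cuff positions")
        p_e_robot = elbow_from_cuffs(p_w_cuff, p_p_cuff, geometry.l_p)
    p_e_robot = np.asarray(p_e_robot, dtype=float)
    p_s_nom = np.asarray(p_s_nom, dtype=float)

    fs_imu = 1.0 / float(np.median(np.diff(t_imu)))
    fs_robot = 1.0 / float(np.median(np.diff(t_robot)))

    # --- IMU route: orientation and joint acceleration in frame I ----------
    q_ia = run_orientation_filter(
        t_imu, gyro, acc, gain=cfg.orientation_gain, gravity=cfg.gravity
    )
    gyro_dot = gyro_derivative(
        t_imu, gyro, cutoff_hz=cfg.lp_cutoff_gyro, order=cfg.butterworth_order
    )
    sf_joint = joint_specific_force(acc, gyro, gyro_dot, geometry.p_imu_to_joint)
    a_e_i = joint_acceleration_inertial(sf_joint, q_ia, gravity=cfg.gravity)
    a_e_i_f = smooth_for_disagreement(
        a_e_i, fs_imu, cfg.lp_cutoff_accel, cfg.butterworth_order
    )

    # --- robot route: twice-differentiated joint position -------------------
    pdd_r = robot_joint_accel(t_robot, p_e_robot)
    pdd_r_f = smooth_for_disagreement(
        pdd_r, fs_robot, cfg.lp_cutoff_accel, cfg.butterworth_order
    )

    # time-align at the robot rate: nearest IMU sample per robot sample
    a_pairs = a_e_i_f[_nearest_indices(t_imu, t_robot)]

    # --- periodic heading updates ------------------------------------------
    state = HeadingState()
    log_rows = []
    converged_t = None
    delta_times: list[float] = []
    delta_values: list[float] = []
    t_update = t_robot[0] + cfg.window
    while t_update <= t_robot[-1] + _EPS:
        sel = (t_robot > t_update - cfg.window - _EPS) & (t_robot <= t_update + _EPS)
        t_win = t_robot[sel]
        gated = False
        if len(t_win) >= 2 and (t_win[-1] - t_win[0]) >= cfg.window - 2.0 / fs_robot:
            gated = motion_gate(
                t_win,
                p_e_robot[sel],
                window_s=t_win[-1] - t_win[0],
                n_subwindows=cfg.n_subwindows,
                sphere_diameter_m=cfg.motion_sphere,
                min_moving=cfg.min_moving_subwindows,
            )
        was_converged = state.converged
        update_heading(
            state,
            a_pairs[sel],
            pdd_r_f[sel],
            gated,
            t_update,
            coarse_step_deg=cfg.coarse_step_deg,
            refine_halfwidth_deg=cfg.refine_halfwidth_deg,
            refine_step_deg=cfg.refine_step_deg,
            convergence_len=cfg.convergence_len,
            convergence_tol_deg=cfg.convergence_tol_deg,
        )
        if state.converged and not was_converged:
            converged_t = t_update
        if gated and state.delta_hat is not None:
            delta_times.append(t_update)
            delta_values.append(state.delta_hat)
        log_rows.append(
            {
                "t": t_update,
                "delta_tilde_deg": np.nan
                if state.delta_tilde is None or not gated
                else np.rad2deg(state.delta_tilde),
                "delta_hat_deg": np.nan
                if state.delta_hat is None
                else np.rad2deg(state.delta_hat),
                "gated": gated,
                "converged": state.converged,
                "cost": np.nan
                if state.delta_hat is None or not np.any(sel)
                else cost(state.delta_hat, a_pairs[sel], pdd_r_f[sel]),
            }
        )
        t_update += cfg.update_period
    heading_log = pd.DataFrame(
        log_rows,
        columns=["t", "delta_tilde_deg", "delta_hat_deg", "gated", "converged", "cost"],
    )

    # --- per-sample heading hold and pose reconstruction --------------------
    n = len(t_imu)
    delta = np.full(n, np.nan)
    if delta_times:
        pos = np.searchsorted(np.asarray(delta_times), t_imu, side="right") - 1
        defined = pos >= 0
        delta[defined] = np.asarray(delta_values)[pos[defined]]
    valid = ~np.isnan(delta)
    converged_mask = (
        t_imu >= converged_t if converged_t is not None else np.zeros(n, dtype=bool)
    )

    p_e_i = _interp_vec(t_imu, t_robot, p_e_robot)
    if p_w_cuff is not None and p_p_cuff is not None:
        x_c_r = np.asarray(p_w_cuff, dtype=float) - np.asarray(p_p_cuff, dtype=float)
        x_c_r /= np.linalg.norm(x_c_r, axis=-1, keepdims=True)
        x_c = _interp_vec(t_imu, t_robot, x_c_r)
        x_c /= np.linalg.norm(x_c, axis=-1, keepdims=True)
    else:
        x_c = None

    frames = []
    if method in ("hybrid", "both"):
        q_ra = np.full((n, 4), np.nan)
        p_s = np.full((n, 3), np.nan)
        elbow = np.full(n, np.nan)
        if np.any(valid):
            q_ra[valid] = quat_multiply(heading_quat(delta[valid]), q_ia[valid])
            p_s[valid] = p_e_i[valid] - rotate(q_ra[valid], geometry.l_a * X_AXIS)
            if x_c is not None:
                x_a_r = rotate(q_ra[valid], X_AXIS)
                elbow[valid] = _angles_deg(x_c[valid], x_a_r)
        frames.append(
            pd.DataFrame(
                {
                    "t": t_imu,
                    "qw": q_ra[:, 0], "qx": q_ra[:, 1],
                    "qy": q_ra[:, 2], "qz": q_ra[:, 3],
                    "elbow_deg": elbow,
                    "psx": p_s[:, 0], "psy": p_s[:, 1], "psz": p_s[:, 2],
                    "valid": valid,
                    "converged": converged_mask,
                    "method": "hybrid",
                }
            )
        )
    if method in ("conventional", "both"):
        x_a_conv = p_e_i - p_s_nom
        norms = np.linalg.norm(x_a_conv, axis=-1, keepdims=True)
        if np.any(norms < 1e-9):
            raise ValueError("elbow coincides with the nominal shoulder position")
        x_a_conv = x_a_conv / norms
        elbow_conv = (
            _angles_deg(x_c, x_a_conv) if x_c is not None else np.full(n, np.nan)
        )
        frames.append(
            pd.DataFrame(
                {
                    "t": t_imu,
                    "qw": np.nan, "qx": np.nan, "qy": np.nan, "qz": np.nan,
                    "elbow_deg": elbow_conv,
                    "psx": p_s_nom[0], "psy": p_s_nom[1], "psz": p_s_nom[2],
                    "valid": True,
                    "converged": True,
                    "method": "conventional",
                }
            )
        )
    pose = pd.concat(frames, ignore_index=True)
    return TrackResult(
        pose=pose,
        heading_log=heading_log,
        q_ia=q_ia,
        delta=delta,
        valid=valid,
        converged_t=converged_t,
        heading_state=state,
    )


def track_trial(trial, cfg: RunConfig | None = None, method: str = "both") -> TrackResult:
    """Convenience wrapper: track a :class:`~armfusion.simulate.SyntheticTrial`."""
    geom = GeometryConfig(
        p_imu_to_joint=np.asarray(trial.config.p_imu_to_joint, dtype=float),
        l_a=trial.config.l_a,
        l_p=trial.config.l_p,
    )
    return track_streams(
        trial.imu.t,
        trial.imu.gyro,
        trial.imu.acc,
        trial.robot.t,
        trial.robot.p_e,
        geom,
        trial.p_s_nom,
        cfg=cfg,
        p_w_cuff=trial.robot.p_w,
        p_p_cuff=trial.robot.p_p,
        method=method,
    )
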
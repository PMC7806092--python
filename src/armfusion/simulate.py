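"""Synthetic two-segment arm motion and simulated measurement streams.

The generator emulates the desk-scale study conditions of a cable-based
upper-limb rehabilitation session: a seated subject whose right hand traces
a rectangular path (the outline of a box on a table) in counterclockwise
cycles, while the shoulder either stays near its nominal position (proper
movement, displacement amplitude ≈ 4 cm) or translates toward the hand with
a raised-cosine profile phase-locked to the cycle (compensatory movement,
amplitude ≈ 14 cm, emulating a trunk lean).  Cycle periods default to 4.6 s
(proper) and 5.4 s (compensatory).

From the ground-truth trajectories the generator produces the two
measurement streams the tracker consumes:

* a 100 Hz IMU stream — body-frame angular rate (plus a constant bias,
  default magnitude 0.34 deg/s, and white noise) and specific force at the
  sensor location on the upper arm (plus white noise);
* a 25 Hz robot stream — elbow position and the two forearm-cuff positions
  in the robot frame, each with additive white noise.

All motion lies in the horizontal plane through the shoulder, so the true
upper-arm orientation is a pure heading rotation; the elbow position is
solved by planar two-link inverse kinematics so the rigid-segment constraint
``‖p_S − p_E‖ = l_A`` holds exactly.  Generation is reproducible from the
seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .quat import heading_quat, quat_conj, quat_log, quat_multiply, rotate

__all__ = [
    "TrialConfig",
    "Truth",
    "ImuStream",
    "RobotStream",
    "SyntheticTrial",
    "generate_arm_motion",
    "simulate_imu",
    "simulate_robot",
    "simulate_trial",
]

#: Default gyroscope-bias direction (unit vector).  Vertical-dominant, so the
#: integrated heading drifts at ~0.9 × the bias magnitude (the phenomenon the
#: heading estimator must track), with a realistic horizontal component that
#: exercises the inclination correction.
_DEFAULT_BIAS_DIR = np.array([1.0, -1.0, 3.0]) / np.sqrt(11.0)


@dataclass
class TrialConfig:
    """Conditions of one simulated trial.

    Distances in meters, rates in Hz, angles in degrees, times in seconds.
    ``gyro_bias_deg_s`` may be a scalar magnitude (applied along the default
    vertical-dominant direction) or a full 3-vector in the body frame.
    """

    duration: float = 60.0
    cycle_period: float = 4.6
    shoulder_amp: float = 0.04
    rect_width: float = 0.40
    rect_depth: float = 0.24
    rect_center: tuple[float, float] = (0.0, 0.33)
    l_a: float = 0.30
    l_f: float = 0.28
    l_p: float = 0.08
    wrist_cuff_offset: float = 0.05
    p_imu_to_joint: tuple[float, float, float] = (0.15, 0.0, 0.0)
    p_s_nom: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_bias_deg_s: float | tuple[float, float, float] = 0.34
    gyro_noise_sd_deg_s: float = 0.5
    acc_noise_sd: float = 0.05
    robot_pos_noise_sd: float = 0.005
    soft_tissue_amp: float = 0.0
    imu_rate: float = 100.0
    robot_rate: float = 25.0
    path_smooth_cutoff_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imu_rate <= 0 or self.robot_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.shoulder_amp < 0:
            raise ValueError("shoulder_amp must be non-negative")
        if min(self.duration, self.cycle_period, self.l_a, self.l_f) <= 0:
            raise ValueError("duration, cycle_period and segment lengths must be positive")

    @property
    def bias_vector_rad(self) -> np.ndarray:
        """Gyroscope bias as a body-frame 3-vector in rad/s."""
        b = np.asarray(self.gyro_bias_deg_s, dtype=float)
        if b.ndim == 0:
            b = float(b) * _DEFAULT_BIAS_DIR
        return np.deg2rad(b)

    @classmethod
    def proper(cls, **kw) -> "TrialConfig":
        """Proper-movement conditions: 4 cm shoulder amplitude, 4.6 s cycles."""
        kw.setdefault("shoulder_amp", 0.04)
        kw.setdefault("cycle_period", 4.6)
        return cls(**kw)

    @classmethod
    def compensatory(cls, **kw) -> "TrialConfig":
        """Compensatory-movement conditions: 14 cm amplitude, 5.4 s cycles."""
        kw.setdefault("shoulder_amp", 0.14)
        kw.setdefault("cycle_period", 5.4)
        return cls(**kw)


@dataclass
class Truth:
    """Ground-truth trajectories sampled at the IMU rate.

    ``q_ra`` is the true upper-arm orientation in the robot frame R
    (scalar-first unit quaternions, shape (n, 4)); positions are meters in R.
    """

    t: np.ndarray
    p_s: np.ndarray
    p_e: np.ndarray
    p_w: np.ndarray
    q_ra: np.ndarray
    x_c: np.ndarray
    elbow_angle_deg: np.ndarray


@dataclass
class ImuStream:
    """Raw IMU measurements: body-frame rad/s and m/s² at ``t`` seconds."""

    t: np.ndarray
    gyro: np.ndarray
    acc: np.ndarray


@dataclass
class RobotStream:
    """Robot-frame position measurements: elbow and the two forearm cuffs."""

    t: np.ndarray
    p_e: np.ndarray
    p_w: np.ndarray | None = None
    p_p: np.ndarray | None = None


@dataclass
class SyntheticTrial:
    """One simulated trial: truth, measurements and cycle segmentation."""

    config: TrialConfig
    truth: Truth
    imu: ImuStream
    robot: RobotStream
    cycle_boundaries: np.ndarray
    p_s_nom: np.ndarray

    def true_cycle_labels(
        self, threshold_m: float = 0.10, fraction_limit: float = 0.20
    ) -> list[str]:
        """Ground-truth label per cycle, from the rule applied to true motion."""
        from .detect import MotionCycle, classify_cycle

        labels = []
        for t0, t1 in zip(self.cycle_boundaries[:-1], self.cycle_boundaries[1:]):
            sel = (self.truth.t >= t0 - 1e-9) & (self.truth.t <= t1 + 1e-9)
            cyc = MotionCycle(
                t_start=t0,
                t_end=t1,
                t=self.truth.t[sel],
                p_s=self.truth.p_s[sel],
                p_s_nom=self.p_s_nom,
            )
            labels.append(classify_cycle(cyc, threshold_m, fraction_limit).label)
        return labels


# --------------------------------------------------------------------------
# ground-truth kinematics
# --------------------------------------------------------------------------

def _rect_path(u: np.ndarray, width: float, depth: float) -> np.ndarray:
    """Point on a centered rectangle at perimeter fraction ``u`` ∈ [0, 1).

    Counterclockwise, starting at the right-front corner ``(w/2, −d/2)``.
    Constant speed in ``u``.
    """
    w, h = 0.5 * width, 0.5 * depth
    per = 2.0 * width + 2.0 * depth
    s = np.mod(u, 1.0) * per
    breaks = np.array([0.0, 2 * h, 2 * h + 2 * w, 4 * h + 2 * w, per])
    xs = np.array([w, w, -w, -w, w])
    ys = np.array([-h, h, h, -h, -h])
    return np.stack([np.interp(s, breaks, xs), np.interp(s, breaks, ys)], axis=-1)


def _smooth_periodic(
    t_ext: np.ndarray, x_ext: np.ndarray, fs: float, cutoff_hz: float, n_crop: tuple[int, int]
) -> np.ndarray:
    """Zero-phase low-pass on a padded signal, cropped back to the trial span.

    Zero-phase (forward-backward) filtering keeps the smoothed trajectory
    phase-locked to the cycle boundaries; the pad absorbs edge transients.
    """
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x_ext, axis=0)
    lo, hi = n_crop
    return y[lo : len(y) - hi]


def generate_arm_motion(cfg: TrialConfig) -> Truth:
    """Ground-truth trajectories of shoulder, elbow, wrist and upper arm.

    The wrist traces a low-pass-smoothed (twice-differentiable) rectangle;
    the shoulder translates horizontally toward the instantaneous hand
    position with a raised-cosine displacement profile peaking at
    ``shoulder_amp``; the elbow follows from planar two-link inverse
    kinematics (elbow-right branch, as for a right arm).  Raises when the
    path leaves the reachable workspace.
    """
    fs = cfg.imu_rate
    n = int(round(cfg.duration * fs)) + 1
    pad = int(round(cfg.cycle_period * fs)) + 1
    k = np.arange(-pad, n + pad)
    t_ext = k / fs
    u = t_ext / cfg.cycle_period

    nom = np.asarray(cfg.p_s_nom, dtype=float)
    cx, cy = cfg.rect_center
    wrist_raw = _rect_path(u, cfg.rect_width, cfg.rect_depth) + np.array(
        [cx + nom[0], cy + nom[1]]
    )
    wrist_xy = _smooth_periodic(t_ext, wrist_raw, fs, cfg.path_smooth_cutoff_hz, (pad, pad))

    # shoulder displacement: raised cosine toward the (raw) hand direction
    to_hand = wrist_raw - nom[:2]
    u_dir_raw = to_hand / np.linalg.norm(to_hand, axis=-1, keepdims=True)
    u_dir = _smooth_periodic(t_ext, u_dir_raw, fs, cfg.path_smooth_cutoff_hz, (pad, pad))
    u_dir /= np.linalg.norm(u_dir, axis=-1, keepdims=True)
    t = k[pad : pad + n] / fs
    disp = 0.5 * cfg.shoulder_amp * (1.0 - np.cos(2.0 * np.pi * t / cfg.cycle_period))
    shoulder_xy = nom[:2] + disp[:, None] * u_dir

    # planar two-link inverse kinematics (elbow-right branch)
    rel = wrist_xy - shoulder_xy
    d = np.linalg.norm(rel, axis=-1)
    span = cfg.l_a + cfg.l_f
    if np.any(d > 0.98 * span) or np.any(d < abs(cfg.l_a - cfg.l_f) + 0.02):
        raise ValueError(
            "hand path unreachable: wrist–shoulder distance "
            f"[{d.min():.3f}, {d.max():.3f}] m outside the workspace of a "
            f"{cfg.l_a:.2f} + {cfg.l_f:.2f} m arm"
        )
    cos_g = (cfg.l_a**2 + d**2 - cfg.l_f**2) / (2.0 * cfg.l_a * d)
    gamma = np.arccos(np.clip(cos_g, -1.0, 1.0))
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    phi = theta - gamma  # heading of the upper arm (shoulder → elbow)
    elbow_xy = shoulder_xy + cfg.l_a * np.stack([np.cos(phi), np.sin(phi)], axis=-1)

    z = np.zeros((n, 1))
    p_s = np.concatenate([shoulder_xy, nom[2] + z], axis=1)
    p_e = np.concatenate([elbow_xy, nom[2] + z], axis=1)
    p_w = np.concatenate([wrist_xy, nom[2] + z], axis=1)
    q_ra = heading_quat(phi)
    x_c = (p_w - p_e) / np.linalg.norm(p_w - p_e, axis=-1, keepdims=True)
    x_a = (p_e - p_s) / cfg.l_a
    dot = np.clip(np.sum(x_c * x_a, axis=-1), -1.0, 1.0)
    crs = np.linalg.norm(np.cross(x_a, x_c), axis=-1)
    elbow_deg = np.rad2deg(np.arctan2(crs, dot))
    return Truth(t=t, p_s=p_s, p_e=p_e, p_w=p_w, q_ra=q_ra, x_c=x_c,
                 elbow_angle_deg=elbow_deg)


# --------------------------------------------------------------------------
# measurement simulation
# --------------------------------------------------------------------------

def _body_rates_from_quats(q: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity by central differences of the log map."""
    n = len(q)
    omega = np.empty((n, 3))
    rel = quat_multiply(quat_conj(q[:-2]), q[2:])
    omega[1:-1] = quat_log(rel) / (2.0 * dt)
    rel0 = quat_multiply(quat_conj(q[0]), q[1])
    reln = quat_multiply(quat_conj(q[-2]), q[-1])
    omega[0] = quat_log(rel0) / dt
    omega[-1] = quat_log(reln) / dt
    return omega


def simulate_imu(truth: Truth, cfg: TrialConfig, rng: np.random.Generator) -> ImuStream:
    """Corrupt the ground truth into a body-frame IMU stream at ``imu_rate``.

    The gyroscope reads the body-frame angular velocity plus a constant bias
    and white noise; the accelerometer reads the specific force at the
    sensor point (15 cm proximal of the elbow by default) plus white noise.
    Optional soft-tissue artifact adds low-frequency (≤ 1 Hz) jitter to the
    sensor position before differentiation.
    """
    dt = 1.0 / cfg.imu_rate
    ape = np.asarray(cfg.p_imu_to_joint, dtype=float)
    p_imu = truth.p_e - rotate(truth.q_ra, ape)
    if cfg.soft_tissue_amp > 0:
        jitter = rng.standard_normal(p_imu.shape)
        sos = signal.butter(2, 1.0, btype="low", fs=cfg.imu_rate, output="sos")
        jitter = signal.sosfiltfilt(sos, jitter, axis=0)
        rms = np.sqrt(np.mean(jitter**2))
        p_imu = p_imu + cfg.soft_tissue_amp / max(rms, 1e-12) * jitter

    acc_world = np.gradient(np.gradient(p_imu, dt, axis=0), dt, axis=0)
    acc_world[:, 2] += 9.81
    acc_body = rotate(quat_conj(truth.q_ra), acc_world)
    gyro_body = _body_rates_from_quats(truth.q_ra, dt)

    gyro = (
        gyro_body
        + cfg.bias_vector_rad
        + np.deg2rad(cfg.gyro_noise_sd_deg_s) * rng.standard_normal(gyro_body.shape)
    )
    acc = acc_body + cfg.acc_noise_sd * rng.standard_normal(acc_body.shape)
    return ImuStream(t=truth.t.copy(), gyro=gyro, acc=acc)


def simulate_robot(truth: Truth, cfg: TrialConfig, rng: np.random.Generator) -> RobotStream:
    """Downsample the truth to the robot rate and add measurement noise.

    Emits the elbow position and both forearm-cuff positions; the cuffs lie
    on the forearm line so the elbow-from-cuffs extrapolation reproduces the
    true elbow exactly in the noise-free case.
    """
    step = cfg.imu_rate / cfg.robot_rate
    n_r = int(np.floor((len(truth.t) - 1) / step)) + 1
    idx = np.round(np.arange(n_r) * step).astype(int)
    t_r = truth.t[idx]
    f = truth.x_c[idx]  # forearm axis elbow → wrist
    p_e = truth.p_e[idx]
    p_p = p_e + cfg.l_p * f
    p_w = p_e + (cfg.l_f - cfg.wrist_cuff_offset) * f
    noise = lambda shape: cfg.robot_pos_noise_sd * rng.standard_normal(shape)
    return RobotStream(
        t=t_r,
        p_e=p_e + noise(p_e.shape),
        p_w=p_w + noise(p_w.shape),
        p_p=p_p + noise(p_p.shape),
    )


def simulate_trial(cfg: TrialConfig) -> SyntheticTrial:
    """Generate a complete reproducible trial from one configuration."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_imu, rng_robot = (np.random.default_rng(s) for s in ss.spawn(2))
    truth = generate_arm_motion(cfg)
    imu = simulate_imu(truth, cfg, rng_imu)
    robot = simulate_robot(truth, cfg, rng_robot)
    n_cycles = int(np.floor(cfg.duration / cfg.cycle_period + 1e-9))
    boundaries = np.arange(n_cycles + 1) * cfg.cycle_period
    return SyntheticTrial(
        config=cfg,
        truth=truth,
        imu=imu,
        robot=robot,
        cycle_boundaries=boundaries,
        p_s_nom=np.asarray(cfg.p_s_nom, dtype=float),
    )
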
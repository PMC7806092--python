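"""Robot-frame pose reconstruction from orientation and heading offset.

Once the heading offset δ̂ between the inertial frame I and the robot
workspace frame R is available, the segment orientation, the inter-segment
joint angle and the position of the segment's free endpoint (the shoulder)
follow by elementary kinematics:

* ``q_RA = Rz(δ̂) ⊗ q_IA`` — segment orientation in R;
* elbow angle = angle between the connected segment's longitudinal axis
  ``x_C`` and the adjacent segment's axis ``x_A`` expressed in R;
* ``p_S = p_E − q_RA ⊗ (l_A x̂) ⊗ q_RA*`` — the shoulder sits one segment
  length behind the elbow along the segment axis.

The *conventional* baseline used by non-augmented end-effector robots is
also provided: it assumes the shoulder never leaves its nominal position and
derives the upper-arm axis from the elbow position alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quat import (
    angle_between,
    heading_quat,
    normalize_vec,
    quat_multiply,
    rotate,
)

__all__ = [
    "PoseEstimate",
    "X_AXIS",
    "elbow_from_cuffs",
    "segment_orientation_R",
    "elbow_angle",
    "shoulder_position",
    "conventional_pose",
]

#: Longitudinal axis of the adjacent segment in its own frame A: the x-axis
#: points along the segment toward the joint (elbow).
X_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass
class PoseEstimate:
    """One reconstructed pose sample.

    ``q_ra`` is the robot-frame segment orientation (scalar-first unit
    quaternion), ``elbow_angle_deg`` the inter-segment angle in degrees in
    [0°, 180°], ``p_s`` the shoulder position in meters in frame R, and
    ``valid`` is False whenever the heading offset was still undefined.
    """

    t: float
    q_ra: np.ndarray | None
    elbow_angle_deg: float
    p_s: np.ndarray | None
    valid: bool
    method: str = "hybrid"


def elbow_from_cuffs(p_w: np.ndarray, p_p: np.ndarray, l_p: float) -> np.ndarray:
    """Extrapolate the forearm-cuff line to the elbow.

    ``p_E = l_p · normalize(p_P − p_W) + p_P`` with ``p_W`` the wrist cuff,
    ``p_P`` the proximal cuff and ``l_p`` the proximal-cuff-to-elbow
    distance.  Batched over leading axes.  Coincident cuffs are degenerate.
    """
    p_w = np.asarray(p_w, dtype=float)
    p_p = np.asarray(p_p, dtype=float)
    return float(l_p) * normalize_vec(p_p - p_w) + p_p


def segment_orientation_R(q_ia: np.ndarray, delta_hat: float) -> np.ndarray:
    """Segment orientation in the robot frame: ``q_RA = Rz(δ̂) ⊗ q_IA``."""
    if delta_hat is None:
        raise ValueError("heading offset undefined — pose unavailable")
    return quat_multiply(heading_quat(delta_hat), np.asarray(q_ia, dtype=float))


def elbow_angle(x_c: np.ndarray, q_ra: np.ndarray) -> float:
    """Inter-segment angle in degrees: ``∠(x_C, q_RA ⊗ x_A ⊗ q_RA*)``.

    Computed via atan2(‖cross‖, dot) for numerical safety near 0° and 180°.
    """
    x_a_in_r = rotate(np.asarray(q_ra, dtype=float), X_AXIS)
    return float(np.rad2deg(angle_between(np.asarray(x_c, dtype=float), x_a_in_r)))


def shoulder_position(p_e: np.ndarray, q_ra: np.ndarray, l_a: float) -> np.ndarray:
    """Free-endpoint (shoulder) position: ``p_S = p_E − q_RA ⊗ (l_A x̂) ⊗ q_RA*``.

    Batched when ``p_e`` and ``q_ra`` carry matching leading axes.
    """
    if l_a <= 0:
        raise ValueError("segment length l_a must be positive")
    p_e = np.asarray(p_e, dtype=float)
    return p_e - rotate(np.asarray(q_ra, dtype=float), float(l_a) * X_AXIS)


def conventional_pose(
    t: float, p_e: np.ndarray, p_s_nom: np.ndarray, x_c: np.ndarray
) -> PoseEstimate:
    """Fixed-shoulder baseline of non-augmented end-effector robots.

    The shoulder is assumed pinned at its nominal position; the upper-arm
    axis is the normalized vector from that nominal shoulder to the measured
    elbow.  By construction the reported shoulder position carries the full
    actual shoulder displacement as error.
    """
    p_e = np.asarray(p_e, dtype=float)
    p_s_nom = np.asarray(p_s_nom, dtype=float)
    x_a = normalize_vec(p_e - p_s_nom)  # raises on degenerate geometry
    ang = float(np.rad2deg(angle_between(np.asarray(x_c, dtype=float), x_a)))
    return PoseEstimate(
        t=float(t),
        q_ra=None,
        elbow_angle_deg=ang,
        p_s=p_s_nom.copy(),
        valid=True,
        method="conventional",
    )
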
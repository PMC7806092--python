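"""Quaternion and vector kinematics primitives.

Conventions
-----------
Quaternions are stored scalar-first ``(w, x, y, z)`` as plain numpy arrays of
shape ``(4,)`` (or ``(n, 4)`` for batches) and follow the Hamilton product
convention: a vector ``v`` is rotated by ``q ⊗ v ⊗ q*`` with ``v`` treated as
the pure quaternion ``(0, v)``.  Coordinate frames are right-handed with the
z-axis pointing straight up; the heading of an orientation is its rotation
about that vertical axis.

Angles are radians everywhere inside the library; degrees appear only at user
interfaces (configuration, CSV output, command line).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_multiply",
    "quat_conj",
    "quat_normalize",
    "quat_canonical",
    "rotate",
    "heading_quat",
    "heading_angle",
    "quat_from_axis_angle",
    "quat_log",
    "cross_matrix",
    "normalize_vec",
    "wrap_angle",
    "angle_between",
    "IDENTITY",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

_UNIT_TOL = 1e-6


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``.

    Supports broadcasting over leading axes; the last axis must have length 4.
    ``norm(a ⊗ b) = norm(a) · norm(b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    """Conjugate ``q* = (w, -x, -y, -z)`` (inverse for unit quaternions)."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Scale to unit norm.  Raises on a (near-)zero quaternion."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Resolve the double cover: flip sign so the scalar part is >= 0."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q``: ``q ⊗ v ⊗ q*``.

    Broadcasts over leading axes.  ``q`` must be unit within 1e-6.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > _UNIT_TOL):
        raise ValueError("rotate() requires unit quaternions")
    w = q[..., 0]
    u = q[..., 1:]
    # q v q* expanded: v + 2 w (u × v) + 2 u × (u × v)
    uv = np.cross(u, v)
    return v + 2.0 * (w[..., None] * uv + np.cross(u, uv))


def heading_quat(delta: float | np.ndarray) -> np.ndarray:
    """Unit quaternion rotating about the vertical z-axis by ``delta`` rad.

    ``[cos(δ/2), 0, 0, sin(δ/2)]``; accepts scalars or arrays (batched on the
    leading axis).
    """
    delta = np.asarray(delta, dtype=float)
    half = 0.5 * delta
    zeros = np.zeros_like(half)
    return np.stack([np.cos(half), zeros, zeros, np.sin(half)], axis=-1)


def heading_angle(q: np.ndarray) -> np.ndarray:
    """Heading (rotation about vertical z) of a unit quaternion, in rad.

    Defined as the angle by which the rotated x-axis is turned in the
    horizontal plane: ``atan2`` of the x-column of the rotation matrix.
    Undefined (returns whatever atan2 gives on a near-zero argument) when the
    body x-axis points straight up or down.
    """
    q = np.asarray(q, dtype=float)
    w, x, y, z = np.moveaxis(q, -1, 0)
    # first column of the rotation matrix = rotate(q, [1,0,0])
    r00 = 1.0 - 2.0 * (y * y + z * z)
    r10 = 2.0 * (x * y + w * z)
    return np.arctan2(r10, r00)


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` rad about unit ``axis``."""
    axis = np.asarray(axis, dtype=float)
    half = 0.5 * float(angle)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_log(q: np.ndarray) -> np.ndarray:
    """Logarithm map: rotation vector (axis · angle, rad) of a unit quaternion.

    The sign ambiguity is resolved toward the short rotation (angle <= pi).
    """
    q = quat_canonical(np.asarray(q, dtype=float))
    w = np.clip(q[..., 0], -1.0, 1.0)
    vec = q[..., 1:]
    s = np.linalg.norm(vec, axis=-1)
    angle = 2.0 * np.arctan2(s, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(s > 1e-12, angle / np.where(s > 1e-12, s, 1.0), 2.0)
    return vec * scale[..., None]


def cross_matrix(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix ``[v]×`` with ``[v]× b = v × b``."""
    x, y, z = np.asarray(v, dtype=float)
    return np.array(
        [
            [0.0, -z, y],
            [z, 0.0, -x],
            [-y, x, 0.0],
        ]
    )


def normalize_vec(v: np.ndarray) -> np.ndarray:
    """Map ``v`` to the unit vector with the same direction.

    Raises ``ValueError`` on a (near-)zero vector — degenerate geometry must
    be surfaced, not silently absorbed.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero vector (degenerate geometry)")
    return v / n


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) in radians to the half-open interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    if out.ndim == 0:
        return float(out)
    return out


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in [0, pi], via atan2(‖u×v‖, u·v).

    Numerically safe near 0 and pi, unlike the arccos of the normalized dot
    product.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = np.cross(u, v)
    return float(np.arctan2(np.linalg.norm(c, axis=-1), np.sum(u * v, axis=-1)))
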
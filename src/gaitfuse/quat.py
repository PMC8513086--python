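"""Quaternion, Euler-angle and rotation-matrix algebra.

Conventions
-----------
* Quaternions are scalar-first ``(w, x, y, z)`` numpy arrays; orientation
  quaternions carry unit norm.  Arrays of shape ``(4,)`` or ``(N, 4)`` are
  accepted everywhere; operations broadcast over the leading axis.
* Euler angles are intrinsic Tait-Bryan ZYX (yaw-pitch-roll), radians,
  returned in ``(roll, pitch, yaw)`` order.  Pitch is the arcsine branch
  and therefore confined to ``[-pi/2, pi/2]``.
* Rotation matrices rotate body-frame vectors into the world frame:
  ``v_world = R(q) @ v_body``.

The two-quadrant constraint (:func:`quadrant_constrain`) takes component-wise
absolute values, collapsing the quaternion sign ambiguities introduced by the
arcsine pitch branch so that a quaternion -> Euler -> quaternion round trip
becomes loss-free for comparison purposes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_multiply",
    "quat_conjugate",
    "quat_norm",
    "quat_normalize",
    "rotate_vector",
    "quat_to_euler",
    "euler_to_quat",
    "quat_to_rotmat",
    "rotmat_to_quat",
    "euler_to_rotmat",
    "rotmat_to_euler",
    "quadrant_constrain",
    "gyro_rate_quaternion",
    "geodesic_angle",
    "random_unit_quaternion",
]

_UNIT_TOL = 1e-6


def _as_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion must have 4 components, got shape {q.shape}")
    return q


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (scalar-first, broadcasting)."""
    a, b = _as_quat(a), _as_quat(b)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_conjugate(q) -> np.ndarray:
    """Conjugate ``q*``: vector part negated.  Inverse for unit quaternions."""
    q = _as_quat(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_norm(q) -> np.ndarray:
    return np.linalg.norm(_as_quat(q), axis=-1)


def quat_normalize(q) -> np.ndarray:
    """Scale to unit norm.  Raises on a zero quaternion."""
    q = _as_quat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def _require_unit(q: np.ndarray) -> None:
    err = np.abs(np.linalg.norm(q, axis=-1) - 1.0)
    if np.any(err > _UNIT_TOL):
        raise ValueError(f"quaternion is not unit norm (max |norm-1| = {err.max():.3g})")


def rotate_vector(q, v) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q``: vec(q ⊗ (0,v) ⊗ q*)."""
    q = _as_quat(q)
    _require_unit(q)
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("v must have 3 components")
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return quat_multiply(quat_multiply(q, qv), quat_conjugate(q))[..., 1:]


def quat_to_euler(q, degrees: bool = False) -> np.ndarray:
    """Unit quaternion -> intrinsic ZYX Euler angles ``(roll, pitch, yaw)``.

    The pitch term is an arcsine, so pitch stays in ``[-pi/2, pi/2]``; the
    arcsine argument is clipped to ``[-1, 1]`` to absorb round-off near
    gimbal lock.
    """
    q = _as_quat(q)
    _require_unit(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    roll = np.arctan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    pitch = np.arcsin(np.clip(2.0 * (w * y - x * z), -1.0, 1.0))
    yaw = np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    e = np.stack([roll, pitch, yaw], axis=-1)
    return np.degrees(e) if degrees else e


def euler_to_quat(euler, degrees: bool = False) -> np.ndarray:
    """ZYX Euler angles ``(roll, pitch, yaw)`` -> unit quaternion."""
    e = np.asarray(euler, dtype=float)
    if e.shape[-1] != 3:
        raise ValueError("euler must have 3 components (roll, pitch, yaw)")
    if degrees:
        e = np.radians(e)
    roll, pitch, yaw = np.moveaxis(e / 2.0, -1, 0)
    cr, sr = np.cos(roll), np.sin(roll)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(yaw), np.sin(yaw)
    return np.stack(
        [
            cy * cp * cr + sy * sp * sr,
            cy * cp * sr - sy * sp * cr,
            cy * sp * cr + sy * cp * sr,
            sy * cp * cr - cy * sp * sr,
        ],
        axis=-1,
    )


def quat_to_rotmat(q) -> np.ndarray:
    """Unit quaternion -> 3x3 rotation matrix (body -> world)."""
    q = _as_quat(q)
    _require_unit(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    m = np.stack(
        [
            1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y),
            2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x),
            2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y),
        ],
        axis=-1,
    )
    return m.reshape(q.shape[:-1] + (3, 3))


def _require_rotmat(m: np.ndarray) -> None:
    eye = np.broadcast_to(np.eye(3), m.shape)
    if not np.allclose(np.swapaxes(m, -1, -2) @ m, eye, atol=1e-6):
        raise ValueError("matrix is not orthonormal")
    if not np.allclose(np.linalg.det(m), 1.0, atol=1e-6):
        raise ValueError("matrix determinant is not +1 (improper rotation)")


def rotmat_to_quat(m) -> np.ndarray:
    """Orthonormal rotation matrix -> unit quaternion (Shepperd's method).

    Returns one representative of the ``±q`` pair (non-negative scalar part).
    """
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    _require_rotmat(m)
    single = m.ndim == 2
    m = m.reshape((-1, 3, 3))
    out = np.empty((m.shape[0], 4))
    for i, r in enumerate(m):
        tr = np.trace(r)
        # pick the largest diagonal pivot for numerical stability
        choices = np.array([tr, r[0, 0], r[1, 1], r[2, 2]])
        case = int(np.argmax(choices))
        if case == 0:
            s = 2.0 * np.sqrt(1.0 + tr)
            q = np.array(
                [0.25 * s, (r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s]
            )
        elif case == 1:
            s = 2.0 * np.sqrt(1.0 + r[0, 0] - r[1, 1] - r[2, 2])
            q = np.array(
                [(r[2, 1] - r[1, 2]) / s, 0.25 * s, (r[0, 1] + r[1, 0]) / s, (r[0, 2] + r[2, 0]) / s]
            )
        elif case == 2:
            s = 2.0 * np.sqrt(1.0 - r[0, 0] + r[1, 1] - r[2, 2])
            q = np.array(
                [(r[0, 2] - r[2, 0]) / s, (r[0, 1] + r[1, 0]) / s, 0.25 * s, (r[1, 2] + r[2, 1]) / s]
            )
        else:
            s = 2.0 * np.sqrt(1.0 - r[0, 0] - r[1, 1] + r[2, 2])
            q = np.array(
                [(r[1, 0] - r[0, 1]) / s, (r[0, 2] + r[2, 0]) / s, (r[1, 2] + r[2, 1]) / s, 0.25 * s]
            )
        if q[0] < 0:
            q = -q
        out[i] = q / np.linalg.norm(q)
    return out[0] if single else out


def euler_to_rotmat(euler, degrees: bool = False) -> np.ndarray:
    return quat_to_rotmat(euler_to_quat(euler, degrees=degrees))


def rotmat_to_euler(m, degrees: bool = False) -> np.ndarray:
    return quat_to_euler(rotmat_to_quat(m), degrees=degrees)


def quadrant_constrain(q, vector_only: bool = False) -> np.ndarray:
    """Two-quadrant constraint: component-wise absolute value.

    With ``vector_only=True`` only the (x, y, z) components are rectified and
    the scalar part is left untouched.  Idempotent in either mode.
    """
    q = _as_quat(q)
    out = np.abs(q)
    if vector_only:
        out = np.concatenate([q[..., :1], out[..., 1:]], axis=-1)
    return out


def gyro_rate_quaternion(q, omega) -> np.ndarray:
    """Quaternion derivative from body angular rate: ``q̇ = ½ q ⊗ (0, ω)``.

    ``omega`` is in rad/s, body frame.
    """
    q = _as_quat(q)
    omega = np.asarray(omega, dtype=float)
    if omega.shape[-1] != 3:
        raise ValueError("omega must have 3 components")
    oq = np.concatenate([np.zeros(omega.shape[:-1] + (1,)), omega], axis=-1)
    return 0.5 * quat_multiply(q, oq)


def geodesic_angle(a, b, degrees: bool = False) -> np.ndarray:
    """Smallest rotation angle between two unit quaternions (double-cover aware)."""
    a, b = _as_quat(a), _as_quat(b)
    dot = np.abs(np.sum(a * b, axis=-1))
    ang = 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))
    return np.degrees(ang) if degrees else ang


def random_unit_quaternion(n: int | None = None, rng=None) -> np.ndarray:
    """Uniformly random unit quaternion(s) (normalized Gaussian sampling)."""
    rng = np.random.default_rng(rng)
    q = rng.standard_normal((4,) if n is None else (n, 4))
    return quat_normalize(q)
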
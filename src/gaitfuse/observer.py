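"""Orientation from one accelerometer + magnetometer sample pair.

The observer estimates the unit quaternion ``q`` (body -> world) that best
explains a normalized accelerometer reading ``a`` (assumed to measure gravity
only) and a normalized magnetometer reading ``m``.  It minimizes the stacked
residual

    f(q) = [ R(q)^T g_ref - a ;  R(q)^T b - m ]

where ``g_ref = (0, 0, 1)`` is the world gravity direction and ``b = (bx, 0,
bz)`` is the world magnetic reference recomputed per sample from the current
estimate (declination-free horizontal component plus dip).  Two minimizers
are provided: fixed-step Gradient Descent and a ridge-stabilized
Gauss-Newton.  With ``m=None`` the observer runs gravity-only; yaw is then
unobservable and stays at the seed's yaw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .quat import quat_normalize, rotate_vector

__all__ = [
    "ObserverConfig",
    "magnetic_reference",
    "residual_and_jacobian",
    "gd_orientation",
    "gn_orientation",
    "estimate_orientation",
]


@dataclass
class ObserverConfig:
    """Settings for the single-sample orientation optimizers.

    step_size applies to gradient descent only; the Gauss-Newton step is
    scale-free.  ridge is the Levenberg term added to J^T J, needed because
    the normal matrix is rank-deficient at an exact solution (unit-norm
    direction is unconstrained by the residual).
    """

    method: Literal["gradient_descent", "gauss_newton"] = "gauss_newton"
    step_size: float = 0.01
    max_iterations: int | None = None  # 500 for GD, 20 for GN
    tolerance: float = 1e-6
    ridge: float = 1e-8

    def __post_init__(self):
        if self.max_iterations is None:
            self.max_iterations = 500 if self.method == "gradient_descent" else 20
        if self.step_size < 0:
            raise ValueError("step_size must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError(f"{name} has zero norm")
    return v / n


def magnetic_reference(q, m) -> np.ndarray:
    """World magnetic reference ``(bx, 0, bz)`` from body reading ``m``.

    Rotates ``m`` into the world frame with the current estimate and folds
    the horizontal component onto the x axis, eliminating sensitivity to
    local declination.  Norm of ``m`` is preserved.
    """
    m = _unit(m, "magnetometer reading")
    h = rotate_vector(q, m)
    return np.array([np.hypot(h[0], h[1]), 0.0, h[2]])


def residual_and_jacobian(q, a, m=None, b=None):
    """Stacked gravity/magnetic residual ``f`` and its Jacobian ``df/dq``.

    Returns ``(f, J)`` with shapes (6,), (6, 4) — or (3,), (3, 4) in
    gravity-only mode (``m`` is None).  ``b`` defaults to
    :func:`magnetic_reference` of ``(q, m)``.
    """
    q = np.asarray(q, dtype=float)
    w, x, y, z = q
    a = _unit(a, "accelerometer reading")

    # body-frame prediction of world gravity (0,0,1)
    fg = np.array(
        [
            2.0 * (x * z - w * y) - a[0],
            2.0 * (w * x + y * z) - a[1],
            1.0 - 2.0 * (x * x + y * y) - a[2],
        ]
    )
    Jg = np.array(
        [
            [-2 * y, 2 * z, -2 * w, 2 * x],
            [2 * x, 2 * w, 2 * z, 2 * y],
            [0.0, -4 * x, -4 * y, 0.0],
        ]
    )
    if m is None:
        return fg, Jg

    m = _unit(m, "magnetometer reading")
    if b is None:
        b = magnetic_reference(q, m)
    bx, bz = b[0], b[2]
    fb = np.array(
        [
            bx * (1.0 - 2.0 * (y * y + z * z)) + 2.0 * bz * (x * z - w * y) - m[0],
            2.0 * bx * (x * y - w * z) + 2.0 * bz * (w * x + y * z) - m[1],
            2.0 * bx * (w * y + x * z) + bz * (1.0 - 2.0 * (x * x + y * y)) - m[2],
        ]
    )
    Jb = np.array(
        [
            [-2 * bz * y, 2 * bz * z, -4 * bx * y - 2 * bz * w, -4 * bx * z + 2 * bz * x],
            [-2 * bx * z + 2 * bz * x, 2 * bx * y + 2 * bz * w, 2 * bx * x + 2 * bz * z, -2 * bx * w + 2 * bz * y],
            [2 * bx * y, 2 * bx * z - 4 * bz * x, 2 * bx * w - 4 * bz * y, 2 * bx * x],
        ]
    )
    return np.concatenate([fg, fb]), np.vstack([Jg, Jb])


def gd_orientation(a, m, q0, cfg: ObserverConfig | None = None) -> np.ndarray:
    """Gradient-descent minimization of the alignment residual.

    Iterates ``q <- normalize(q - mu * J^T f)`` until the gradient norm falls
    below ``cfg.tolerance`` or ``cfg.max_iterations`` is reached.
    """
    cfg = cfg or ObserverConfig(method="gradient_descent")
    q = quat_normalize(np.asarray(q0, dtype=float))
    for _ in range(cfg.max_iterations):
        f, J = residual_and_jacobian(q, a, m)
        grad = J.T @ f
        gn = np.linalg.norm(grad)
        if gn < cfg.tolerance:
            break
        q = quat_normalize(q - cfg.step_size * grad)
    return q


def gn_orientation(a, m, q0, cfg: ObserverConfig | None = None) -> np.ndarray:
    """Gauss-Newton minimization on the unit-quaternion sphere.

    Iterates ``q <- normalize(q - step)`` where the step solves the ridge
    normal equations ``(A^T A + (ridge + λ) I) s = P J^T f`` restricted to
    the tangent space of the sphere (``P = I - q q^T``, ``A = J P``).  The
    restriction matters: the raw 4-space Gauss-Newton step is dominated by
    its radial component, which renormalization cancels, stalling the
    descent.  λ is a Levenberg-Marquardt damping term adapted each
    iteration (a step must not increase the residual against the current
    magnetic reference to be accepted); the constant ridge covers the rank
    deficiency of the tangent normal matrix.  Converges quadratically near
    the minimum, typically in a handful of iterations.
    """
    cfg = cfg or ObserverConfig(method="gauss_newton")
    q = quat_normalize(np.asarray(q0, dtype=float))
    eye = np.eye(4)
    lam = 1e-4
    for _ in range(cfg.max_iterations):
        b = magnetic_reference(q, m) if m is not None else None
        f, J = residual_and_jacobian(q, a, m, b)
        grad = J.T @ f
        if np.linalg.norm(grad) < cfg.tolerance:
            break
        P = eye - np.outer(q, q)
        A = J @ P
        f_norm = np.linalg.norm(f)
        accepted = False
        for _ in range(30):
            H = A.T @ A + (cfg.ridge + lam) * eye
            try:
                step = P @ np.linalg.solve(H, P @ grad)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
                raise np.linalg.LinAlgError(
                    "singular Gauss-Newton normal matrix; increase ObserverConfig.ridge"
                ) from exc
            q_new = quat_normalize(q - step)
            f_new, _ = residual_and_jacobian(q_new, a, m, b)
            if np.linalg.norm(f_new) < f_norm:
                accepted = True
                converged = np.linalg.norm(step) < 1e-10
                q = q_new
                lam = max(lam * 0.3, 1e-9)
                break
            lam *= 10.0
        if not accepted or converged:
            break
    return q


def estimate_orientation(a, m, q0, cfg: ObserverConfig | None = None) -> np.ndarray:
    """Dispatch to the optimizer named in ``cfg.method``."""
    cfg = cfg or ObserverConfig()
    if cfg.method == "gradient_descent":
        return gd_orientation(a, m, q0, cfg)
    if cfg.method == "gauss_newton":
        return gn_orientation(a, m, q0, cfg)
    raise ValueError(f"unknown observer method: {cfg.method!r}")
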
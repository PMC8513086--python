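"""Quaternion sensor-fusion filters: Complementary, Kalman, Madgwick.

All three share the same structure: the gyroscope propagates the orientation
at high frequency, and the accelerometer/magnetometer pair pulls the
estimate back toward the gravity/field-consistent orientation at low
frequency.  They differ in how the correction is applied:

* **Complementary** — linear blend ``alpha * q_gyro + (1 - alpha) * q_obs``
  between the gyro-propagated quaternion and the observer output
  (hemisphere-aligned before blending), then renormalized.
* **Kalman** — 4-state quaternion Kalman filter.  Prediction uses the
  first-order transition ``F = I + 0.5 * Omega(w) * dt``; the measurement is
  the observer quaternion with identity measurement model.  The process
  covariance is ``Q = beta * gyro_var * dt^2 * I``, with the gyro variance
  taken from a static window when available.
* **Madgwick** — gradient step of the alignment objective fused directly
  into the rate integration:
  ``q <- normalize(q + (q_dot_gyro - beta * grad/||grad||) * dt)``.

Filter gains here are deliberately generalist defaults; each is exposed on
:class:`FilterConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io import ImuSample, ImuSeries
from .observer import ObserverConfig, estimate_orientation, magnetic_reference, residual_and_jacobian
from .quat import gyro_rate_quaternion, quat_normalize

__all__ = [
    "FilterConfig",
    "FilterState",
    "complementary_step",
    "kalman_step",
    "madgwick_step",
    "run_filter",
    "gyro_in_rad",
]

_DEG2RAD = np.pi / 180.0


@dataclass
class FilterConfig:
    """Fusion-filter settings.

    alpha is the complementary gyro weight in [0, 1] (1 = pure gyro).
    beta is the Madgwick gradient gain (rad/s) or, for the Kalman filter,
    the process-noise weight multiplying the gyro-variance-derived Q.
    gyro_var (rad^2/s^2) scales Kalman Q; estimate it from a static window
    with :func:`gaitfuse.preprocess.static_gyro_variance` when you have one.
    """

    filter_kind: Literal["complementary", "kalman", "madgwick"] = "madgwick"
    alpha: float = 0.98
    beta: float = 0.1
    observer: ObserverConfig = field(default_factory=ObserverConfig)
    dt: float = 1.0 / 75.0
    initial_orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )
    gyro_var: float = 1e-4
    measurement_var: float = 1e-2
    initial_covariance: float = 1e-2
    gyro_units: str = "auto"  # 'rad/s' | 'deg/s' | 'auto'

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.initial_orientation = quat_normalize(
            np.asarray(self.initial_orientation, dtype=float)
        )


@dataclass
class FilterState:
    """Running filter state: current estimate, covariance, timestamp."""

    q: np.ndarray
    P: np.ndarray | None = None
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t: float = 0.0

    @classmethod
    def initial(cls, cfg: FilterConfig, t: float = 0.0) -> "FilterState":
        P = np.eye(4) * cfg.initial_covariance if cfg.filter_kind == "kalman" else None
        return cls(q=cfg.initial_orientation.copy(), P=P, t=t)


def gyro_in_rad(gyro: np.ndarray, units: str) -> np.ndarray:
    """Convert gyro readings to rad/s.

    ``'auto'`` applies a magnitude heuristic: human-movement angular rates
    rarely exceed ~10 rad/s sustained, so if the 95th percentile magnitude
    exceeds 20 the stream is treated as deg/s.
    """
    gyro = np.asarray(gyro, dtype=float)
    if units == "rad/s":
        return gyro
    if units == "deg/s":
        return gyro * _DEG2RAD
    if units == "auto":
        mags = np.linalg.norm(np.atleast_2d(gyro), axis=-1)
        scale = np.percentile(mags, 95) if mags.size > 1 else mags.max(initial=0.0)
        return gyro * _DEG2RAD if scale > 20.0 else gyro
    raise ValueError(f"unknown gyro units {units!r}")


def _resolve_sample(state: FilterState, sample: ImuSample, cfg: FilterConfig):
    dt = sample.t - state.t
    if dt <= 0:
        raise ValueError(f"non-positive sample interval dt={dt}")
    omega = gyro_in_rad(sample.gyro, cfg.gyro_units)
    a = np.asarray(sample.accel, dtype=float)
    m = np.asarray(sample.mag, dtype=float)
    if np.linalg.norm(m) == 0.0:
        m = None
    return dt, omega, a, m


def _observer_quat(q_seed, a, m, cfg: FilterConfig) -> np.ndarray:
    """Observer output hemisphere-aligned with the seed quaternion."""
    z = estimate_orientation(a, m, q_seed, cfg.observer)
    if np.dot(z, q_seed) < 0:
        z = -z
    return z


def complementary_step(state: FilterState, sample: ImuSample, cfg: FilterConfig) -> FilterState:
    """One complementary-filter update: gyro propagation + linear blend."""
    dt, omega, a, m = _resolve_sample(state, sample, cfg)
    q_gyro = quat_normalize(state.q + gyro_rate_quaternion(state.q, omega) * dt)
    if np.linalg.norm(a) == 0.0:
        warnings.warn("zero accelerometer reading; skipping observer correction", stacklevel=2)
        q = q_gyro
    else:
        q_obs = _observer_quat(q_gyro, a, m, cfg)
        q = quat_normalize(cfg.alpha * q_gyro + (1.0 - cfg.alpha) * q_obs)
    return replace(state, q=q, t=sample.t)


def madgwick_step(state: FilterState, sample: ImuSample, cfg: FilterConfig) -> FilterState:
    """One Madgwick update: rate integration minus normalized gradient step."""
    dt, omega, a, m = _resolve_sample(state, sample, cfg)
    qdot = gyro_rate_quaternion(state.q, omega)
    if cfg.beta > 0.0:
        if np.linalg.norm(a) == 0.0:
            warnings.warn("zero accelerometer reading; gravity objective skipped", stacklevel=2)
        else:
            f, J = residual_and_jacobian(state.q, a, m)
            grad = J.T @ f
            gn = np.linalg.norm(grad)
            # floor guards the normalization: at an exactly consistent estimate
            # the gradient is pure round-off and must not be blown up to unit size
            if gn > 1e-12:
                qdot = qdot - cfg.beta * grad / gn
    q = quat_normalize(state.q + qdot * dt)
    return replace(state, q=q, t=sample.t)


def _omega_matrix(omega: np.ndarray) -> np.ndarray:
    wx, wy, wz = omega
    return np.array(
        [
            [0.0, -wx, -wy, -wz],
            [wx, 0.0, wz, -wy],
            [wy, -wz, 0.0, wx],
            [wz, wy, -wx, 0.0],
        ]
    )


def kalman_step(state: FilterState, sample: ImuSample, cfg: FilterConfig) -> FilterState:
    """One quaternion Kalman update (predict with gyro, correct with observer)."""
    dt, omega, a, m = _resolve_sample(state, sample, cfg)
    if state.P is None:
        raise ValueError("Kalman state requires an initialized covariance P")

    F = np.eye(4) + 0.5 * _omega_matrix(omega) * dt
    q_pred = quat_normalize(F @ state.q)
    Q = cfg.beta * cfg.gyro_var * dt * dt * np.eye(4)
    P_pred = F @ state.P @ F.T + Q

    if np.linalg.norm(a) == 0.0:
        warnings.warn("zero accelerometer reading; Kalman update skipped", stacklevel=2)
        return replace(state, q=q_pred, P=0.5 * (P_pred + P_pred.T), t=sample.t)

    z = _observer_quat(q_pred, a, m, cfg)
    R = cfg.measurement_var * np.eye(4)
    K = P_pred @ np.linalg.inv(P_pred + R)
    q = quat_normalize(q_pred + K @ (z - q_pred))
    P = (np.eye(4) - K) @ P_pred
    P = 0.5 * (P + P.T)
    evals = np.linalg.eigvalsh(P)
    if evals.min() < 0:
        warnings.warn("Kalman covariance lost positive semi-definiteness; flooring", stacklevel=2)
        w, V = np.linalg.eigh(P)
        P = (V * np.clip(w, 0.0, None)) @ V.T
    return replace(state, q=q, P=P, t=sample.t)


_STEPS = {
    "complementary": complementary_step,
    "kalman": kalman_step,
    "madgwick": madgwick_step,
}


def run_filter(series: ImuSeries, cfg: FilterConfig) -> np.ndarray:
    """Run the configured filter over a series; one unit quaternion per sample.

    The first output equals ``cfg.initial_orientation``; subsequent samples
    are stepped with per-sample dt taken from the timestamps.  The gyro-unit
    heuristic, when ``cfg.gyro_units='auto'``, is resolved once for the whole
    series rather than per sample.
    """
    if len(series) < 2:
        raise ValueError("series must contain at least 2 samples")
    step = _STEPS[cfg.filter_kind]

    if cfg.gyro_units == "auto":
        gyro = gyro_in_rad(series.gyro, "auto")
        units = "rad/s"
    else:
        gyro = series.gyro
        units = cfg.gyro_units
    cfg = replace(cfg, gyro_units=units)

    state = FilterState.initial(cfg, t=float(series.t[0]))
    out = np.empty((len(series), 4))
    out[0] = state.q
    for i in range(1, len(series)):
        sample = ImuSample(float(series.t[i]), series.accel[i], gyro[i], series.mag[i])
        state = step(state, sample, cfg)
        out[i] = state.q
    return out
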
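"""Synthetic two-segment hinge gait: ground truth + ideal IMU signals.

The simulator emulates a robotic-trainer-style gait trial: a thigh segment
oscillating about the mediolateral (y) axis and a shank segment whose
orientation composes the thigh motion with a knee flexion program.  Both
rotations share the hinge axis, so the commanded knee angle equals the
pitch difference of the two segments exactly and the body angular rates
have the closed form ``omega = d(angle)/dt`` about y.

From a truth orientation series the inverse sensor model produces what an
ideal strapped-down IMU would read — gravity and the magnetic field rotated
into the body frame, plus the body angular rate — and then adds seeded
Gaussian noise and constant per-axis biases.  Linear (translational)
acceleration is neglected by default, matching slow treadmill-trainer
motion, so the accelerometer assumption of the observers holds exactly in
the noiseless case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImuSeries
from .quat import (
    euler_to_quat,
    quat_conjugate,
    quat_multiply,
    rotate_vector,
)

__all__ = [
    "MotionProgram",
    "NoiseModel",
    "HingeTrajectory",
    "hinge_trajectory",
    "imu_from_orientation",
    "static_sequence",
    "GRAVITY_WORLD",
    "FIELD_WORLD",
]

GRAVITY_WORLD = np.array([0.0, 0.0, 1.0])  # accelerometer units of g, z-up
# mid-latitude field: 60-degree dip below horizontal, unit magnitude
FIELD_WORLD = np.array([np.cos(np.radians(60.0)), 0.0, -np.sin(np.radians(60.0))])


@dataclass
class MotionProgram:
    """Flexion-extension program for the two-segment hinge.

    rom is peak-to-peak knee flexion in degrees (60 by default, the standard
    robotic-trainer knee setting); thigh_amplitude is peak-to-peak hip
    oscillation (45 by default).  The cosine waveform starts at zero flexion
    so the motion begins at the neutral pose.
    """

    rom: float = 60.0
    cadence: float = 1.0          # cycles/s
    duration: float = 60.0        # s
    fs: float = 75.0              # Hz
    waveform: str = "cosine"      # 'cosine' | 'double_peak'
    thigh_amplitude: float = 45.0  # degrees peak-to-peak
    second_peak_fraction: float = 0.35  # double-peak: early-stance lobe height

    def __post_init__(self):
        if self.rom < 0:
            raise ValueError("rom must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.fs <= 2.0 * self.cadence:
            raise ValueError("sampling rate must exceed twice the cadence (Nyquist)")


@dataclass
class NoiseModel:
    """Gaussian sensor noise (per-axis sd) and constant biases.

    Units follow the simulated channels: gyro deg/s, accel g, mag in field
    units.  ``seed`` makes the noise bit-reproducible.
    """

    gyro_sd: float = 0.0
    accel_sd: float = 0.0
    mag_sd: float = 0.0
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mag_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: int | None = None

    def __post_init__(self):
        if min(self.gyro_sd, self.accel_sd, self.mag_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for name in ("gyro_bias", "accel_bias", "mag_offset"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass
class HingeTrajectory:
    """Ground truth of a simulated trial."""

    t: np.ndarray
    q_proximal: np.ndarray
    q_distal: np.ndarray
    knee_angle: np.ndarray        # degrees
    omega_proximal: np.ndarray    # rad/s, body frame
    omega_distal: np.ndarray
    fs: float


def _knee_waveform(program: MotionProgram, t: np.ndarray):
    """Knee flexion angle (deg) and rate (deg/s) over time."""
    ph = 2.0 * np.pi * program.cadence * t
    if program.waveform == "cosine":
        k = 0.5 * program.rom * (1.0 - np.cos(ph))
        kdot = 0.5 * program.rom * np.sin(ph) * 2.0 * np.pi * program.cadence
        return k, kdot
    if program.waveform == "double_peak":
        # two positive raised-cosine lobes per cycle: a tall swing peak and a
        # smaller early-stance peak, echoing the physiological knee curve
        frac = np.mod(program.cadence * t, 1.0)
        k = np.zeros_like(t)
        kdot = np.zeros_like(t)
        for center, width, amp in (
            (0.75, 0.5, 1.0),                          # swing-phase peak
            (0.2, 0.3, program.second_peak_fraction),  # stance-phase peak
        ):
            u = (frac - center) / width
            inside = np.abs(u) < 0.5
            lobe = amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * u))
            dlobe = -amp * np.pi * np.sin(2.0 * np.pi * u) / width * program.cadence
            k += np.where(inside, lobe, 0.0)
            kdot += np.where(inside, dlobe, 0.0)
        k *= program.rom
        kdot *= program.rom
        return k, kdot
    raise ValueError(f"unknown waveform {program.waveform!r}")


def hinge_trajectory(program: MotionProgram) -> HingeTrajectory:
    """Generate the two segments' truth orientations and the knee angle."""
    n = int(round(program.fs * program.duration))
    t = np.arange(n) / program.fs

    half_hip = 0.5 * program.thigh_amplitude
    hip = half_hip * np.sin(2.0 * np.pi * program.cadence * t)
    hipdot = half_hip * np.cos(2.0 * np.pi * program.cadence * t) * 2.0 * np.pi * program.cadence
    knee, kneedot = _knee_waveform(program, t)

    zeros = np.zeros_like(t)
    # pure pitch rotations: euler (roll=0, pitch=angle, yaw=0)
    q_prox = euler_to_quat(np.stack([zeros, np.radians(hip), zeros], axis=-1))
    q_dist = euler_to_quat(np.stack([zeros, np.radians(hip + knee), zeros], axis=-1))

    deg2rad = np.pi / 180.0
    omega_prox = np.stack([zeros, hipdot * deg2rad, zeros], axis=-1)
    omega_dist = np.stack([zeros, (hipdot + kneedot) * deg2rad, zeros], axis=-1)

    return HingeTrajectory(
        t=t,
        q_proximal=q_prox,
        q_distal=q_dist,
        knee_angle=knee,
        omega_proximal=omega_prox,
        omega_distal=omega_dist,
        fs=program.fs,
    )


def _body_rates_from_quat(q: np.ndarray, fs: float) -> np.ndarray:
    """Body angular rate from finite-differenced quaternions: 2 vec(q* ⊗ q̇)."""
    qdot = np.gradient(q, 1.0 / fs, axis=0)
    return 2.0 * quat_multiply(quat_conjugate(q), qdot)[:, 1:]


def imu_from_orientation(
    q_series,
    fs: float,
    noise: NoiseModel | None = None,
    gravity: np.ndarray = GRAVITY_WORLD,
    field_vec: np.ndarray = FIELD_WORLD,
    omega_body: np.ndarray | None = None,
    t: np.ndarray | None = None,
) -> ImuSeries:
    """Inverse sensor model: what an ideal IMU reads along ``q_series``.

    accel = gravity rotated into the body frame (specific force, linear
    acceleration neglected); mag likewise for the field; gyro = body rate
    (deg/s), either supplied analytically via ``omega_body`` (rad/s) or
    finite-differenced from the quaternions.  Noise/biases from ``noise``
    are applied with its own seeded generator.
    """
    q = np.asarray(q_series, dtype=float)
    noise = noise or NoiseModel()
    n = q.shape[0]
    if t is None:
        t = np.arange(n) / fs

    qc = quat_conjugate(q)
    accel = rotate_vector(qc, np.broadcast_to(gravity, (n, 3)))
    mag = rotate_vector(qc, np.broadcast_to(field_vec, (n, 3)))
    if omega_body is None:
        omega_body = _body_rates_from_quat(q, fs)
    gyro = np.degrees(np.asarray(omega_body, dtype=float))

    rng = np.random.default_rng(noise.seed)
    accel = accel + noise.accel_bias + noise.accel_sd * rng.standard_normal((n, 3))
    gyro = gyro + noise.gyro_bias + noise.gyro_sd * rng.standard_normal((n, 3))
    mag = mag + noise.mag_offset + noise.mag_sd * rng.standard_normal((n, 3))

    return ImuSeries(
        t=t,
        accel=accel,
        gyro=gyro,
        mag=mag,
        rate_hz=fs,
        gyro_units="deg/s",
        accel_units="g",
        source="synthetic",
    )


def static_sequence(
    duration: float,
    orientation=None,
    noise: NoiseModel | None = None,
    fs: float = 75.0,
) -> ImuSeries:
    """Constant-orientation series (calibration fixture)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(fs * duration))
    if orientation is None:
        orientation = np.array([1.0, 0.0, 0.0, 0.0])
    q = np.broadcast_to(np.asarray(orientation, dtype=float), (n, 4))
    return imu_from_orientation(q, fs, noise=noise, omega_body=np.zeros((n, 3)))
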
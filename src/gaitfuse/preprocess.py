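"""Signal conditioning and sensor calibration applied before fusion.

Accelerometer/gyroscope calibration follows the static-window convention:
the device is held still for the first few seconds, the channels are
low-pass filtered, and the window mean is removed from the whole recording.
For the accelerometer the expected gravity contribution of the static pose
is preserved (only the residual is treated as bias) — removing the raw mean
would delete gravity and break every orientation observer downstream.

Magnetometer hard-iron calibration uses the min/max centering of a
360-degree rotation maneuver about all three axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .filters import gyro_in_rad
from .io import ImuSeries

__all__ = [
    "CalibrationParams",
    "lowpass",
    "static_calibration",
    "static_gyro_variance",
    "mag_calibration",
    "apply_calibration",
]

GRAVITY_MAGNITUDE = {"g": 1.0, "m/s^2": 9.80665}


@dataclass
class CalibrationParams:
    """Constant per-axis corrections: additive biases and mag hard-iron/scale."""

    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mag_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mag_scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        for name in ("accel_bias", "gyro_bias", "mag_offset", "mag_scale"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.mag_scale <= 0):
            raise ValueError("mag_scale components must be > 0")


def lowpass(x, cutoff_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass, per channel."""
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2}); got {cutoff_hz}")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, x, axis=0)


def _static_window(series: ImuSeries, window_s: float) -> slice:
    fs = series.rate_hz or 1.0 / np.median(np.diff(series.t))
    n = int(round(window_s * fs))  # count-based: a 5 s window at 75 Hz is 375 samples
    if len(series) < n:
        raise ValueError(
            f"series has {len(series)} samples, shorter than the "
            f"{window_s:.2f} s ({n}-sample) calibration window"
        )
    return slice(0, n)


def static_calibration(
    series: ImuSeries,
    window_s: float = 5.0,
    cutoff_hz: float = 10.0,
    gyro_still_sd: float = 5.0,
) -> CalibrationParams:
    """Accel/gyro biases from the mean of the filtered first ``window_s`` seconds.

    The gyro bias is the window mean directly (a still device has zero true
    rate).  The accel bias is the window mean minus the expected gravity
    vector: +1 g (in the declared units) along the axis with the largest
    mean magnitude, signed to match.  A warning is emitted if the gyro
    standard deviation in the window suggests the device was moving
    (``gyro_still_sd`` in the series' own gyro units).
    """
    win = _static_window(series, window_s)
    fs = series.rate_hz or 1.0 / np.median(np.diff(series.t))
    cutoff = min(cutoff_hz, 0.45 * fs)
    accel = lowpass(series.accel, cutoff, fs)[win]
    gyro = lowpass(series.gyro, cutoff, fs)[win]

    if np.any(series.gyro[win].std(axis=0) > gyro_still_sd):
        warnings.warn(
            "gyro variability in the calibration window exceeds the stillness "
            "threshold; was the device static?",
            stacklevel=2,
        )

    accel_mean = accel.mean(axis=0)
    axis = int(np.argmax(np.abs(accel_mean)))
    g_expect = np.zeros(3)
    g_expect[axis] = np.sign(accel_mean[axis]) * GRAVITY_MAGNITUDE.get(series.accel_units, 1.0)
    return CalibrationParams(
        accel_bias=accel_mean - g_expect,
        gyro_bias=gyro.mean(axis=0),
    )


def static_gyro_variance(series: ImuSeries, window_s: float = 5.0) -> float:
    """Mean per-axis gyro variance (rad^2/s^2) over the static window.

    Feeds the Kalman process covariance; uses raw (unfiltered) samples so the
    variance reflects the sensor noise the filter will actually see.
    """
    win = _static_window(series, window_s)
    gyro = gyro_in_rad(series.gyro[win], series.gyro_units)
    return float(gyro.var(axis=0, ddof=1).mean())


def mag_calibration(series: ImuSeries, min_spread: float = 1e-6) -> CalibrationParams:
    """Hard-iron offset and per-axis scale from a full-rotation maneuver.

    offset = (max + min) / 2 per axis; scale maps each axis' half-range to
    the mean half-range.  Requires genuine rotation: each axis must sweep a
    spread above ``min_spread``.
    """
    hi = series.mag.max(axis=0)
    lo = series.mag.min(axis=0)
    half_range = (hi - lo) / 2.0
    if np.any(half_range < min_spread):
        raise ValueError(
            "magnetometer channel(s) nearly constant; the calibration maneuver "
            "must rotate the device through 360 degrees about all three axes"
        )
    return CalibrationParams(
        mag_offset=(hi + lo) / 2.0,
        mag_scale=half_range.mean() / half_range,
    )


def apply_calibration(series: ImuSeries, params: CalibrationParams) -> ImuSeries:
    """Subtract biases/offsets and apply mag scales; timestamps untouched."""
    out = series.copy()
    out.accel = out.accel - params.accel_bias
    out.gyro = out.gyro - params.gyro_bias
    out.mag = (out.mag - params.mag_offset) * params.mag_scale
    return out
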
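"""Delimited-text readers/writers and the in-memory IMU containers.

File dialect: comma-separated, period decimal, UTF-8, optional header.
An IMU stream is 10 columns — timestamp (s) then 3-axis accelerometer,
gyroscope, magnetometer.  A quaternion stream is 5 columns — timestamp then
(w, x, y, z).  Angle and cycle tables are ordinary CSV written with pandas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .quat import quat_normalize

__all__ = [
    "ImuSample",
    "ImuSeries",
    "read_imu",
    "write_imu",
    "read_quaternions",
    "write_quaternions",
]

IMU_COLUMNS = [
    "t",
    "ax", "ay", "az",
    "gx", "gy", "gz",
    "mx", "my", "mz",
]
QUAT_COLUMNS = ["t", "qw", "qx", "qy", "qz"]


@dataclass(frozen=True)
class ImuSample:
    """One 9-axis reading: timestamp (s) + accel, gyro, mag triplets."""

    t: float
    accel: np.ndarray  # declared units, default g
    gyro: np.ndarray   # declared units, default deg/s
    mag: np.ndarray    # arbitrary consistent field units

    def __post_init__(self):
        for name in ("accel", "gyro", "mag"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        if not np.isfinite([self.t, *self.accel, *self.gyro, *self.mag]).all():
            raise ValueError("ImuSample fields must all be finite")


@dataclass
class ImuSeries:
    """Time-ordered 9-axis samples for one body segment.

    Column arrays share the leading sample axis; timestamps are strictly
    increasing seconds.  ``gyro_units`` is ``'deg/s'`` or ``'rad/s'`` (or
    ``'auto'`` to let the fusion stage apply its magnitude heuristic);
    ``accel_units`` is ``'g'`` or ``'m/s^2'``.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    rate_hz: float | None = None
    gyro_units: str = "deg/s"
    accel_units: str = "g"
    source: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("accel", "gyro", "mag"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 2 or v.shape != (self.t.size, 3):
                raise ValueError(f"{name} must have shape (n_samples, 3)")
            setattr(self, name, v)
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValueError(
                f"timestamps must be strictly increasing; first violation at index {bad[0] + 1}"
            )
        if self.rate_hz is None and self.t.size > 1:
            self.rate_hz = float(1.0 / np.median(dt))

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> ImuSample:
        return ImuSample(float(self.t[i]), self.accel[i], self.gyro[i], self.mag[i])

    def copy(self) -> "ImuSeries":
        return replace(
            self,
            t=self.t.copy(),
            accel=self.accel.copy(),
            gyro=self.gyro.copy(),
            mag=self.mag.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.t, self.accel, self.gyro, self.mag]),
            columns=IMU_COLUMNS,
        )


def _read_numeric_table(path, n_cols: int, col_names: list[str]) -> np.ndarray:
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1:
                try:
                    [float(p) for p in parts]
                except ValueError:
                    continue  # header row
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} columns, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def read_imu(
    path,
    gyro_units: str = "deg/s",
    accel_units: str = "g",
    rate_hz: float | None = None,
) -> ImuSeries:
    """Parse a 10-column IMU stream (timestamp + 9 channels)."""
    data = _read_numeric_table(path, 10, IMU_COLUMNS)
    return ImuSeries(
        t=data[:, 0],
        accel=data[:, 1:4],
        gyro=data[:, 4:7],
        mag=data[:, 7:10],
        rate_hz=rate_hz,
        gyro_units=gyro_units,
        accel_units=accel_units,
        source=str(path),
    )


def write_imu(series: ImuSeries, path, header: bool = True) -> None:
    series.to_frame().to_csv(path, index=False, header=header, float_format="%.17g")


def read_quaternions(path, norm_warn: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Parse a 5-column quaternion stream; returns ``(t, q)`` with q unit-normalized.

    Rows whose norm deviates from 1 by more than ``norm_warn`` (fractional)
    trigger a warning; zero-norm rows are an error.
    """
    data = _read_numeric_table(path, 5, QUAT_COLUMNS)
    t, q = data[:, 0], data[:, 1:5]
    norms = np.linalg.norm(q, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"{path}: zero-norm quaternion at data row {zero[0]}")
    off = np.abs(norms - 1.0) > norm_warn
    if off.any():
        warnings.warn(
            f"{path}: {int(off.sum())} quaternion rows deviate from unit norm by >"
            f" {norm_warn:.0%}; renormalizing",
            stacklevel=2,
        )
    return t, quat_normalize(q)


def write_quaternions(t, q, path, header: bool = True) -> None:
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    pd.DataFrame(
        np.column_stack([t, q]), columns=QUAT_COLUMNS
    ).to_csv(path, index=False, header=header, float_format="%.17g")
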
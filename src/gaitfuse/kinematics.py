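"""Joint angles from two segment orientations; gait-cycle pattern extraction.

A joint angle is the relative rotation between a proximal segment (e.g.,
thigh) and a distal segment (e.g., shank), reported per anatomical plane in
degrees.  Two modes are offered:

* ``'euler_diff'`` (default): per-plane difference of the two segments'
  Euler angles — the "per plane of motion" reading.
* ``'relative'``: Euler decomposition of the relative quaternion
  ``q_proximal* ⊗ q_distal``.

Cycle extraction delimits gait cycles at successive rising crossings of an
angle threshold, resamples each cycle to a fixed percentage grid, and
reports ROM statistics (per-cycle range of motion, mean/sd/CI, polynomial
fit with estimated extremes).  Because the boundary rule is angle-based, a
mid-range threshold can start cycles at the swing phase; the crossing
phase is recorded on the result so the inversion is detectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .quat import quat_conjugate, quat_multiply, quat_to_euler

__all__ = [
    "AxisMapping",
    "JointAngleSeries",
    "CyclePattern",
    "joint_angles",
    "pattern_extraction",
    "cycle_statistics",
    "poly_fit_cycle",
    "error_metrics",
    "compare_patterns",
]

PERCENT_POINTS = 101  # 0..100% inclusive


@dataclass(frozen=True)
class AxisMapping:
    """Which Euler angle (roll/pitch/yaw) feeds which anatomical plane.

    Defaults suit a knee hinge about the mediolateral (body y) axis:
    flexion-extension appears in pitch.
    """

    sagittal: str = "pitch"
    frontal: str = "roll"
    transverse: str = "yaw"

    _IDX = {"roll": 0, "pitch": 1, "yaw": 2}

    def index(self, plane: str) -> int:
        return self._IDX[getattr(self, plane)]


@dataclass
class JointAngleSeries:
    """Per-sample joint angles in degrees for the three anatomical planes."""

    t: np.ndarray
    sagittal: np.ndarray
    frontal: np.ndarray
    transverse: np.ndarray
    convention: str = "euler_diff/ZYX"

    def __len__(self) -> int:
        return self.t.size


@dataclass
class CyclePattern:
    """Resampled gait cycles plus their dispersion and ROM statistics.

    Curves live on a 0-100% cycle-percentage grid.  ``ci95`` is the 95%
    half-width ``1.96 * rom_sd`` (normal approximation).  ``min_est`` /
    ``max_est`` are the extremes of the polynomial fit to the mean curve,
    evaluated densely — a noise-suppressed alternative to the raw extremes.
    """

    grid: np.ndarray
    cycles: np.ndarray               # (n_cycles, n_points)
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    variance: float
    rom_per_cycle: np.ndarray
    average_rom: float
    rom_sd: float
    rom_max: float
    ci95: float
    min_observed: float
    max_observed: float
    threshold: float
    crossing_phase: str = "rising"
    poly_coeffs: np.ndarray | None = None
    r_squared: float | None = None
    min_est: float | None = None
    max_est: float | None = None

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]


def joint_angles(
    q_proximal,
    q_distal,
    t=None,
    mapping: AxisMapping = AxisMapping(),
    mode: str = "euler_diff",
) -> JointAngleSeries:
    """Joint angles (degrees) from two time-aligned orientation series."""
    qp = np.atleast_2d(np.asarray(q_proximal, dtype=float))
    qd = np.atleast_2d(np.asarray(q_distal, dtype=float))
    if qp.shape != qd.shape:
        raise ValueError(f"orientation series length mismatch: {qp.shape} vs {qd.shape}")
    if t is None:
        t = np.arange(qp.shape[0], dtype=float)
    t = np.asarray(t, dtype=float)
    if t.size != qp.shape[0]:
        raise ValueError("timestamps length mismatch")

    if mode == "euler_diff":
        e = quat_to_euler(qd, degrees=True) - quat_to_euler(qp, degrees=True)
    elif mode == "relative":
        e = quat_to_euler(quat_multiply(quat_conjugate(qp), qd), degrees=True)
    else:
        raise ValueError(f"unknown joint-angle mode {mode!r}")

    return JointAngleSeries(
        t=t,
        sagittal=e[:, mapping.index("sagittal")],
        frontal=e[:, mapping.index("frontal")],
        transverse=e[:, mapping.index("transverse")],
        convention=f"{mode}/ZYX",
    )


def _rising_crossings(x: np.ndarray, threshold: float) -> np.ndarray:
    below = x[:-1] < threshold
    at_or_above = x[1:] >= threshold
    return np.flatnonzero(below & at_or_above) + 1


def pattern_extraction(
    angles,
    threshold: float,
    n_points: int = PERCENT_POINTS,
    length_gate: tuple[float, float] = (0.5, 1.5),
) -> CyclePattern:
    """Segment an angle curve into cycles at rising threshold crossings.

    Cycles whose sample count falls outside ``length_gate`` times the median
    cycle length are discarded; survivors are linearly resampled to
    ``n_points`` spanning 0-100% of the cycle, and ROM statistics are
    computed via :func:`cycle_statistics` and :func:`poly_fit_cycle`.
    """
    x = np.asarray(angles, dtype=float)
    if x.ndim != 1:
        raise ValueError("angles must be a 1-D curve")
    if not (x.min() <= threshold <= x.max()):
        raise ValueError(
            f"threshold {threshold} outside signal range [{x.min():.3g}, {x.max():.3g}]"
        )
    crossings = _rising_crossings(x, threshold)
    if crossings.size < 2:
        raise ValueError("fewer than 2 threshold crossings: no complete cycles found")

    lengths = np.diff(crossings)
    med = np.median(lengths)
    keep = (lengths >= length_gate[0] * med) & (lengths <= length_gate[1] * med)
    starts, ends = crossings[:-1][keep], crossings[1:][keep]
    if starts.size == 0:
        raise ValueError("all candidate cycles rejected by the length gate")

    grid = np.linspace(0.0, 100.0, n_points)
    cycles = np.empty((starts.size, n_points))
    for i, (s, e) in enumerate(zip(starts, ends)):
        seg = x[s : e + 1]  # inclusive end: cycle spans crossing to crossing
        cycles[i] = np.interp(grid, np.linspace(0.0, 100.0, seg.size), seg)

    pattern = CyclePattern(
        grid=grid,
        cycles=cycles,
        mean_curve=cycles.mean(axis=0),
        sd_curve=cycles.std(axis=0, ddof=1) if cycles.shape[0] > 1 else np.zeros(n_points),
        variance=0.0,
        rom_per_cycle=np.empty(0),
        average_rom=0.0,
        rom_sd=0.0,
        rom_max=0.0,
        ci95=0.0,
        min_observed=float(x.min()),
        max_observed=float(x.max()),
        threshold=float(threshold),
    )
    cycle_statistics(pattern)
    poly_fit_cycle(pattern)
    return pattern


def cycle_statistics(pattern: CyclePattern) -> CyclePattern:
    """Fill the ROM statistics of a pattern in place (and return it).

    rom_per_cycle is max - min of each resampled cycle; ci95 is the normal
    95% half-width ``1.96 * rom_sd``.  With a single cycle the sd is
    undefined and reported as 0 with a warning.
    """
    rom = pattern.cycles.max(axis=1) - pattern.cycles.min(axis=1)
    pattern.rom_per_cycle = rom
    pattern.average_rom = float(rom.mean())
    pattern.rom_max = float(rom.max())
    if rom.size > 1:
        pattern.rom_sd = float(rom.std(ddof=1))
    else:
        warnings.warn("single cycle: ROM standard deviation undefined, reporting 0", stacklevel=2)
        pattern.rom_sd = 0.0
    pattern.ci95 = float(1.96 * pattern.rom_sd)
    pattern.variance = float(pattern.rom_sd**2)
    return pattern


def poly_fit_cycle(
    pattern: CyclePattern, degree: int = 9, dense_points: int = 1001
) -> CyclePattern:
    """Least-squares polynomial of the mean curve over cycle percentage.

    Fills ``poly_coeffs`` (highest degree first, numpy convention),
    ``r_squared``, and the fitted extremes ``min_est`` / ``max_est``
    evaluated on a dense 0-100% grid.
    """
    y = pattern.mean_curve
    if degree >= y.size:
        raise ValueError("polynomial degree must be below the number of grid points")
    coeffs = np.polyfit(pattern.grid, y, degree)
    fitted = np.polyval(coeffs, pattern.grid)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    pattern.poly_coeffs = coeffs
    pattern.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dense = np.polyval(coeffs, np.linspace(0.0, 100.0, dense_points))
    pattern.min_est = float(dense.min())
    pattern.max_est = float(dense.max())
    return pattern


def error_metrics(a, b, eps: float = 1e-9):
    """RMSE and MAPE (%) between two equal-length series.

    For 2-D inputs (samples x channels) per-channel values are returned
    along with their means.  MAPE excludes reference entries with
    ``|a| < eps``; the excluded count is included in the result.

    Returns a dict with keys ``rmse``, ``mape``, and for multi-channel
    input additionally ``rmse_per_channel``, ``mape_per_channel``,
    ``mape_excluded``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"series length mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    if a.ndim == 1:
        a, diff = a[:, None], diff[:, None]
    rmse_ch = np.sqrt(np.mean(diff**2, axis=0))
    mask = np.abs(a) >= eps
    mape_ch = np.array(
        [
            100.0 * np.mean(np.abs(diff[mask[:, j], j]) / np.abs(a[mask[:, j], j]))
            if mask[:, j].any()
            else np.nan
            for j in range(a.shape[1])
        ]
    )
    excluded = int((~mask).sum())
    if rmse_ch.size == 1:
        return {"rmse": float(rmse_ch[0]), "mape": float(mape_ch[0]), "mape_excluded": excluded}
    return {
        "rmse": float(rmse_ch.mean()),
        "mape": float(np.nanmean(mape_ch)),
        "rmse_per_channel": rmse_ch,
        "mape_per_channel": mape_ch,
        "mape_excluded": excluded,
    }


def compare_patterns(p1: CyclePattern, p2: CyclePattern):
    """Align two patterns' mean curves on a common grid and score them.

    Returns ``(grid, curve1, curve2, metrics)`` with metrics from
    :func:`error_metrics`.  Mismatched grids are resampled to the finer one
    with a warning.
    """
    g1, g2 = p1.grid, p2.grid
    c1, c2 = p1.mean_curve, p2.mean_curve
    if g1.size != g2.size or not np.allclose(g1, g2):
        warnings.warn("pattern grids differ; resampling to the finer grid", stacklevel=2)
        grid = g1 if g1.size >= g2.size else g2
        c1 = np.interp(grid, g1, c1)
        c2 = np.interp(grid, g2, c2)
    else:
        grid = g1
    return grid, c1, c2, error_metrics(c1, c2)
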
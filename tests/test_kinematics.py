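"""Joint angles, cycle extraction, ROM statistics and comparison metrics."""

import numpy as np
import pytest

import gaitfuse as gf
from gaitfuse.kinematics import (
    compare_patterns,
    cycle_statistics,
    error_metrics,
    joint_angles,
    pattern_extraction,
    poly_fit_cycle,
)
from gaitfuse.quat import euler_to_quat


def hinge_pair(theta_deg, n=None):
    """Proximal at identity, distal rotated by theta about the pitch axis."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    n = n or theta.size
    qp = np.tile([1.0, 0, 0, 0], (n, 1))
    zeros = np.zeros(n)
    qd = euler_to_quat(np.stack([zeros, np.radians(theta), zeros], axis=-1))
    return qp, qd


class TestJointAngles:
    def test_identical_series_zero_angles(self):
        qp, qd = hinge_pair(np.zeros(10))
        ja = joint_angles(qp, qp)
        assert np.allclose(ja.sagittal, 0) and np.allclose(ja.frontal, 0)

    @pytest.mark.parametrize("mode", ["euler_diff", "relative"])
    def test_hinge_rotation_appears_in_sagittal(self, mode):
        theta = np.linspace(-85.0, 85.0, 50)
        qp, qd = hinge_pair(theta)
        ja = joint_angles(qp, qd, mode=mode)
        assert np.allclose(ja.sagittal, theta, atol=1e-6)

    def test_modes_agree_on_hinge_motion(self, noiseless_gait):
        traj, _ = noiseless_gait
        a = joint_angles(traj.q_proximal, traj.q_distal, mode="euler_diff")
        b = joint_angles(traj.q_proximal, traj.q_distal, mode="relative")
        assert np.max(np.abs(a.sagittal - b.sagittal)) < 1.0

    def test_length_mismatch_rejected(self):
        qp, qd = hinge_pair(np.zeros(5))
        with pytest.raises(ValueError, match="mismatch"):
            joint_angles(qp[:4], qd)


class TestPatternExtraction:
    def test_sinusoid_cycle_count(self):
        t = np.arange(0, 30.0, 1 / 75.0)
        x = 30.0 * (1 - np.cos(2 * np.pi * 1.0 * t))
        pattern = pattern_extraction(x, threshold=30.0)
        assert abs(pattern.n_cycles - 29) <= 1

    def test_identical_cycles_zero_dispersion(self):
        t = np.arange(0, 20.0, 1 / 75.0)
        x = 30.0 * (1 - np.cos(2 * np.pi * 1.0 * t))
        pattern = pattern_extraction(x, threshold=30.0)
        assert np.all(pattern.sd_curve < 0.1)
        assert pattern.ci95 < 0.1
        assert pattern.variance < 0.01

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            pattern_extraction(np.full(1000, 5.0), threshold=10.0)

    def test_too_few_crossings_rejected(self):
        x = np.concatenate([np.zeros(50), np.ones(50) * 10])
        with pytest.raises(ValueError, match="threshold|cycles"):
            pattern_extraction(x, threshold=5.0)

    def test_grid_is_percentage(self):
        t = np.arange(0, 10.0, 1 / 75.0)
        x = np.sin(2 * np.pi * t)
        pattern = pattern_extraction(x, threshold=0.0)
        assert pattern.grid.size == 101
        assert pattern.grid[0] == 0.0 and pattern.grid[-1] == 100.0

    def test_rom_matches_waveform_amplitude(self):
        t = np.arange(0, 30.0, 1 / 75.0)
        x = 30.0 * (1 - np.cos(2 * np.pi * 1.0 * t))  # peak-to-peak 60
        pattern = pattern_extraction(x, threshold=30.0)
        assert abs(pattern.average_rom - 60.0) < 0.2


class TestCycleStatistics:
    @pytest.mark.parametrize("sd,expected_ci", [(2.75, 5.39), (3.90, 7.64)])
    def test_ci_half_width_from_rom_sd(self, sd, expected_ci):
        """ci95 = 1.96 * sd, checked against hand-computed reference values."""
        rng = np.random.default_rng(8)
        base = 30.0 * (1 - np.cos(2 * np.pi * np.linspace(0, 1, 101)))
        # per-cycle amplitude scaling with the target ROM sd around 60 deg
        roms = 60.0 + sd * rng.standard_normal(400)
        cycles = base[None, :] / 60.0 * roms[:, None]
        pattern = gf.CyclePattern(
            grid=np.linspace(0, 100, 101), cycles=cycles,
            mean_curve=cycles.mean(axis=0), sd_curve=cycles.std(axis=0, ddof=1),
            variance=0, rom_per_cycle=np.empty(0), average_rom=0, rom_sd=0,
            rom_max=0, ci95=0, min_observed=0, max_observed=0, threshold=30.0,
        )
        cycle_statistics(pattern)
        assert pattern.ci95 == pytest.approx(1.96 * pattern.rom_sd)
        assert pattern.ci95 == pytest.approx(expected_ci, abs=0.5)
        assert round(1.96 * sd, 2) == expected_ci

    def test_single_cycle_sd_zero_with_warning(self):
        t = np.linspace(0, 1, 200)
        x = np.sin(2 * np.pi * t)
        grid = np.linspace(0, 100, 101)
        pattern = gf.CyclePattern(
            grid=grid, cycles=x[None, ::2][:, :101], mean_curve=x[::2][:101],
            sd_curve=np.zeros(101), variance=0, rom_per_cycle=np.empty(0),
            average_rom=0, rom_sd=0, rom_max=0, ci95=0, min_observed=-1,
            max_observed=1, threshold=0.0,
        )
        with pytest.warns(UserWarning, match="single cycle"):
            cycle_statistics(pattern)
        assert pattern.rom_sd == 0.0 and pattern.ci95 == 0.0

    def test_ordering_invariants(self, noisy_gait):
        traj, _ = noisy_gait
        pattern = pattern_extraction(traj.knee_angle, threshold=30.0)
        assert pattern.average_rom <= pattern.rom_max
        assert pattern.min_est <= pattern.max_est
        assert pattern.ci95 >= 0.0


class TestPolyFit:
    def test_self_fit_recovers_polynomial(self):
        grid = np.linspace(0, 100, 101)
        true_coeffs = np.array([2e-8, -3e-6, 1e-4, -0.01, 0.5, 1.0])  # degree 5
        curve = np.polyval(true_coeffs, grid)
        pattern = gf.CyclePattern(
            grid=grid, cycles=curve[None, :], mean_curve=curve,
            sd_curve=np.zeros(101), variance=0, rom_per_cycle=np.array([1.0]),
            average_rom=1, rom_sd=0, rom_max=1, ci95=0, min_observed=0,
            max_observed=0, threshold=0,
        )
        poly_fit_cycle(pattern, degree=5)
        assert pattern.r_squared == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(pattern.poly_coeffs, true_coeffs, atol=1e-6)

    def test_constant_curve_degenerate(self):
        grid = np.linspace(0, 100, 101)
        curve = np.full(101, 7.5)
        pattern = gf.CyclePattern(
            grid=grid, cycles=curve[None, :], mean_curve=curve,
            sd_curve=np.zeros(101), variance=0, rom_per_cycle=np.array([0.0]),
            average_rom=0, rom_sd=0, rom_max=0, ci95=0, min_observed=7.5,
            max_observed=7.5, threshold=0,
        )
        poly_fit_cycle(pattern, degree=3)
        assert pattern.min_est == pytest.approx(7.5, abs=1e-6)
        assert pattern.max_est == pytest.approx(7.5, abs=1e-6)

    def test_fitted_extremes_bracket_smooth_curve(self, noisy_gait):
        traj, _ = noisy_gait
        pattern = pattern_extraction(traj.knee_angle, threshold=30.0)
        resid = np.max(np.abs(np.polyval(pattern.poly_coeffs, pattern.grid) - pattern.mean_curve))
        assert pattern.min_est <= pattern.mean_curve.min() + resid
        assert pattern.max_est >= pattern.mean_curve.max() - resid


class TestErrorMetrics:
    def test_identity_and_offset(self):
        a = np.linspace(1, 10, 50)
        m = error_metrics(a, a)
        assert m["rmse"] == 0.0 and m["mape"] == 0.0
        m = error_metrics(a, a + 1.0)
        assert m["rmse"] == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        a, b = rng.standard_normal(500) + 5.0, rng.standard_normal(500) + 5.0
        m = error_metrics(a, b)
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean((a - b) ** 2)), abs=1e-12)
        assert m["mape"] == pytest.approx(100 * np.mean(np.abs(a - b) / np.abs(a)), abs=1e-12)

    def test_multichannel_returns_per_channel_and_average(self, rng):
        a, b = rng.standard_normal((100, 4)) + 3, rng.standard_normal((100, 4)) + 3
        m = error_metrics(a, b)
        assert m["rmse_per_channel"].shape == (4,)
        assert m["rmse"] == pytest.approx(m["rmse_per_channel"].mean())

    def test_near_zero_reference_masked(self):
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([0.5, 1.0, 2.0])
        m = error_metrics(a, b)
        assert m["mape_excluded"] == 1
        assert np.isfinite(m["mape"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            error_metrics(np.zeros(3), np.zeros(4))


class TestComparePatterns:
    def _pattern(self, curve, grid=None):
        grid = np.linspace(0, 100, 101) if grid is None else grid
        return gf.CyclePattern(
            grid=grid, cycles=curve[None, :], mean_curve=curve,
            sd_curve=np.zeros_like(curve), variance=0,
            rom_per_cycle=np.array([np.ptp(curve)]), average_rom=np.ptp(curve),
            rom_sd=0, rom_max=np.ptp(curve), ci95=0, min_observed=curve.min(),
            max_observed=curve.max(), threshold=0,
        )

    def test_self_comparison_zero(self):
        curve = np.sin(np.linspace(0, 2 * np.pi, 101)) * 30 + 30
        _, _, _, m = compare_patterns(self._pattern(curve), self._pattern(curve))
        assert m["rmse"] == 0.0

    def test_constant_offset_equals_rmse(self):
        curve = np.sin(np.linspace(0, 2 * np.pi, 101)) * 30 + 30
        _, _, _, m = compare_patterns(self._pattern(curve), self._pattern(curve + 2.5))
        assert m["rmse"] == pytest.approx(2.5)

    def test_grid_mismatch_resampled_with_warning(self):
        c1 = np.sin(np.linspace(0, 2 * np.pi, 101)) * 30 + 30
        c2 = np.sin(np.linspace(0, 2 * np.pi, 51)) * 30 + 30
        p2 = self._pattern(c2, grid=np.linspace(0, 100, 51))
        with pytest.warns(UserWarning, match="grids differ"):
            grid, a, b, m = compare_patterns(self._pattern(c1), p2)
        assert grid.size == 101 and a.size == b.size == 101
        assert np.isfinite(m["rmse"])
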
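"""Retarded-time pressure solver, attenuation law, and spectra."""

import numpy as np
import pytest

import protoacoustic as pa
from protoacoustic.thermoacoustic import PulseProfile

from conftest import point_source_grid


def closed_form_point_source(eps, dV_m3, d_m, medium, pulse, t):
    """Analytic pressure of a point source: A / d * S'(t - d/c).

    Independent oracle for the discretised retarded-time integral.
    """
    tau = t - d_m / medium.cs
    c = pulse.duration / 2.0
    sig = pulse.sigma
    # baseline-subtracted Gaussian on [0, duration], analytic derivative
    from scipy.special import erf

    base = np.exp(-(c**2) / (2 * sig**2))
    norm = np.sqrt(2 * np.pi) * sig * 0.5 * (
        erf((pulse.duration - c) / (np.sqrt(2) * sig)) - erf(-c / (np.sqrt(2) * sig))
    ) - base * pulse.duration
    inside = (tau >= 0) & (tau <= pulse.duration)
    g = np.exp(-((tau - c) ** 2) / (2 * sig**2))
    sprime = np.where(inside, -(tau - c) / sig**2 * g / norm, 0.0)
    A = medium.alpha_thermal * eps * dV_m3 / (4 * np.pi * medium.Cp * d_m)
    return A * sprime


class TestPressureSolver:
    def test_zero_dose_gives_zero_trace(self):
        grid = pa.DoseGrid(origin=(0, 0, 0), spacing=1.0, values=np.zeros((3, 3, 3)))
        tr = pa.thermoacoustic_pressure(grid, (10.0, 0.0, 0.0), dt=1e-8)
        assert not np.any(tr.p)

    def test_point_source_matches_closed_form(self):
        """Single voxel, Gaussian pulse: < 1% RMS against the analytic
        retarded solution."""
        grid = point_source_grid(value=1e4, spacing=1.0)
        medium = pa.AcousticMedium()
        pulse = PulseProfile(duration=10e-6, shape="gaussian")
        obs = np.array([0.0, 0.0, 12.0])
        tr = pa.thermoacoustic_pressure(grid, obs, medium, pulse, dt=1e-8)
        oracle = closed_form_point_source(
            1e4, 1e-9, 12.0e-3, medium, pulse, tr.t
        )
        rms = np.sqrt(np.mean((tr.p - oracle) ** 2))
        assert rms < 0.01 * np.abs(oracle).max()

    def test_superposition_on_small_grid(self):
        """Multi-voxel result equals the sum of per-voxel closed forms."""
        rng = np.random.default_rng(7)
        values = rng.uniform(0.5, 2.0, size=(3, 3, 3)) * 1e3
        grid = pa.DoseGrid(origin=(-1.5, -1.5, -1.5), spacing=1.0, values=values)
        medium = pa.AcousticMedium()
        pulse = PulseProfile(duration=10e-6)
        obs = np.array([2.0, 25.0, 3.0])
        tr = pa.thermoacoustic_pressure(grid, obs, medium, pulse, dt=1e-8)
        xs, ys, zs = grid.voxel_centers()
        oracle = np.zeros_like(tr.t)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for k, z in enumerate(zs):
                    d = np.linalg.norm(obs - [x, y, z]) * 1e-3
                    oracle += closed_form_point_source(
                        values[i, j, k], 1e-9, d, medium, pulse, tr.t
                    )
        rms = np.sqrt(np.mean((tr.p - oracle) ** 2))
        assert rms < 0.01 * np.abs(oracle).max()

    def test_amplitude_linear_in_protons(self, dose_100mev):
        """Doubling the particles per pulse doubles the emitted amplitude,
        exactly."""
        obs = (0.0, 0.0, 90.0)
        tr1 = pa.thermoacoustic_pressure(dose_100mev, obs, dt=1e-8)
        doubled = pa.DoseGrid(
            origin=dose_100mev.origin,
            spacing=dose_100mev.spacing,
            values=2.0 * dose_100mev.values,
        )
        tr2 = pa.thermoacoustic_pressure(doubled, obs, dt=1e-8)
        assert tr2.peak_amplitude() == pytest.approx(
            2.0 * tr1.peak_amplitude(), rel=1e-12
        )

    def test_bipolarity_zero_net_impulse(self, dose_100mev):
        """The trace is a time derivative of a smooth kernel, so its
        integral vanishes."""
        tr = pa.thermoacoustic_pressure(dose_100mev, (0.0, 0.0, 90.0), dt=1e-8)
        net = abs(np.sum(tr.p) * tr.dt)
        duration = tr.t[-1] - tr.t[0]
        assert net <= 1e-3 * tr.peak_amplitude() * duration
        assert tr.p.min() < 0 < tr.p.max()  # both compression and rarefaction

    def test_retarded_time_causality(self):
        grid = point_source_grid(value=1e4, spacing=1.0, position=(0, 0, 0))
        medium = pa.AcousticMedium()
        tr = pa.thermoacoustic_pressure(grid, (0, 0, 30.0), medium, dt=1e-8)
        onset = 30.0e-3 / medium.cs
        before = tr.p[tr.t < onset - 2 * tr.dt]
        assert not np.any(before)

    def test_coarse_dt_rejected(self, dose_100mev):
        with pytest.raises(ValueError, match="dt"):
            pa.thermoacoustic_pressure(dose_100mev, (0, 0, 90.0), dt=1e-6)


class TestAttenuation:
    def test_identity_at_reference(self):
        assert pa.attenuated_amplitude(2.92, 2.0, 2.0, 0.95) == pytest.approx(2.92)

    def test_zero_absorption_is_pure_spreading(self):
        assert pa.attenuated_amplitude(1.0, 5.0, 40.0, 0.0) == pytest.approx(5.0 / 40.0)

    def test_published_20mm_value(self):
        """2.92 Pa at 2 mm propagated to 20 mm with 0.95 Np/m."""
        p = pa.attenuated_amplitude(2.92, 2.0, 20.0, 0.95)
        assert p == pytest.approx(0.287, abs=0.001)
        assert p == pytest.approx(0.28, rel=0.05)

    def test_back_propagation_rejected(self):
        with pytest.raises(ValueError):
            pa.attenuated_amplitude(1.0, 10.0, 5.0, 0.95)

    def test_pressure_vs_distance_table(self):
        table = pa.max_pressure_vs_distance(
            2.92, 2.0, np.arange(5.0, 41.0, 5.0), 0.95
        )
        assert len(table) == 8
        p = table["pressure_Pa"].to_numpy()
        assert np.all(np.diff(p) < 0)
        assert p[-1] < p[0] / 8.0

    def test_single_reference_distance(self):
        table = pa.max_pressure_vs_distance(1.5, 2.0, [2.0], 0.95)
        assert table["pressure_Pa"].to_numpy() == pytest.approx([1.5])

    def test_unsorted_distances_rejected(self):
        with pytest.raises(ValueError):
            pa.max_pressure_vs_distance(1.0, 2.0, [5.0, 4.0], 0.95)


class TestSpectrum:
    def test_pure_sinusoid_frequency(self):
        dt = 1e-7  # 10 MHz
        t = np.arange(4096) * dt
        tr = pa.PressureTrace(t=t, p=np.sin(2 * np.pi * 250e3 * t), dt=dt)
        fc = pa.central_frequency(tr)
        assert fc == pytest.approx(250e3, abs=2.5e3)

    def test_gaussian_derivative_peak(self):
        """Derivative-of-Gaussian pulse: |F| ~ f exp(-2 pi^2 f^2 sig^2)
        peaks at 1/(2 pi sig) (closed-form Fourier transform)."""
        sig = 2e-6
        dt = 1e-8
        t = np.arange(8192) * dt
        c = 20e-6
        p = -(t - c) / sig**2 * np.exp(-((t - c) ** 2) / (2 * sig**2))
        tr = pa.PressureTrace(t=t, p=p, dt=dt)
        fc, (lo, hi) = pa.central_frequency(tr, return_edges=True)
        expected = 1.0 / (2 * np.pi * sig)
        assert fc == pytest.approx(expected, rel=0.03)
        assert lo < fc < hi

    def test_all_zero_trace_rejected(self):
        tr = pa.PressureTrace(t=np.arange(128) * 1e-8, p=np.zeros(128), dt=1e-8)
        with pytest.raises(ValueError):
            pa.central_frequency(tr)

    def test_short_trace_rejected(self):
        tr = pa.PressureTrace(t=np.arange(32) * 1e-8, p=np.ones(32), dt=1e-8)
        with pytest.raises(ValueError):
            pa.central_frequency(tr)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        t = np.arange(128) * 1e-8
        tr = pa.PressureTrace(
            t=t, p=np.sin(t * 1e6), dt=1e-8, observation_point=(1.0, 2.0, 3.0)
        )
        tr.save(tmp_path / "trace")
        back = pa.PressureTrace.load(tmp_path / "trace")
        np.testing.assert_allclose(back.t, tr.t)
        np.testing.assert_allclose(back.p, tr.p)
        np.testing.assert_allclose(back.observation_point, tr.observation_point)

    def test_dose_grid_round_trip(self, tmp_path):
        grid = point_source_grid(value=3.5, spacing=2.0)
        grid.save(tmp_path / "dose")
        back = pa.DoseGrid.load(tmp_path / "dose")
        np.testing.assert_allclose(back.values, grid.values)
        np.testing.assert_allclose(back.origin, grid.origin)
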
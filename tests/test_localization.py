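"""Cross-correlation TOA estimation and TDOA source reconstruction."""

import warnings

import numpy as np
import pytest

import protoacoustic as pa
from protoacoustic.localization import LowCorrelationWarning


def bipolar_template(dt=1e-8, n=2000, sigma=1e-6, center=8e-6):
    t = np.arange(n) * dt
    p = -(t - center) / sigma**2 * np.exp(-((t - center) ** 2) / (2 * sigma**2))
    return pa.PressureTrace(t=t, p=p, dt=dt)


def delayed_copy(template, delay_samples, n=6000):
    """Template embedded in a longer trace at an integer-sample delay."""
    p = np.zeros(n)
    k = int(delay_samples)
    p[k : k + len(template.p)] = template.p
    t = np.arange(n) * template.dt
    return pa.PressureTrace(t=t, p=p, dt=template.dt)


def fractional_delay(template, delay_samples, n=6000):
    """Band-limited fractional shift via the Fourier shift theorem."""
    p = np.zeros(n)
    p[: len(template.p)] = template.p
    spec = np.fft.rfft(p)
    f = np.fft.rfftfreq(n, template.dt)
    spec *= np.exp(-2j * np.pi * f * delay_samples * template.dt)
    t = np.arange(n) * template.dt
    return pa.PressureTrace(t=t, p=np.fft.irfft(spec, n), dt=template.dt)


class TestEstimateToa:
    def test_integer_sample_delay(self):
        tpl = bipolar_template()
        tr = delayed_copy(tpl, 1234)
        toa = pa.estimate_toa(tr, tpl)
        assert toa == pytest.approx(1234 * tpl.dt, abs=0.05 * tpl.dt)

    @pytest.mark.parametrize("delay", [500.5, 1000.25, 2000.75])
    def test_fractional_delay_subsample_recovery(self, delay):
        """Band-limited half-sample shifts recovered within 0.1 sample by
        parabolic peak interpolation."""
        tpl = bipolar_template()
        tr = fractional_delay(tpl, delay)
        toa = pa.estimate_toa(tr, tpl)
        assert toa == pytest.approx(delay * tpl.dt, abs=0.1 * tpl.dt)

    def test_time_axis_offsets_are_honoured(self):
        tpl = bipolar_template()
        tr = delayed_copy(tpl, 1000)
        shifted = pa.PressureTrace(t=tr.t - 2e-6, p=tr.p, dt=tr.dt)
        toa = pa.estimate_toa(shifted, tpl)
        assert toa == pytest.approx(1000 * tpl.dt - 2e-6, abs=0.05 * tpl.dt)

    def test_uncorrelated_noise_is_flagged(self):
        rng = np.random.default_rng(11)
        tpl = bipolar_template()
        noise = pa.PressureTrace(
            t=np.arange(6000) * tpl.dt, p=rng.normal(size=6000), dt=tpl.dt
        )
        with pytest.warns(LowCorrelationWarning):
            pa.estimate_toa(noise, tpl)

    def test_flat_trace_rejected(self):
        tpl = bipolar_template()
        flat = pa.PressureTrace(t=np.arange(6000) * tpl.dt, p=np.zeros(6000), dt=tpl.dt)
        with pytest.raises(ValueError):
            pa.estimate_toa(flat, tpl)

    def test_mismatched_sampling_rejected(self):
        tpl = bipolar_template()
        tr = delayed_copy(tpl, 100)
        bad = pa.PressureTrace(t=tr.t * 2, p=tr.p, dt=2 * tr.dt)
        with pytest.raises(ValueError):
            pa.estimate_toa(bad, tpl)


class TestCorrectToas:
    def test_zero_correction_is_identity(self):
        toas = np.array([1e-5, 2e-5, 3e-5])
        np.testing.assert_array_equal(pa.correct_toas(toas, 0.0), toas)

    def test_constant_correction_cancels_in_tdoas(self):
        """A constant 1.08 us shift moves every TOA equally, so the TDOAs
        (and hence the reconstruction) are unchanged."""
        toas = np.array([1e-5, 2e-5, 3e-5, 4e-5])
        corrected = pa.correct_toas(toas, 1.08e-6)
        np.testing.assert_allclose(corrected - toas, 1.08e-6)
        before = pa.tdoas_from_toas(toas).delta_t
        after = pa.tdoas_from_toas(corrected).delta_t
        np.testing.assert_allclose(after, before, atol=1e-18)

    def test_per_sensor_vector_changes_tdoas(self):
        toas = np.array([1e-5, 2e-5, 3e-5, 4e-5])
        corr = np.array([1.0e-6, 1.2e-6, 1.1e-6, 1.3e-6])
        after = pa.tdoas_from_toas(pa.correct_toas(toas, corr)).delta_t
        before = pa.tdoas_from_toas(toas).delta_t
        np.testing.assert_allclose(after - before, corr - corr[0], atol=1e-18)


def synthetic_tdoas(array, source, c=1500.0, jitter=0.0, rng=None, ref=0):
    d = np.linalg.norm(array.positions - source, axis=1) * 1e-3  # m
    toas = d / c
    if jitter > 0:
        toas = toas + rng.normal(0.0, jitter, size=len(toas))
    return pa.tdoas_from_toas(toas, reference=ref, c=c)


class TestSolvePosition:
    def test_centroid_of_symmetric_array(self):
        positions = np.array(
            [
                [10.0, 0.0, 0.0],
                [-10.0, 0.0, 0.0],
                [0.0, 10.0, 0.0],
                [0.0, -10.0, 0.0],
                [0.0, 0.0, 10.0],
                [0.0, 0.0, -10.0],
            ]
        )
        array = pa.SensorArray(positions=positions)
        tdoas = pa.TDOASet(delta_t=np.zeros(6), reference=0, c=1500.0)
        res = pa.solve_position(array, tdoas)
        assert res.converged
        np.testing.assert_allclose(res.position, [0.0, 0.0, 0.0], atol=1e-6)

    def test_table1_exact_recovery(self, table1_array):
        """Noiseless TDOAs synthesised from the published source position
        are inverted to < 1e-6 mm (forward-model self-consistency)."""
        tdoas = synthetic_tdoas(table1_array, pa.TABLE1_SOURCE)
        res = pa.solve_position(table1_array, tdoas, init=np.array([-50.0, 10.0, 150.0]))
        assert res.converged
        assert pa.localization_error(res, pa.TABLE1_SOURCE) < 1e-6

    def test_exact_recovery_inside_convex_hull(self, table1_array):
        rng = np.random.default_rng(3)
        span = table1_array.positions.max(axis=0) - table1_array.positions.min(axis=0)
        lo = table1_array.positions.min(axis=0) + 0.1 * span
        hi = table1_array.positions.max(axis=0) - 0.1 * span
        for _ in range(5):
            src = rng.uniform(lo, hi)
            tdoas = synthetic_tdoas(table1_array, src)
            res = pa.solve_position(table1_array, tdoas)
            assert pa.localization_error(res, src) < 1e-6

    def test_three_sensors_refused(self):
        with pytest.raises(ValueError, match="4 sensors"):
            pa.SensorArray(positions=np.zeros((3, 3)))

    def test_coplanar_sensors_refused(self):
        flat = np.array(
            [[0.0, 0.0, 5.0], [10.0, 0.0, 5.0], [0.0, 10.0, 5.0], [10.0, 10.0, 5.0]]
        )
        with pytest.raises(ValueError, match="coplanar"):
            pa.SensorArray(positions=flat)

    def test_four_wellconditioned_sensors_solve(self):
        positions = np.array(
            [
                [0.0, 0.0, 0.0],
                [40.0, 0.0, 0.0],
                [0.0, 40.0, 0.0],
                [0.0, 0.0, 40.0],
            ]
        )
        array = pa.SensorArray(positions=positions)
        src = np.array([12.0, 9.0, 14.0])
        res = pa.solve_position(array, synthetic_tdoas(array, src))
        assert pa.localization_error(res, src) < 1e-6

    def test_translation_equivariance(self, table1_array):
        """Translating sensors and source together leaves the error field
        unchanged."""
        rng = np.random.default_rng(5)
        shift = np.array([37.0, -12.0, 64.0])
        src = pa.TABLE1_SOURCE
        toas = synthetic_tdoas(table1_array, src)
        jit = rng.normal(0.0, 5e-8, size=len(table1_array))
        jit -= jit[0]
        noisy = pa.TDOASet(delta_t=toas.delta_t + jit, reference=0, c=1500.0)
        res1 = pa.solve_position(table1_array, noisy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            moved = pa.SensorArray(positions=table1_array.positions + shift)
        res2 = pa.solve_position(moved, noisy)
        e1 = pa.localization_error(res1, src)
        e2 = pa.localization_error(res2, src + shift)
        assert e1 == pytest.approx(e2, rel=1e-4, abs=1e-9)

    def test_error_degrades_monotonically_with_jitter(self, table1_array):
        """Mean reconstruction error over 50 seeded trials grows with the
        TOA jitter level."""
        rng = np.random.default_rng(42)
        means = []
        for sigma in (0.0, 1e-8, 5e-8, 1e-7):
            errs = []
            for _ in range(50):
                tdoas = synthetic_tdoas(
                    table1_array, pa.TABLE1_SOURCE, jitter=sigma, rng=rng
                )
                res = pa.solve_position(table1_array, tdoas)
                errs.append(pa.localization_error(res, pa.TABLE1_SOURCE))
            means.append(np.mean(errs))
        assert np.all(np.diff(means) > 0)

    def test_tdoa_reference_entry_must_be_zero(self):
        with pytest.raises(ValueError):
            pa.TDOASet(delta_t=np.array([1e-6, 0.0, 0.0, 0.0]), reference=0)


class TestLocalizationError:
    def test_identical_points(self):
        assert pa.localization_error(np.zeros(3), np.zeros(3)) == 0.0

    def test_unit_axis_offset(self):
        assert pa.localization_error(
            np.array([1.0, 0.0, 0.0]), np.zeros(3)
        ) == pytest.approx(1.0)

    def test_published_pair_distance(self):
        """Distance between the published reconstruction and the published
        source is ~0.99 mm, consistent with the 'one millimetre or below'
        accuracy statement."""
        from protoacoustic.scene import TABLE1_RECONSTRUCTED

        err = pa.localization_error(TABLE1_RECONSTRUCTED, pa.TABLE1_SOURCE)
        assert err == pytest.approx(0.99, abs=0.01)
        assert err <= 1.0
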
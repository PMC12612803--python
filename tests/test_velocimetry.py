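"""Substitution-method estimators: closed forms and delay recovery."""

import numpy as np
import pytest
import scipy.fft as sfft
from hypothesis import given, settings, strategies as st

from porespeed.velocimetry import (envelope, group_delay, phase_delay,
                                   phase_histogram, plane_statistics,
                                   steady_state_phase, substitution_velocity)


def spectral_delay(series: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exact (non-integer) delay via the Fourier shift theorem."""
    n = len(series)
    f = sfft.rfftfreq(n, d=dt)
    return sfft.irfft(sfft.rfft(series) * np.exp(-2j * np.pi * f * tau), n=n)


def pulse(n=4096, dt=2e-9, f=5e5, start_frac=0.25):
    t = np.arange(n) * dt
    s = np.sin(2 * np.pi * f * t)
    s[t >= 1 / f] = 0.0
    return np.roll(s, int(n * start_frac))


class TestSubstitutionVelocity:
    def test_zero_delay_gives_water_speed(self):
        assert substitution_velocity(0.0, 8e-3) == 1500.0

    def test_printed_worked_examples(self):
        # the printed lags are rounded to 3 significant figures, so the
        # back-substituted velocities match the printed ones to ~0.1 %
        v1 = substitution_velocity(-2.79e-6, 8e-3, 1500.0)
        assert v1 == pytest.approx(3145.5, abs=0.1)
        assert v1 == pytest.approx(3147.0, rel=2e-3)
        v2 = substitution_velocity(-1.72e-6, 8e-3, 1500.0)
        assert v2 == pytest.approx(2214.0, abs=0.1)
        assert v2 == pytest.approx(2211.0, rel=2e-3)

    @given(st.floats(min_value=1000.1, max_value=3999.9))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, v):
        d = 8e-3
        delta_t = d / v - d / 1500.0
        assert substitution_velocity(delta_t, d) == pytest.approx(v, rel=1e-12)

    def test_strictly_decreasing_in_delay(self):
        ds = np.linspace(-3e-6, 3e-6, 25)
        vs = [substitution_velocity(d, 8e-3) for d in ds]
        assert np.all(np.diff(vs) < 0)

    def test_nonphysical_delay_rejected(self):
        with pytest.raises(ValueError):
            substitution_velocity(-8e-3 / 1500.0, 8e-3)


class TestEnvelope:
    def test_pure_sinusoid_envelope_is_constant(self):
        t = np.arange(8192) * 1e-8
        e = envelope(1.7 * np.sin(2 * np.pi * 1e6 * t))
        core = e[1000:-1000]
        np.testing.assert_allclose(core, 1.7, rtol=1e-3)

    def test_am_recovery(self):
        n, dt = 16384, 1e-8
        t = np.arange(n) * dt
        a = 1.0 + 0.5 * np.sin(2 * np.pi * 2e4 * t)
        e = envelope(a * np.sin(2 * np.pi * 2e6 * t))
        core = slice(2000, -2000)
        assert np.max(np.abs(e[core] - a[core]) / a[core]) < 0.02

    def test_zero_series(self):
        np.testing.assert_array_equal(envelope(np.zeros(64)), np.zeros(64))

    def test_bounds_signal(self):
        s = pulse()
        assert np.all(envelope(s) >= np.abs(s) - 1e-9)


class TestGroupDelay:
    def test_self_delay_is_zero_with_unit_peak(self):
        s = pulse()
        d = group_delay(s, s, 2e-9)
        assert d.delta_t == pytest.approx(0.0, abs=1e-12)
        assert d.peak_correlation == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [-37, 12, 150])
    def test_integer_sample_shift_recovered_exactly(self, k):
        s = pulse()
        d = group_delay(np.roll(s, k), s, 2e-9)
        assert d.delta_t == pytest.approx(k * 2e-9, abs=1e-15)

    def test_flat_envelope_rejected(self):
        with pytest.raises(ValueError):
            group_delay(np.zeros(128), np.zeros(128), 1e-9)


class TestPhaseDelay:
    def test_self_delay_is_zero(self):
        s = pulse()
        assert phase_delay(s, s, 2e-9, 5e5).delta_t == pytest.approx(0.0,
                                                                     abs=1e-15)

    @pytest.mark.parametrize("f_c", [2.5e5, 5e5, 7.5e5])
    @pytest.mark.parametrize("tau", [3.21e-7, -2.5e-7])
    def test_pure_spectral_delay_recovered(self, f_c, tau):
        s = pulse(f=f_c)
        sig = spectral_delay(s, 2e-9, tau)
        d = phase_delay(sig, s, 2e-9, f_c)
        assert d.delta_t == pytest.approx(tau, rel=1e-6)

    def test_sign_convention_later_is_positive(self):
        s = pulse()
        d = phase_delay(np.roll(s, 50), s, 2e-9, 5e5)
        assert d.delta_t > 0

    def test_out_of_band_carrier_rejected(self):
        s = pulse()
        with pytest.raises(ValueError):
            phase_delay(s, s, 2e-9, 1e9)

    def test_agrees_with_group_delay_on_pure_delay(self):
        s = pulse()
        tau = 1.234e-7
        sig = spectral_delay(s, 2e-9, tau)
        dg = group_delay(sig, s, 2e-9).delta_t
        dp = phase_delay(sig, s, 2e-9, 5e5).delta_t
        assert abs(dg - dp) <= 2e-9  # within one sample refinement step


class TestSteadyStatePhase:
    dt = 1e-9
    f = 5e5
    duration = 80e-6

    def cw(self, tau=0.0):
        t = np.arange(int(self.duration / self.dt) + 100) * self.dt
        return np.sin(2 * np.pi * self.f * (t - tau))

    def test_identical_signals_zero_phase(self):
        s = self.cw()
        assert steady_state_phase(s, s, self.dt, self.f, self.duration) == \
            pytest.approx(0.0, abs=1e-6)

    def test_quarter_period_delay(self):
        tau = 1 / self.f / 4
        phi = steady_state_phase(self.cw(tau), self.cw(), self.dt, self.f,
                                 self.duration)
        assert phi == pytest.approx(np.pi / 2, abs=1e-3)

    def test_full_period_wraps_to_zero(self):
        tau = 1 / self.f
        phi = steady_state_phase(self.cw(tau), self.cw(), self.dt, self.f,
                                 self.duration)
        assert min(phi, 2 * np.pi - phi) == pytest.approx(0.0, abs=1e-3)

    def test_short_record_rejected(self):
        s = self.cw()[:1000]
        with pytest.raises(ValueError):
            steady_state_phase(s, s, self.dt, self.f, self.duration)


class TestPlaneStatistics:
    def test_constant_field(self):
        assert plane_statistics(np.full((4, 4), 3.0)) == (3.0, 0.0)

    def test_two_pixel_field(self):
        mean, std = plane_statistics(np.array([2.0, 6.0]))
        assert (mean, std) == (4.0, 2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(13, 17))
        mean, std = plane_statistics(f)
        assert mean == pytest.approx(f.sum() / f.size)
        assert std == pytest.approx(
            np.sqrt(((f - f.mean()) ** 2).sum() / f.size))


class TestPhaseHistogram:
    def test_constant_phase_single_bin_goodman_pass(self):
        h = phase_histogram(np.full(1000, 1.3))
        assert np.count_nonzero(h.probabilities) == 1
        assert h.goodman_pass
        assert h.probabilities.sum() == pytest.approx(1.0)

    def test_uniform_phases_fail_goodman(self):
        rng = np.random.default_rng(0)
        h = phase_histogram(rng.uniform(0, 2 * np.pi, size=65536))
        np.testing.assert_allclose(h.probabilities, 1 / 16, atol=0.01)
        assert not h.goodman_pass

    def test_offset_invariance_of_mean_shift(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 0.1, size=4096) % (2 * np.pi)
        b = (a + 0.7) % (2 * np.pi)

        def circ_mean(ph, off):
            h = phase_histogram(ph, offset=off)
            centers = (np.arange(16) + 0.5) * h.bin_width
            ang = np.angle(np.sum(h.probabilities *
                                  np.exp(1j * (centers - off))))
            return ang

        for off in (0.0, 0.5, 2.0):
            shift = (circ_mean(b, off) - circ_mean(a, off)) % (2 * np.pi)
            assert shift == pytest.approx(0.7, abs=0.05)
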
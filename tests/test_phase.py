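"""Detrending, smoothing, and instantaneous phase/amplitude estimation."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from vertexdyn import phase as ph
from vertexdyn import synthetic as syn

DT = 3.0


def _sinusoid(period=150.0, amp=3.5, mean=35.0, duration=600.0, dt=DT, trend=0.0):
    t = np.arange(0.0, duration, dt)
    return t, mean + amp * np.sin(2 * np.pi * t / period) + trend * t


class TestDetrend:
    def test_constant_maps_to_zero(self):
        out = ph.detrend(np.full(300, 42.0), DT)
        assert np.abs(out).max() < 1e-9 * 42.0

    def test_linear_trend_removed(self):
        """The ramp's contribution to the detrended output (difference with
        the trend-free twin) carries under 5% of the original slope."""
        t, x_trend = _sinusoid(trend=0.01)
        _, x_flat = _sinusoid(trend=0.0)
        resid = ph.detrend(x_trend, DT) - ph.detrend(x_flat, DT)
        core = slice(40, -40)
        slope = np.polyfit(t[core], resid[core], 1)[0]
        assert abs(slope) < 0.05 * 0.01

    def test_sinusoid_attenuation_closed_form(self):
        """Subtracting the Gaussian-filtered copy leaves the oscillation
        scaled by 1 - exp(-2 pi^2 sigma^2 / T^2)."""
        t, x = _sinusoid(period=150.0, amp=1.0, mean=0.0)
        out = ph.detrend(x, DT, sigma_s=60.0)
        expected = 1.0 - np.exp(-2 * np.pi ** 2 * 60.0 ** 2 / 150.0 ** 2)
        core = slice(50, -50)
        meas = np.sqrt(2 * np.mean(out[core] ** 2))
        assert meas == pytest.approx(expected, rel=0.02)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            ph.detrend(np.ones(50), DT)


class TestSmooth:
    def test_cubic_passes_through(self):
        t = np.arange(200, dtype=float)
        x = 2.0 + 0.3 * t - 0.01 * t ** 2 + 1e-4 * t ** 3
        assert np.allclose(ph.smooth(x, DT), x, atol=1e-9 * np.abs(x).max())

    def test_noise_variance_reduced_by_coefficient_norm(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, 200000)
        win = ph.sg_window_frames(DT)
        expected = np.sum(savgol_coeffs(win, 3) ** 2)
        out = ph.smooth(x, DT)
        assert np.var(out[win:-win]) == pytest.approx(expected, rel=0.05)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ph.smooth(np.ones(5), DT)

    def test_noisy_sinusoid_recovered(self):
        rng = np.random.default_rng(1)
        t, clean = _sinusoid(amp=3.5, mean=0.0)
        noisy = clean + rng.normal(0, 3.5 / 5, len(clean))
        out = ph.smooth(noisy, DT)
        assert np.corrcoef(out, clean)[0, 1] > 0.99


class TestInstantaneousPhase:
    def test_convention_zero_at_trough_180_at_peak(self):
        t, areas, true_ph = syn.make_oscillating_areas(3, 600, DT, snr=0, seed=2)
        for i in range(3):
            tr = ph.phase_from_area(areas[i], DT)
            d = (tr.phase_deg - true_ph[i] + 180.0) % 360.0 - 180.0
            core = slice(10, -10)
            # exact convention at extrema: |phase error| < 2 deg wherever the
            # true phase sits at a trough (0) or peak (+-180)
            tp = true_ph[i][core]
            at_extremum = (np.abs(tp) < 6.0) | (np.abs(np.abs(tp) - 180.0) < 6.0)
            assert np.abs(d[core][at_extremum]).max() < 2.0
            assert np.sqrt(np.mean(d[core] ** 2)) < 5.0

    def test_contraction_has_negative_area_slope(self):
        t, areas, _ = syn.make_oscillating_areas(1, 600, DT, snr=0, seed=3)
        tr = ph.phase_from_area(areas[0], DT)
        dA = np.gradient(tr.smoothed)
        phase = tr.phase_deg[5:-5]
        dA = dA[5:-5]
        away_from_extrema = np.minimum(np.abs(phase), 180 - np.abs(phase)) > 10
        sign_ok = np.sign(dA) == np.sign(phase)
        assert sign_ok[away_from_extrema].mean() >= 0.95

    def test_amplitude_equals_sinusoid_amplitude(self):
        t, areas, _ = syn.make_oscillating_areas(1, 600, DT, amplitude=0.1,
                                                 mean_area_um2=35.0, snr=0, seed=4)
        tr = ph.phase_from_area(areas[0], DT)
        mid = slice(20, -20)
        assert np.abs(tr.amplitude[mid] - 3.5).max() / 3.5 < 0.05

    def test_noisy_phase_rmse_under_15_deg(self):
        t, areas, true_ph = syn.make_oscillating_areas(20, 600, DT, snr=5, seed=5)
        errs = []
        for i in range(20):
            tr = ph.phase_from_area(areas[i], DT)
            d = (tr.phase_deg - true_ph[i] + 180.0) % 360.0 - 180.0
            errs.append(d[10:-10])
        rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rmse < 15.0

    def test_phase_recovery_unbiased(self):
        t, areas, true_ph = syn.make_oscillating_areas(40, 600, DT, snr=5, seed=6)
        biases = []
        for i in range(40):
            tr = ph.phase_from_area(areas[i], DT)
            d = (tr.phase_deg - true_ph[i] + 180.0) % 360.0 - 180.0
            biases.append(np.mean(d[10:-10]))
        assert abs(np.mean(biases)) < 3.0

    def test_hilbert_fallback_agrees(self):
        t, areas, _ = syn.make_oscillating_areas(3, 600, DT, snr=0, seed=7)
        for i in range(3):
            a = ph.phase_from_area(areas[i], DT)
            b = ph.phase_from_area(areas[i], DT, method="hilbert")
            d = (a.phase_deg - b.phase_deg + 180.0) % 360.0 - 180.0
            assert np.sqrt(np.mean(d[10:-10] ** 2)) < 10.0

    def test_monotone_signal_rejected(self):
        x = np.linspace(0, 10, 300)
        with pytest.raises(ValueError):
            ph.instantaneous_phase_amplitude(x, DT)


class TestSegmentCycles:
    def _trace(self, unwrapped):
        unwrapped = np.asarray(unwrapped, dtype=float)
        wrapped = (unwrapped + 180.0) % 360.0 - 180.0
        return ph.PhaseTrace(wrapped, unwrapped, np.ones_like(unwrapped),
                             unwrapped, unwrapped, DT)

    def test_three_periods_give_two_or_three_cycles(self):
        t, areas, _ = syn.make_oscillating_areas(1, 460, DT, snr=0, seed=8,
                                                 period_range_s=(150.0, 150.0))
        tr = ph.phase_from_area(areas[0], DT)
        cycles, _ = ph.segment_cycles(tr)
        assert 2 <= len(cycles) <= 3
        for a, b in cycles:
            assert tr.unwrapped_deg[b - 1] - tr.unwrapped_deg[a] == pytest.approx(
                360.0, abs=25.0)

    def test_constant_phase_gives_no_cycles(self):
        cycles, _ = ph.segment_cycles(self._trace(np.full(100, 17.0)))
        assert cycles == []

    def test_jump_artifact_masks_frames(self):
        u = np.concatenate([np.linspace(-180, 170, 50),
                            np.linspace(170 + 250, 170 + 250 + 350, 50)])
        cycles, mask = ph.segment_cycles(self._trace(u))
        assert not mask[49] and not mask[50]
        for a, b in cycles:
            assert not (a <= 49 < b)
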
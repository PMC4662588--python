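"""Measurement toolkit: spectra, peaks, slopes, bands, plateaus, envelopes."""

import numpy as np
import pytest

import reedbank as rb
from reedbank.analysis import (
    PeakSet,
    PlateauMap,
    Spectrum,
    attenuation_slopes,
    dominant_frequency_map,
    envelope,
    find_peaks,
    impulse_spectrum,
    peak_ratios,
    phase_band_period,
    plateau_ratios,
    plateau_values,
)
from reedbank.timedomain import Trajectory


def _tone_trajectory(freq_hz, sample_rate, duration, bank=None):
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    if bank is None:
        bank = rb.ReedBank(
            natural_freq_hz=np.array([freq_hz, 2 * freq_hz]), gamma=0.02,
            coupling=np.zeros(1), f0=0.0,
        )
    x = np.vstack([np.sin(2 * np.pi * freq_hz * t)] * bank.n)
    return Trajectory(t, x, np.gradient(x, t, axis=1), bank, None)


class TestImpulseSpectrum:
    def test_pure_tone_peak_recovered_within_grid_resolution(self):
        traj = _tone_trajectory(1000.0, 40000.0, 0.05)
        spec = impulse_spectrum(traj, pad_factor=8)
        ps = find_peaks(spec.magnitude[0], spec.freq_hz, min_prominence_db=3.0,
                        floor_db=20.0)
        main = ps.location[np.argmax(ps.height)]
        assert main == pytest.approx(1000.0, abs=spec.grid_step_hz)

    def test_uncoupled_impulse_line_shape(self):
        bank = rb.ReedBank(
            natural_freq_hz=np.array([1600.0, 1800.0]), gamma=0.025,
            coupling=np.zeros(1), f0=0.0,
        )
        traj = rb.simulate_impulse(bank, 0.25)
        spec = impulse_spectrum(traj)
        for j, fj in enumerate(bank.natural_freq_hz):
            mag = spec.magnitude[j]
            peak_f = spec.freq_hz[np.argmax(mag)]
            assert peak_f == pytest.approx(fj, rel=0.005)
            half = mag >= mag.max() / np.sqrt(2)
            bw = spec.freq_hz[half][-1] - spec.freq_hz[half][0]
            assert bw == pytest.approx(0.025 * fj, rel=0.1)

    def test_parseval_energy_match(self, impulse_traj_k200):
        """Per-reed time-domain energy equals spectral energy (pad aside)."""
        traj = impulse_traj_k200
        spec = impulse_spectrum(traj, pad_factor=1)
        n = traj.time_s.size
        for reed in (50, 100, 150):
            x = traj.displacement[reed]
            e_time = np.sum(x**2)
            mag = spec.magnitude[reed]
            # rfft Parseval: DC/Nyquist bins counted once, others twice
            e_freq = (2 * np.sum(mag**2) - mag[0] ** 2 - mag[-1] ** 2 * (n % 2 == 0)) / n
            assert e_freq == pytest.approx(e_time, rel=0.01)

    def test_forced_trajectory_rejected(self, wilson_2500):
        traj = rb.simulate_forced(wilson_2500, rb.DriveSpec(50.0, 0.05))
        with pytest.raises(ValueError):
            impulse_spectrum(traj)


class TestFindPeaks:
    def test_single_parabola_vertex(self):
        axis = np.linspace(0.0, 10.0, 101)
        series = 10.0 ** (-((axis - 4.96) ** 2) / 20.0)
        ps = find_peaks(series, axis, min_prominence_db=0.1)
        assert len(ps) == 1
        assert ps.location[0] == pytest.approx(4.96, abs=1e-6)

    def test_two_gaussians_20db_apart(self):
        axis = np.linspace(0.0, 100.0, 2001)
        series = np.exp(-((axis - 30.0) ** 2) / 8.0) + 0.1 * np.exp(
            -((axis - 70.0) ** 2) / 8.0
        )
        ps = find_peaks(series, axis, min_prominence_db=1.0)
        assert len(ps) == 2
        np.testing.assert_allclose(ps.location, [30.0, 70.0], atol=0.1)
        assert 20 * np.log10(ps.height[0] / ps.height[1]) == pytest.approx(
            20.0, abs=0.1
        )

    def test_spatial_profile_has_main_secondary_and_ripples(
        self, spatial_response_k200, greenwood_k200
    ):
        ps = find_peaks(
            spatial_response_k200.amplitude, greenwood_k200.natural_freq_hz,
            min_prominence_db=0.5,
        )
        assert len(ps) >= 3  # main + secondary + at least one ripple
        assert ps.location[-1] == pytest.approx(1726.0, abs=5.0)

    def test_all_zero_series_yields_empty_set(self):
        ps = find_peaks(np.zeros(10), np.arange(10.0))
        assert len(ps) == 0

    def test_floor_filter_drops_deep_peaks(self):
        axis = np.linspace(0.0, 100.0, 2001)
        series = np.exp(-((axis - 30.0) ** 2) / 8.0) + 1e-3 * np.exp(
            -((axis - 70.0) ** 2) / 8.0
        )
        assert len(find_peaks(series, axis, floor_db=40.0)) == 1
        assert len(find_peaks(series, axis, floor_db=80.0)) == 2


class TestPeakRatios:
    def test_geometric_train_has_constant_ratio(self):
        loc = 1000.0 * 1.05 ** np.arange(5)
        ps = PeakSet(loc, np.ones(5), np.ones(5))
        np.testing.assert_allclose(peak_ratios(ps), 1.05, rtol=1e-12)

    def test_single_peak_yields_empty(self):
        ps = PeakSet(np.array([5.0]), np.array([1.0]), np.array([1.0]))
        assert peak_ratios(ps).size == 0


class TestAttenuationSlopes:
    def test_power_law_profile_recovered_exactly(self):
        """Amplitude ~ (f/f0)^(+-s) has slope 20*s*log10(2) = 6.02*s dB/oct."""
        freqs = np.linspace(1000.0, 2000.0, 201)
        j = 100
        f_peak = freqs[j]
        s_low, s_high = 12.0, 40.0
        amp = np.where(
            freqs <= f_peak,
            (freqs / f_peak) ** s_low,
            (freqs / f_peak) ** -s_high,
        )
        bank = rb.ReedBank(freqs, 0.02, np.zeros(200), f0=0.0)
        resp = rb.ComplexResponse(amp.astype(complex), f_peak, bank)
        lo, hi = attenuation_slopes(resp, j, fit_range_db=(3.0, 23.0))
        assert lo == pytest.approx(20 * s_low * np.log10(2), rel=1e-3)
        assert hi == pytest.approx(20 * s_high * np.log10(2), rel=1e-3)

    def test_symmetric_peak_has_equal_slopes(self):
        freqs = np.geomspace(1000.0, 2000.0, 201)
        j = 100
        logr = np.log2(freqs / freqs[j])
        amp = 10.0 ** (-np.abs(logr) * 10.0)
        bank = rb.ReedBank(freqs, 0.02, np.zeros(200), f0=0.0)
        resp = rb.ComplexResponse(amp.astype(complex), freqs[j], bank)
        lo, hi = attenuation_slopes(resp, j)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_edge_reed_rejected(self, spatial_response_k200):
        with pytest.raises(ValueError):
            attenuation_slopes(spatial_response_k200, 0)


class TestPhaseBands:
    def test_synthetic_minima_every_30_hz(self):
        freqs = np.arange(1500.0, 2000.0, 2.5)
        # rising envelope peaking at 1950 Hz, modulated by 30 Hz-period ripples
        base = np.exp(-(((freqs - 1950.0) / 150.0) ** 2))
        amp = base * (1.0 + 0.4 * np.cos(2 * np.pi * freqs / 30.0))
        bank = rb.ReedBank(freqs, 0.02, np.zeros(freqs.size - 1), f0=0.0)
        resp = rb.ComplexResponse(amp.astype(complex), 1950.0, bank)
        assert phase_band_period(resp) == pytest.approx(30.0, abs=1.0)

    def test_uncoupled_profile_has_no_bands(self):
        bank = rb.build_greenwood_bank(kappa=0.0)
        resp = rb.solve_phasors(bank, 1750.0)
        with pytest.raises(ValueError):
            phase_band_period(resp)

    def test_stronger_coupling_widens_bands(
        self, spatial_response_k200, greenwood_k400
    ):
        p200 = phase_band_period(spatial_response_k200)
        p400 = phase_band_period(rb.solve_phasors(greenwood_k400, 1750.0))
        assert p400 > p200

    def test_minima_coincide_with_rapid_phase_transitions(
        self, spatial_response_k200, greenwood_k200
    ):
        """The phase gradient is locally maximal at the amplitude minima."""
        _, minima_f = phase_band_period(spatial_response_k200,
                                        return_minima=True)
        freqs = greenwood_k200.natural_freq_hz
        dphase = np.abs(np.diff(spatial_response_k200.phase_lag_cycles))
        for fm in minima_f:
            i = int(np.argmin(np.abs(freqs - fm)))
            window = dphase[max(0, i - 6): i + 6]
            assert dphase[i - 1 : i + 1].max() >= 0.8 * window.max()


class TestPlateaus:
    def test_uncoupled_map_follows_natural_frequencies(self):
        bank = rb.build_linear_bank(1000.0, 2000.0, 51, 0.0, 0.025)
        traj = rb.simulate_impulse(bank, 0.05)
        pmap = dominant_frequency_map(impulse_spectrum(traj))
        np.testing.assert_allclose(
            pmap.dominant_freq_hz, bank.natural_freq_hz, rtol=0.005
        )
        # strictly monotone map clusters into no plateaus
        assert plateau_ratios(pmap).size == 0

    def test_synthetic_staircase_ratio(self):
        levels = np.concatenate(
            [np.full(10, 1000.0), np.full(10, 1100.0), np.full(10, 1210.0)]
        )
        pmap = PlateauMap(levels, grid_step_hz=2.5)
        np.testing.assert_allclose(plateau_ratios(pmap), 1.1, rtol=1e-12)

    def test_single_plateau_yields_empty(self):
        pmap = PlateauMap(np.full(9, 1500.0), grid_step_hz=2.5)
        assert plateau_ratios(pmap).size == 0

    def test_short_runs_are_not_plateaus(self):
        vals = np.array([1000.0, 1000.0, 1500.0, 1500.0, 1500.0])
        pmap = PlateauMap(vals, grid_step_hz=2.5)
        assert plateau_values(pmap, min_run=3).tolist() == [1500.0]

    def test_identical_oscillators_share_map_entry(self):
        bank = rb.ReedBank(
            natural_freq_hz=np.array([1500.0, 1500.000001]), gamma=0.025,
            coupling=np.zeros(1), f0=0.0,
        )
        traj = rb.simulate_impulse(bank, 0.05)
        pmap = dominant_frequency_map(impulse_spectrum(traj))
        assert pmap.dominant_freq_hz[0] == pytest.approx(
            pmap.dominant_freq_hz[1], abs=1e-6
        )


class TestEnvelope:
    def test_beat_of_two_tones(self):
        t = np.arange(0.0, 1.0, 1.0 / 8000.0)
        f = 200.0
        x = np.sin(2 * np.pi * f * t) + np.sin(2 * np.pi * 1.05 * f * t)
        env = envelope(x)
        from scipy.signal import find_peaks as sp_find_peaks

        peaks, _ = sp_find_peaks(env[100:-100])
        spacing = np.mean(np.diff(peaks)) / 8000.0
        assert 1.0 / spacing == pytest.approx(0.05 * f, rel=0.05)

    def test_uncoupled_impulse_envelope_decays_exponentially(self):
        bank = rb.ReedBank(
            natural_freq_hz=np.array([500.0, 900.0]), gamma=0.02,
            coupling=np.zeros(1), f0=0.0,
        )
        traj = rb.simulate_impulse(bank, 0.25)
        env = envelope(traj.displacement[0])
        t = traj.time_s
        # fit down to 1% of the initial envelope: above the integration
        # noise floor and clear of the analytic-signal edge artifacts
        stop = int(np.argmax(env < env.max() * 1e-2))
        sl = slice(500, stop)
        rate = np.polyfit(t[sl], np.log(env[sl]), 1)[0]
        assert rate == pytest.approx(-0.02 * 2 * np.pi * 500.0 / 2, rel=0.02)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.ones(5))


class TestSpectrumValidation:
    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([3.0, 2.0, 1.0]), np.ones((1, 3)))

    def test_ripple_count_grows_with_finer_spacing_and_weaker_coupling(self):
        """More oscillators per frequency span -> more ripples; stronger
        coupling -> fewer, larger ripples."""
        def n_ripples(n_reeds, kappa):
            bank = rb.build_linear_bank(1500.0, 2000.0, n_reeds, kappa, 0.025)
            resp = rb.solve_phasors(bank, 1750.0)
            return len(find_peaks(resp.amplitude, bank.natural_freq_hz,
                                  min_prominence_db=0.5))

        assert n_ripples(201, 2.0e8) > n_ripples(101, 2.0e8)
        assert n_ripples(201, 4.0e8) < n_ripples(201, 1.0e8)
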
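import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soaesim import (ChainConfig, segment_plan, averaged_power_spectrum,
                     normalize_to_reference, summed_spectrum, layered_spectra,
                     spatiotemporal_map, recorded_emission_spectrum,
                     load_recording, reference_peak_density, detect_peaks,
                     simulate)
from soaesim.spectral_analysis import Spectrum


class TestSegmentPlan:
    @pytest.mark.parametrize("record,window,hop,expected", [
        (1600.0, 128.0, 32.0, 47),
        (128.0, 128.0, 32.0, 1),
        (3200.0, 128.0, 32.0, 97),
        (120_000.0, 80.0, 20.0, 5997),
    ])
    def test_counts(self, record, window, hop, expected):
        assert segment_plan(record, window, hop) == expected

    def test_window_longer_than_record(self):
        with pytest.raises(ValueError):
            segment_plan(100.0, 128.0, 32.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(10, 5000), st.floats(1, 500), st.floats(0.5, 200))
    def test_matches_brute_force_enumeration(self, record, window, hop):
        if window > record:
            return
        # enumerate fully contained placements on a fine lattice
        count = 0
        start = 0.0
        while start + window <= record * (1 + 1e-12):
            count += 1
            start += hop
        assert segment_plan(record, window, hop) == count


class TestAveragedPowerSpectrum:
    def test_parseval_on_bin_sinusoid(self):
        si, window = 0.016, 128.0
        t = si * np.arange(int(3200 / si))
        A, f0 = 2.0, 1.0  # 1 kHz sits exactly on the 7.8125-Hz bin grid
        sig = A * np.sin(2 * np.pi * f0 * t)
        freqs, psd = averaged_power_spectrum(sig, si, window, 32.0)
        df = freqs[1] - freqs[0]
        k = np.argmin(np.abs(freqs - f0))
        assert k == np.argmax(psd)
        power = psd[k - 2:k + 3].sum() * df
        assert power == pytest.approx(A**2 / 2, rel=0.01)

    def test_white_noise_variance_shrinks_with_averaging(self):
        rng = np.random.default_rng(7)
        si = 0.016
        sig = rng.normal(size=int(3200 / si))
        # non-overlapping segments: independent periodograms
        _, p_many = averaged_power_spectrum(sig, si, 128.0, 128.0)
        _, p_one = averaged_power_spectrum(sig[:8000], si, 128.0, 128.0)
        n_seg = segment_plan(3200.0, 128.0, 128.0)
        interior = slice(10, -10)
        ratio = p_many[interior].std() / p_one[interior].std()
        assert ratio < 2.0 / np.sqrt(n_seg)

    def test_zero_signal(self):
        _, psd = averaged_power_spectrum(np.zeros(10000), 0.016, 128.0, 32.0)
        assert np.all(psd == 0.0)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            averaged_power_spectrum(np.array([]), 0.016, 128.0, 32.0)


class TestNormalization:
    def test_reference_normalizes_itself_to_zero_db(self):
        """The free-running reference unit's own spectrum peaks at 0 dB."""
        cfg = ChainConfig(N=2, seed=0, t_total=560.0, t_equilibrate=160.0)
        trace = simulate(cfg)
        freqs, psd = averaged_power_spectrum(trace.x[0], 0.016, 128.0, 32.0)
        spec = normalize_to_reference(freqs, psd, cfg, 128.0, 32.0, 10)
        assert spec.power_db.max() == pytest.approx(0.0, abs=1e-9)

    def test_reference_cached(self):
        r1 = reference_peak_density(400.0, 0.016, 128.0, 32.0)
        r2 = reference_peak_density(400.0, 0.016, 128.0, 32.0)
        assert r1 == r2 and r1 > 0


class TestLayeredAndMaps:
    def test_layered_uncoupled_peaks_at_own_frequencies(self, single_unit_trace):
        lay = layered_spectra(single_unit_trace)
        df = lay.freqs_khz[1] - lay.freqs_khz[0]
        for n in (1, 2):
            spec = lay.oscillator(n)
            f_peak = spec.freqs_khz[np.argmax(spec.power_db)]
            f_nat = single_unit_trace.config.freqs_khz[n - 1]
            assert abs(f_peak - f_nat) <= df

    def test_spatiotemporal_map_identity(self, short_uniform_chain):
        m = spatiotemporal_map(short_uniform_chain)
        assert np.array_equal(m, short_uniform_chain.x)

    def test_spatiotemporal_map_normalized(self, short_uniform_chain):
        m = spatiotemporal_map(short_uniform_chain, normalize_amplitude=True)
        assert np.abs(m).max() == pytest.approx(1.0)

    def test_summed_spectrum_metadata(self, short_uniform_chain):
        spec = summed_spectrum(short_uniform_chain)
        assert spec.n_segments == segment_plan(320.0, 128.0, 32.0)
        assert spec.freqs_khz[0] == 0.0
        assert spec.freqs_khz[-1] == pytest.approx(1000 / 0.016 / 2 / 1000)


def _comb_recording(rng, fs=50_000, dur_s=10.0, n_tones=12, f0=1000.0,
                    spacing=240.0, amp=1.0, noise_sd=0.05):
    t = np.arange(int(fs * dur_s)) / fs
    sig = noise_sd * rng.normal(size=t.size)
    for k in range(n_tones):
        sig += amp * np.sin(2 * np.pi * (f0 + k * spacing) * t + rng.uniform(0, 2 * np.pi))
    return sig


class TestRecordedPath:
    def test_record_equals_control_cancels(self):
        rng = np.random.default_rng(0)
        rec = _comb_recording(rng, dur_s=2.0)
        spec = recorded_emission_spectrum(rec, 1 / 50_000, control=rec)
        assert spec.power is not None
        assert np.all(spec.power <= 1e-12)

    def test_comb_spacing_recovered(self):
        """Synthetic emission comb: 12 tones 240 Hz apart over noise."""
        rng = np.random.default_rng(42)
        rec = _comb_recording(rng)
        ctrl = 0.05 * rng.normal(size=rec.size)
        spec = recorded_emission_spectrum(rec, 1 / 50_000, control=ctrl)
        ps = detect_peaks(spec, band_khz=(0.5, 4.2))
        assert ps.count == 12
        assert ps.spacing_mean_hz == pytest.approx(240.0, abs=10.0)

    def test_segmenting_of_long_recording(self):
        # 120 s at 20-us sampling, 80-ms windows, 20-ms hop
        assert segment_plan(120_000.0, 80.0, 20.0) == 5997

    def test_sampling_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        rec = rng.normal(size=50_000)
        with pytest.raises(ValueError):
            recorded_emission_spectrum(rec, 2e-5, control=rec,
                                       control_sample_interval_s=1e-5)

    def test_load_two_column_text(self, tmp_path):
        t = np.arange(2000) * 2e-5
        p = np.sin(2 * np.pi * 1000 * t)
        path = tmp_path / "rec.txt"
        np.savetxt(path, np.column_stack([t, p]))
        data, si = load_recording(path)
        assert si == pytest.approx(2e-5)
        assert np.allclose(data, p)

    def test_load_wav(self, tmp_path):
        from scipy.io import wavfile
        fs = 50_000
        sig = (0.3 * np.sin(2 * np.pi * 1000 * np.arange(fs) / fs))
        path = tmp_path / "rec.wav"
        wavfile.write(path, fs, sig.astype(np.float32))
        data, si = load_recording(path)
        assert si == pytest.approx(1 / fs)
        assert data.size == fs


class TestPhaseGradient:
    def test_uniform_traveling_wave_sign(self):
        """A synthetic wave moving from high to low chain index produces a
        positive adjacent phase gradient."""
        from soaesim import adjacent_phase_differences, ChainConfig, Trace
        cfg = ChainConfig(N=12, t_total=200.0, t_equilibrate=0.0)
        t = 0.016 * np.arange(int(200.0 / 0.016))
        n = np.arange(12)[:, None]
        x = np.cos(2 * np.pi * 1.5 * t[None, :] + 0.4 * n)
        trace = Trace(times=t, x=x, config=cfg, sample_interval=0.016)
        d = adjacent_phase_differences(trace, window_ms=100.0)
        assert np.allclose(d, 0.4, atol=0.05)
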
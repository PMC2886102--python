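import numpy as np
import pytest

from soaesim import (ChainConfig, ChainState, AlphaProfileSpec, NoiseSpec,
                     frequency_ladder, amplitude_profile, intrinsic_rhs,
                     simulate, averaged_power_spectrum)


class TestFrequencyLadder:
    def test_geometric_ladder_values(self):
        f = frequency_ladder(110)
        assert f[0] == 1.0
        assert np.isclose(f[-1], 3 ** (109 / 110))
        assert round(float(f[-1]), 2) == 2.97

    def test_long_chain_keeps_denominator(self):
        f = frequency_ladder(210, 110)
        assert np.isclose(f[-1], 3 ** (209 / 110))
        assert round(float(f[-1]), 2) == 8.06

    def test_exactly_geometric_and_increasing(self):
        f = frequency_ladder(110)
        ratios = f[1:] / f[:-1]
        assert np.all(np.diff(f) > 0)
        assert np.allclose(ratios, 3 ** (1 / 110), rtol=0, atol=1e-14)
        assert round(float(ratios[0]), 4) == 1.0100  # ~1% per unit

    @pytest.mark.parametrize("N,denom", [(0, 110), (-3, 110), (10, 0)])
    def test_invalid_arguments(self, N, denom):
        with pytest.raises(ValueError):
            frequency_ladder(N, denom)


class TestAmplitudeProfile:
    def test_taper18_values(self):
        a = amplitude_profile("taper18", 110)
        assert a[8] == pytest.approx(0.5)       # n = 9 -> 9/18
        assert a[49] == 1.0                      # n = 50, plateau
        assert a[109] == pytest.approx(1 / 18)   # n = 110 -> (111-110)/18

    def test_taper18_plateau_and_symmetry(self):
        a = amplitude_profile("taper18", 110)
        # 74-entry central plateau; the taper formulas also reach 1 at
        # n = 18 and n = 93, so 76 entries equal 1 in total
        assert np.all(a[18:92] == 1.0)
        assert int(np.sum(a == 1.0)) == 76
        # symmetric under n -> 111 - n
        assert np.allclose(a, a[::-1])

    def test_parabolic(self):
        a = amplitude_profile("parabolic", 110)
        assert a[0] == pytest.approx(110 / 3025)
        n = np.arange(1, 111)
        assert np.allclose(a, n * (111 - n) / 3025.0)

    def test_uniform(self):
        assert np.all(amplitude_profile("uniform", 110) == 1.0)

    def test_disordered_reproducible_and_clipped(self):
        a1 = amplitude_profile("disordered", 110, rng_seed=42)
        a2 = amplitude_profile("disordered", 110, rng_seed=42)
        assert np.array_equal(a1, a2)
        # taper preserved at the ends, disorder confined to the center
        taper = amplitude_profile("taper18", 110)
        assert np.array_equal(a1[:18], taper[:18])
        assert np.array_equal(a1[92:], taper[92:])
        center = a1[18:92]
        assert abs(center.mean() - 1.0) < 0.02
        assert np.all(center >= 0)
        # a huge sd exercises the clip at zero
        wild = amplitude_profile("disordered", 110, rng_seed=0, disorder_sd=5.0)
        assert np.all(wild >= 0)

    def test_invalid_kind_and_size(self):
        with pytest.raises(ValueError):
            amplitude_profile("sigmoid", 110)
        with pytest.raises(ValueError):
            amplitude_profile("taper18", 64)
        with pytest.raises(ValueError):
            amplitude_profile("parabolic", 210)


class TestChainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(N=1)
        with pytest.raises(ValueError):
            ChainConfig(gamma=-0.1)
        with pytest.raises(ValueError):
            ChainConfig(t_total=100.0, t_equilibrate=200.0)
        with pytest.raises(ValueError):
            ChainConfig(delta=0.5, F=0.0)

    def test_derived_arrays(self):
        cfg = ChainConfig(N=110)
        assert np.allclose(cfg.omegas, 2 * np.pi * cfg.freqs_khz)
        assert np.allclose(cfg.omegas / cfg.mus, 5.0)
        assert np.all(np.diff(cfg.omegas) > 0)

    def test_natural_unit_conversion(self):
        cfg = ChainConfig(gamma=1.0, delta=0.2, F=1.8,
                          noise=NoiseSpec(sd=0.1))
        assert cfg.gamma_eff == pytest.approx(2 * np.pi)
        assert cfg.delta_eff == pytest.approx(0.4 * np.pi)
        assert cfg.noise_sd_eff == pytest.approx(0.2 * np.pi)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = ChainConfig(N=110, gamma=1.0, delta=0.2, F=1.8,
                          alpha_profile=AlphaProfileSpec(kind="taper18"),
                          noise=NoiseSpec(sd=0.1, update_interval=0.016),
                          seed=77)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert ChainConfig.from_yaml(p) == cfg


class TestIntrinsicDynamics:
    def test_origin_is_fixed_point(self):
        cfg = ChainConfig(N=4)
        state = ChainState(x=np.zeros(4), y=np.zeros(4))
        dx, dy = intrinsic_rhs(state, cfg)
        assert np.all(dx == 0) and np.all(dy == 0)

    def test_dimension_mismatch(self):
        cfg = ChainConfig(N=4)
        state = ChainState(x=np.zeros(3), y=np.zeros(3))
        with pytest.raises(ValueError):
            intrinsic_rhs(state, cfg)

    def test_limit_cycle_amplitude_and_frequency(self, single_unit_trace):
        """Weakly nonlinear limit: amplitude ~ 2 sqrt(alpha), frequency at f_n."""
        x = single_unit_trace.x[0]
        assert np.abs(x).max() == pytest.approx(2.0, rel=0.02)
        freqs, psd = averaged_power_spectrum(x, 0.016, 128.0, 32.0)
        f_peak = freqs[np.argmax(psd)]
        assert abs(f_peak - 1.0) <= 0.01  # within 1% of 1 kHz

    def test_nearly_sinusoidal_third_harmonic(self, single_unit_trace):
        """omega/mu = 5 keeps the third harmonic >= 20 dB below the fundamental."""
        x = single_unit_trace.x[0]
        freqs, psd = averaged_power_spectrum(x, 0.016, 128.0, 32.0)
        p1 = psd[np.argmin(np.abs(freqs - 1.0))]
        i3 = np.argmin(np.abs(freqs - 3.0))
        p3 = psd[i3 - 2:i3 + 3].max()
        assert 10 * np.log10(p1 / p3) >= 20.0

    @pytest.mark.parametrize("alpha", [0.25, 1.0, 4.0])
    def test_amplitude_scales_as_sqrt_alpha(self, alpha):
        cfg = ChainConfig(N=2, seed=1, t_total=360.0, t_equilibrate=160.0)
        alphas = np.array([alpha, alpha])
        from soaesim.sim_engine import initialize, _simulate_deterministic
        state = initialize(cfg, seed=1, alphas=alphas)
        times = cfg.t_equilibrate + 0.016 * np.arange(
            int(round(cfg.record_ms / 0.016)))
        x = _simulate_deterministic(cfg, state, alphas, cfg.omegas, cfg.mus,
                                    0.0, times, 1e-6, 1e-9)
        assert np.abs(x[0]).max() == pytest.approx(2 * np.sqrt(alpha), rel=0.05)

    def test_zero_alpha_does_not_oscillate(self):
        """alpha = 0 units decay from small perturbations (silent taper ends)."""
        cfg = ChainConfig(N=2, seed=1, t_total=200.0, t_equilibrate=0.0)
        from soaesim.sim_engine import _simulate_deterministic
        from soaesim import ChainState
        state = ChainState(x=np.array([0.1, 0.1]), y=np.array([0.0, 0.0]))
        alphas = np.zeros(2)
        times = 0.016 * np.arange(int(round(200.0 / 0.016)))
        x = _simulate_deterministic(cfg, state, alphas, cfg.omegas, cfg.mus,
                                    0.0, times, 1e-6, 1e-9)
        # at alpha = 0 the linear part is marginal and only the cubic term
        # damps, so decay from small amplitude is slow: assert the envelope
        # shrinks and never grows
        env = np.abs(x).max(axis=0)
        assert env.max() <= 0.1 * 1.001
        assert np.abs(x[:, -500:]).max() < 0.09
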
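"""Simulator checks: waveform fidelity, I/Q physics, quantization, determinism."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import periodogram

import respiradar as rr
from conftest import steady_scenario


def spectral_peak_hz(values, fs):
    f, p = periodogram(values - np.mean(values), fs=fs)
    return f[np.argmax(p)]


def count_cycles_by_crossings(displacement, level):
    """Independent oracle: upward crossings of the mid-excursion level."""
    above = displacement > level
    return int(np.sum(~above[:-1] & above[1:]))


class TestGenerateDisplacement:
    def test_fundamental_matches_rate(self):
        ref = rr.generate_displacement(steady_scenario(60.0), sampling_rate=1092.0)
        assert spectral_peak_hz(ref.displacement, 1092.0) == pytest.approx(1.0, abs=1 / 60)

    def test_zero_amplitude_gives_flat_trace(self):
        sc = steady_scenario(60.0, displacement_amplitude=0.0)
        ref = rr.generate_displacement(sc, sampling_rate=1092.0)
        assert np.all(ref.displacement == 0.0)

    def test_cycle_count_matches_zero_crossing_oracle(self):
        sc = rr.RespirationScenario(
            segments=((10.0, 90.0), (10.0, 54.0)), rate_jitter_sd=0.0, seed=0
        )
        ref = rr.generate_displacement(sc, sampling_rate=1092.0)
        n_cycles = count_cycles_by_crossings(ref.displacement, sc.displacement_amplitude / 2)
        assert abs(n_cycles - 24) <= 1  # 15 cycles at 90 bpm + 9 at 54 bpm

    def test_peak_to_peak_equals_amplitude(self):
        ref = rr.generate_displacement(steady_scenario(60.0), sampling_rate=1092.0)
        assert np.ptp(ref.displacement) == pytest.approx(1e-3, rel=1e-4)

    def test_per_segment_spectral_peak_within_one_bin(self):
        sc = rr.RespirationScenario(
            segments=((40.0, 90.0), (40.0, 55.0)), rate_jitter_sd=0.0, seed=2
        )
        ref = rr.generate_displacement(sc, sampling_rate=1092.0)
        half = len(ref.times) // 2
        for chunk, rate in ((slice(None, half), 90.0), (slice(half, None), 55.0)):
            peak = spectral_peak_hz(ref.displacement[chunk], 1092.0)
            assert abs(peak - rate / 60.0) <= 1 / 40.0 + 1e-9

    def test_empty_scenario_rejected(self):
        with pytest.raises(ValueError, match="empty scenario"):
            rr.RespirationScenario(segments=())


class TestSimulateIQ:
    def test_zero_phase_operating_point(self, clean_config):
        ref = rr.ReferenceTrace(times=np.arange(100) / 1092.0, displacement=np.zeros(100))
        cfg = dataclasses.replace(clean_config, nominal_distance_d0=0.0, residual_phase_phi=0.0)
        iq = rr.simulate_iq(ref, cfg)
        assert np.allclose(iq.i_channel, 0.0) and np.allclose(iq.q_channel, 1.0)

    def test_envelope_conserved_under_quantization(self):
        sc = steady_scenario(60.0, duration=10.0)
        cfg = rr.RadarConfig(noise_sd=0.0, adc_bits=10, residual_phase_phi=1.0)
        iq, _ = rr.simulate_recording(sc, cfg)
        env_err = np.abs(iq.i_channel**2 + iq.q_channel**2 - 1.0)
        assert env_err.max() < 2**-8

    def test_quarter_wavelength_step_flips_both_channels(self, clean_config):
        lam = clean_config.wavelength
        n = 200
        disp = np.concatenate([np.zeros(n), np.full(n, lam / 4)])
        ref = rr.ReferenceTrace(times=np.arange(2 * n) / 1092.0, displacement=disp)
        cfg = dataclasses.replace(clean_config, residual_phase_phi=0.7)
        iq = rr.simulate_iq(ref, cfg)
        assert np.allclose(iq.i_channel[n:], -iq.i_channel[:n])
        assert np.allclose(iq.q_channel[n:], -iq.q_channel[:n])

    def test_demodulated_phase_linear_in_displacement(self, clean_config):
        ref = rr.generate_displacement(steady_scenario(60.0), 1092.0)
        cfg = dataclasses.replace(clean_config, residual_phase_phi=0.3)
        iq = rr.simulate_iq(ref, cfg)
        phase = np.unwrap(np.arctan2(iq.i_channel, iq.q_channel))
        r = np.corrcoef(phase, ref.displacement)[0, 1]
        assert r > 0.9999

    def test_non_uniform_grid_rejected(self, clean_config):
        t = np.array([0.0, 0.1, 0.3, 0.35])
        ref = rr.ReferenceTrace(times=t, displacement=np.zeros(4))
        with pytest.raises(ValueError, match="non-uniform sampling"):
            rr.simulate_iq(ref, clean_config)

    def test_recording_deterministic_given_seed(self, noisy_config):
        sc = steady_scenario(80.0, jitter=2.0, seed=4)
        iq1, ref1 = rr.simulate_recording(sc, noisy_config, seed=4)
        iq2, ref2 = rr.simulate_recording(sc, noisy_config, seed=4)
        assert np.array_equal(iq1.i_channel, iq2.i_channel)
        assert np.array_equal(iq1.q_channel, iq2.q_channel)
        assert np.array_equal(ref1.displacement, ref2.displacement)


class TestQuantizeADC:
    def test_grid_points_map_to_themselves(self):
        out = rr.quantize_adc(np.array([-1.0, 1.0]), bits=1, full_scale=2.0)
        assert np.array_equal(out, [-1.0, 1.0])

    def test_level_count_bounded(self):
        sweep = np.linspace(-1, 1, 50_000)
        out = rr.quantize_adc(sweep, bits=10, full_scale=1.0)
        assert len(np.unique(out)) <= 1024

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).uniform(-2, 2, size=256)
        once = rr.quantize_adc(x, bits=10, full_scale=1.0)
        assert np.array_equal(rr.quantize_adc(once, bits=10, full_scale=1.0), once)

    def test_in_range_error_bounded(self):
        x = np.random.default_rng(0).uniform(-1, 1, size=1000)
        out = rr.quantize_adc(x, bits=10, full_scale=1.0)
        assert np.max(np.abs(out - x)) <= 1.0 / 2**10 + 1e-12

    def test_disabling_requires_explicit_config(self):
        with pytest.raises(ValueError, match="bits"):
            rr.quantize_adc(np.zeros(3), bits=0, full_scale=1.0)
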
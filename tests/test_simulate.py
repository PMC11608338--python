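"""Trajectory statistics, filtering and noise synthesis."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from channelsim.markov import KineticModel, Topology, stationary_distribution
from channelsim.simulate import (
    NoiseSpectrum,
    SimulationConfig,
    StepResponse,
    apply_step_response,
    bessel_step_response,
    filtered_white_noise,
    noise_from_spectrum,
    scale_to_snr,
    simulate_ideal,
    simulate_recording,
)


class TestIdealTrajectory:
    def test_dwell_law_and_occupancy(self, two_state):
        # k = 100 /s at 100 kHz for 4e6 samples -> ~2000 dwells per class
        cfg = SimulationConfig(n_samples=4_000_000, seed=5)
        ideal = simulate_ideal(two_state, cfg)
        ev = ideal.true_events.retained()
        k = 100.0
        for cls in "CO":
            d = ev.durations_s[ev.classes == cls]
            se = d.std() / np.sqrt(d.size)
            assert abs(d.mean() - 1 / k) < 3 * se
            assert stats.kstest(d, "expon", args=(0, 1 / k)).pvalue > 0.01
        # ergodic occupancy vs stationary law
        pi_open = stationary_distribution(two_state)[1]
        p = ideal.class_per_sample.mean()
        n_dwell = ev.durations_s[ev.classes == "O"].size
        se_p = p * (1 - p) * np.sqrt(2.0 / n_dwell)
        assert abs(p - pi_open) < 3 * max(se_p, 1e-3)

    def test_asymmetric_occupancy(self):
        m = KineticModel(Topology("CO"), np.array([300.0, 100.0]))
        cfg = SimulationConfig(n_samples=2_000_000, seed=8)
        ideal = simulate_ideal(m, cfg)
        assert abs(ideal.class_per_sample.mean() - 0.75) < 0.02

    def test_absorbing_state_rejected(self):
        m = KineticModel(Topology("CO"), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            simulate_ideal(m, SimulationConfig(n_samples=100, seed=0))

    def test_reproducible(self, two_state):
        cfg = SimulationConfig(n_samples=50_000, seed=77)
        a = simulate_ideal(two_state, cfg)
        b = simulate_ideal(two_state, cfg)
        np.testing.assert_array_equal(a.class_per_sample, b.class_per_sample)


class TestStepResponse:
    def test_bessel_shape(self):
        step = bessel_step_response(1e4, 1e5)
        s = step.samples
        assert s[0] == 0.0
        assert s[-1] == 1.0
        peak = np.argmax(s)
        assert np.all(np.diff(s[: peak + 1]) >= 0)  # monotone rise to the peak
        assert s.max() < 1.03  # Bessel: barely any overshoot

    def test_rise_time_matches_corner(self):
        fc, fs = 1e4, 1e5
        s = bessel_step_response(fc, fs).samples
        rise = (np.argmax(s >= 0.9) - np.argmax(s >= 0.1)) / fs
        assert abs(rise - 0.34 / fc) / (0.34 / fc) < 0.15

    def test_near_nyquist_approaches_one_sample_step(self):
        s = bessel_step_response(4.5e4, 1e5).samples
        assert s[2] > 0.85  # essentially settled within a couple of samples

    def test_corner_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bessel_step_response(6e4, 1e5)

    def test_normalization_invariants(self):
        with pytest.raises(ValueError):
            StepResponse(np.array([0.2, 1.0]))
        with pytest.raises(ValueError):
            StepResponse(np.array([0.0, 0.9]))
        raw = np.array([10.0, 11.0, 12.0, 12.0])
        s = StepResponse.from_raw(raw).samples
        assert s[0] == 0.0 and s[-1] == 1.0


class TestApplyStep:
    def test_one_sample_step_is_identity(self):
        x = np.repeat([22000.0, 20000.0, 22000.0], [50, 30, 20])
        ident = StepResponse(np.array([0.0, 1.0]))
        np.testing.assert_array_equal(apply_step_response(x, (22000, 20000), ident), x)

    def test_constant_trace_unchanged(self):
        x = np.full(200, 22000.0)
        step = bessel_step_response(1e4, 1e5)
        np.testing.assert_allclose(apply_step_response(x, (22000, 20000), step), x)

    def test_single_transition_superposition(self):
        step = bessel_step_response(1e4, 1e5)
        t0, n = 100, 300
        x = np.where(np.arange(n) >= t0, 20000.0, 22000.0)
        y = apply_step_response(x, (22000.0, 20000.0), step)
        s = step.samples
        expected = np.full(n, 22000.0)
        for k in range(t0, n):
            j = k - t0 + 1
            expected[k] = 22000.0 + (20000.0 - 22000.0) * (
                s[j] if j < s.size else 1.0
            )
        np.testing.assert_allclose(y, expected, atol=1e-8)


class TestNoise:
    def test_zero_spectrum_gives_silence(self):
        spec = NoiseSpectrum(np.array([0.0, 5e4]), np.array([0.0, 0.0]))
        out = noise_from_spectrum(spec, 1024, 1e5, seed=1)
        np.testing.assert_array_equal(out, np.zeros(1024))

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpectrum(np.array([0.0, 1e4]), np.array([1.0, -1.0]))

    def test_periodogram_follows_spectrum(self):
        # Lorentzian-ish colored spectrum
        f = np.linspace(0, 5e4, 200)
        p = 1.0 / (1.0 + (f / 5e3) ** 2)
        spec = NoiseSpectrum(f, p)
        n, fs = 4096, 1e5
        pxx = np.zeros(n // 2 + 1)
        for s in range(16):
            x = noise_from_spectrum(spec, n, fs, seed=s)
            fr, px = sps.periodogram(x, fs=fs)
            pxx += px
        sel = slice(2, -2)
        target = np.interp(fr[sel], f, p)
        r = np.corrcoef(np.log(pxx[sel]), np.log(target))[0, 1]
        assert r > 0.99

    def test_filtered_white_attenuates(self):
        fc, fs = 1e4, 1e5
        x = filtered_white_noise(fc, fs, 1 << 15, seed=4)
        assert x.var() < 1.0  # low-pass removes power from unit-variance input
        fr, px = sps.welch(x, fs=fs, nperseg=2048)
        passband = px[(fr > 500) & (fr < 0.5 * fc)].mean()
        stop = px[(fr > 2 * fc) & (fr < 2.5 * fc)].mean()
        assert 10 * np.log10(passband / stop) > 20

    def test_filtered_white_deterministic(self):
        a = filtered_white_noise(1e4, 1e5, 4096, seed=9)
        b = filtered_white_noise(1e4, 1e5, 4096, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_scale_to_snr(self, rng):
        noise = rng.standard_normal(10_000)
        out = scale_to_snr(noise, amplitude=2000.0, snr=5.0)
        assert abs(out.std() - 400.0) < 1e-9 * 400.0
        # doubling SNR halves sigma; shape preserved up to a scalar
        half = scale_to_snr(noise, amplitude=2000.0, snr=10.0)
        np.testing.assert_allclose(half, out / 2)
        with pytest.raises(ValueError):
            scale_to_snr(np.zeros(100), 2000.0, 5.0)


class TestRecording:
    def test_bit_identical_given_seed(self, two_state):
        cfg = SimulationConfig(n_samples=30_000, seed=3)
        a, _ = simulate_recording(two_state, cfg)
        b, _ = simulate_recording(two_state, cfg)
        np.testing.assert_array_equal(a, b)

    def test_empirical_snr(self, two_state):
        cfg = SimulationConfig(n_samples=400_000, seed=6)
        noisy, ideal = simulate_recording(two_state, cfg)
        clean = apply_step_response(
            ideal, (cfg.level_closed, cfg.level_open), cfg.resolved_step()
        )
        resid_sigma = (noisy - clean).std()
        assert abs(cfg.amplitude / resid_sigma - cfg.snr) / cfg.snr < 0.05

    def test_rectangular_limit(self):
        # ideal one-sample step + astronomically high SNR = rectangular trace
        m = KineticModel(Topology("CO"), np.array([50.0, 50.0]))
        cfg = SimulationConfig(
            n_samples=100_000, seed=21, snr=1e9,
            step_response=StepResponse(np.array([0.0, 1.0])),
        )
        noisy, ideal = simulate_recording(m, cfg)
        rect = ideal.levels(cfg.level_closed, cfg.level_open)
        assert np.abs(noisy - rect).max() < 1e-3 * cfg.amplitude
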
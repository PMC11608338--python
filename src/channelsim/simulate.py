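"""Synthesis of realistic single-channel current recordings.

The simulator reproduces what a patch-clamp setup does to ideal gating:

1. a continuous-time trajectory of the kinetic model is drawn by
   competing-exponentials event simulation (transitions are instantaneous on
   the sampling time scale) and discretized by sample-and-hold;
2. every level change of the resulting rectangular current trace is replaced
   by the low-pass filter's step response (superposition of scaled steps);
3. noise — either low-pass-filtered white noise or noise synthesized from a
   measured power spectrum by the random-phase/inverse-FFT method — is scaled
   to the requested signal-to-noise ratio, SNR = I/sigma with I the open-closed
   current amplitude and sigma the noise standard deviation, and added.

Open-channel noise is not modeled: a single sigma applies to both levels.
All operations are pure functions of their inputs and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit
from scipy import signal as sps

from .events import EventList
from .markov import KineticModel, generator_matrix, stationary_distribution

__all__ = [
    "StepResponse",
    "NoiseSpectrum",
    "SimulationConfig",
    "IdealTimeSeries",
    "bessel_step_response",
    "simulate_ideal",
    "apply_step_response",
    "noise_from_spectrum",
    "filtered_white_noise",
    "scale_to_snr",
    "simulate_recording",
]


@dataclass(frozen=True)
class StepResponse:
    """Sampled response of the recording system to a unit level step.

    ``samples[0]`` is the last pre-transition sample (must be ~0) and the
    response must settle at 1 (|last - 1| < 1e-3). Use :meth:`from_raw` to
    normalize a measured trace.
    """

    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1 or s.size < 2:
            raise ValueError("step response needs at least 2 samples")
        if abs(s[0]) > 1e-3:
            raise ValueError("step response must start at 0")
        if abs(s[-1] - 1.0) > 1e-3:
            raise ValueError("step response must settle at 1")

    def __len__(self) -> int:
        return self.samples.size

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "StepResponse":
        """Normalize a measured step trace to run from 0 to 1."""
        raw = np.asarray(raw, dtype=float)
        span = raw[-1] - raw[0]
        if span == 0:
            raise ValueError("step trace has zero span")
        return cls((raw - raw[0]) / span)


@dataclass(frozen=True)
class NoiseSpectrum:
    """One-sided noise power spectral density sampled at ascending frequencies."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)
        if f.shape != p.shape or f.ndim != 1 or f.size < 2:
            raise ValueError("frequencies and power must be equal-length 1-D arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to turn a kinetic model into a noisy recording.

    Defaults follow common single-channel practice: 100 kHz sampling, a 4-pole
    low-pass Bessel filter at 10 kHz, SNR = 5, closed level 22000 AU and open
    level 20000 AU (amplitude 2000 AU).
    """

    n_samples: int
    sampling_frequency: float = 1e5
    snr: float = 5.0
    level_closed: float = 22000.0
    level_open: float = 20000.0
    seed: int = 0
    filter_corner: float = 1e4
    filter_poles: int = 4
    step_response: Optional[StepResponse] = None  # None -> analytic Bessel
    noise_spectrum: Optional[NoiseSpectrum] = None  # None -> filtered white

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.level_closed == self.level_open:
            raise ValueError("open and closed current levels must differ")
        if not 0 < self.filter_corner < self.sampling_frequency / 2:
            raise ValueError("filter corner must lie below Nyquist")

    @property
    def amplitude(self) -> float:
        """Open-closed current amplitude I of the SNR definition."""
        return abs(self.level_open - self.level_closed)

    def resolved_step(self) -> StepResponse:
        if self.step_response is not None:
            return self.step_response
        return bessel_step_response(
            self.filter_corner, self.sampling_frequency, self.filter_poles
        )


@dataclass
class IdealTimeSeries:
    """Ground-truth gating trajectory, discretized at the sampling rate."""

    class_per_sample: np.ndarray  # uint8, 1 = open
    state_per_sample: np.ndarray  # int16 state index along the chain
    sampling_frequency: float

    @property
    def n_samples(self) -> int:
        return self.class_per_sample.size

    @property
    def true_events(self) -> EventList:
        return EventList.from_class_samples(
            self.class_per_sample, self.sampling_frequency
        )

    def levels(self, level_closed: float, level_open: float) -> np.ndarray:
        """Rectangular current trace at the two conductance levels."""
        return np.where(
            self.class_per_sample.astype(bool), level_open, level_closed
        ).astype(float)


@njit(nogil=True)
def _fill_path(state0, t_end, total_rate, p_up, exp_draws, uni_draws, states, dwells):
    """Consume pre-drawn unit exponentials/uniforms along the embedded chain."""
    n_draw = exp_draws.shape[0]
    s = state0
    t = 0.0
    k = 0
    while k < n_draw:
        states[k] = s
        dwell = exp_draws[k] / total_rate[s]
        dwells[k] = dwell
        t += dwell
        k += 1
        if t >= t_end:
            return k, t, s, True
        if uni_draws[k - 1] < p_up[s]:
            s += 1
        else:
            s -= 1
    return k, t, s, False


def _simulate_path(
    model: KineticModel, t_end: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Event-driven trajectory: (state indices, dwell durations in seconds).

    The initial state is drawn from the stationary distribution; the final
    dwell overruns ``t_end`` (it is clipped by discretization).
    """
    q = generator_matrix(model)
    total_rate = -np.diag(q)
    if np.any(total_rate <= 0):
        raise ValueError("model has an absorbing state (all outgoing rates zero)")
    fwd, _ = model.forward_backward()
    n = model.n_states
    p_up = np.zeros(n)
    p_up[: n - 1] = fwd / total_rate[: n - 1]  # last state can only step down
    pi = stationary_distribution(model)
    state0 = int(rng.choice(n, p=pi))

    mean_rate = float(pi @ total_rate)
    chunk = max(1024, int(1.2 * mean_rate * t_end) + 64)
    states_parts, dwell_parts = [], []
    t_acc, s = 0.0, state0
    while True:
        states = np.empty(chunk, dtype=np.int16)
        dwells = np.empty(chunk, dtype=np.float64)
        exp_draws = rng.standard_exponential(chunk)
        uni_draws = rng.random(chunk)
        k, t, s, done = _fill_path(
            s, t_end - t_acc, total_rate, p_up, exp_draws, uni_draws, states, dwells
        )
        states_parts.append(states[:k])
        dwell_parts.append(dwells[:k])
        t_acc += t
        if done:
            break
        # draws exhausted mid-trajectory: s is already the post-transition state
        chunk = max(1024, int(1.2 * mean_rate * (t_end - t_acc)) + 64)
    return np.concatenate(states_parts), np.concatenate(dwell_parts)


def simulate_ideal(
    model: KineticModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> IdealTimeSeries:
    """Draw a gating trajectory and discretize it by sample-and-hold.

    Each sampling interval records the state occupying its start, so gating
    faster than the sampling rate is handled exactly (short dwells simply
    vanish from the sampled trace, as they do in a real digitizer).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_frequency
    t_end = config.n_samples / fs
    states, dwells = _simulate_path(model, t_end, rng)
    starts = np.concatenate([[0.0], np.cumsum(dwells)[:-1]])
    sample_times = np.arange(config.n_samples) / fs
    idx = np.searchsorted(starts, sample_times, side="right") - 1
    state_per_sample = states[idx]
    open_states = np.flatnonzero(model.topology.open_mask)
    class_per_sample = np.isin(state_per_sample, open_states).astype(np.uint8)
    return IdealTimeSeries(class_per_sample, state_per_sample, fs)


def bessel_step_response(
    corner_frequency: float,
    sampling_frequency: float,
    n_poles: int = 4,
) -> StepResponse:
    """Digital step response of an n-pole low-pass Bessel filter.

    The filter is magnitude-normalized (-3 dB at the corner) and the response
    is truncated once it has settled to within 1e-4 of its final value, then
    rescaled to end exactly at 1.
    """
    if not 0 < corner_frequency < sampling_frequency / 2:
        raise ValueError("corner frequency must lie strictly below Nyquist")
    sos = sps.bessel(
        n_poles, corner_frequency, btype="low", output="sos",
        fs=sampling_frequency, norm="mag",
    )
    n = int(20 * sampling_frequency / corner_frequency) + 50
    step = sps.sosfilt(sos, np.ones(n))
    settled = np.flatnonzero(np.abs(step - step[-1]) >= 1e-4 * abs(step[-1]))
    cut = settled[-1] + 2 if settled.size else 2
    step = step[: min(cut, n)] / step[-1]
    step = np.concatenate([[0.0], step])  # explicit pre-transition sample
    step[-1] = 1.0
    return StepResponse(step)


def apply_step_response(
    ideal: IdealTimeSeries | np.ndarray,
    levels: tuple[float, float],
    step: StepResponse,
) -> np.ndarray:
    """Replace each level change by the filter's step-response trajectory.

    Implemented as FIR filtering of the rectangular trace with the impulse
    response ``diff(step)`` — the linear superposition of one scaled step per
    transition. The convention is that ``step[0]`` is the last pre-transition
    sample, so the sample at a transition already carries ``step[1]``; the
    ideal one-sample step ``[0, 1, 1, ...]`` is the identity. The trace is
    padded by holding the initial level so no transient wraps in.
    """
    level_closed, level_open = levels
    if isinstance(ideal, IdealTimeSeries):
        x = ideal.levels(level_closed, level_open)
    else:
        x = np.asarray(ideal, dtype=float)
    h = np.diff(step.samples)
    n = x.size
    pad = h.size
    xp = np.concatenate([np.full(pad, x[0]), x])
    y = sps.fftconvolve(xp, h)[pad : pad + n]
    return y


def noise_from_spectrum(
    spectrum: NoiseSpectrum,
    n_samples: int,
    sampling_frequency: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Synthesize colored noise by randomizing the phases of a power spectrum.

    The spectrum is interpolated onto the FFT frequency grid; each positive
    bin gets amplitude proportional to sqrt(power) and a phase uniform on
    [0, 2pi). Hermitian symmetry is implicit in the inverse real FFT, the DC
    component is zeroed (zero-mean output) and the overall scale is arbitrary
    (:func:`scale_to_snr` sets it).
    """
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_frequency)
    power = np.interp(freqs, spectrum.frequencies, spectrum.power)
    amp = np.sqrt(power)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = amp[-1] * np.where(rng.random() < 0.5, 1.0, -1.0)
    return np.fft.irfft(spec, n=n_samples)


def filtered_white_noise(
    corner_frequency: float,
    sampling_frequency: float,
    n_samples: int,
    seed: int | np.random.Generator,
    n_poles: int = 4,
) -> np.ndarray:
    """Standard-normal white noise through an n-pole low-pass Bessel filter.

    Returned unscaled; a warm-up segment is discarded so the filter state is
    stationary from the first sample.
    """
    if not 0 < corner_frequency < sampling_frequency / 2:
        raise ValueError("corner frequency must lie strictly below Nyquist")
    rng = np.random.default_rng(seed)
    warmup = int(10 * sampling_frequency / corner_frequency) + 16
    sos = sps.bessel(
        n_poles, corner_frequency, btype="low", output="sos",
        fs=sampling_frequency, norm="mag",
    )
    white = rng.standard_normal(n_samples + warmup)
    return sps.sosfilt(sos, white)[warmup:]


def scale_to_snr(noise: np.ndarray, amplitude: float, snr: float) -> np.ndarray:
    """Rescale a noise series so that SNR = amplitude / std(noise) holds."""
    noise = np.asarray(noise, dtype=float)
    sd = noise.std()
    if sd == 0:
        raise ValueError("noise has zero variance; cannot set an SNR")
    if snr <= 0:
        raise ValueError("snr must be positive")
    return noise * (amplitude / snr / sd)


def simulate_recording(
    model: KineticModel, config: SimulationConfig
) -> tuple[np.ndarray, IdealTimeSeries]:
    """Full pipeline: trajectory -> step-response filtering -> scaled noise.

    Returns the observable noisy trace together with the ground-truth
    trajectory. Trajectory and noise use independent substreams derived from
    ``config.seed``, so the pair is reproducible bit-for-bit.
    """
    ss_traj, ss_noise = np.random.SeedSequence(config.seed).spawn(2)
    ideal = simulate_ideal(model, config, rng=np.random.default_rng(ss_traj))
    filtered = apply_step_response(
        ideal, (config.level_closed, config.level_open), config.resolved_step()
    )
    noise_rng = np.random.default_rng(ss_noise)
    if config.noise_spectrum is not None:
        noise = noise_from_spectrum(
            config.noise_spectrum, config.n_samples, config.sampling_frequency,
            noise_rng,
        )
    else:
        noise = filtered_white_noise(
            config.filter_corner, config.sampling_frequency, config.n_samples,
            noise_rng, config.filter_poles,
        )
    return filtered + scale_to_snr(noise, config.amplitude, config.snr), ideal
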
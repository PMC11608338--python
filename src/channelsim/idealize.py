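"""Idealization: turning a noisy current trace into open/closed dwell times.

Two jump detectors are provided. The workhorse is a higher-order Hinkley
(cumulative-sum) detector: against the currently hypothesized level it
accumulates the normalized deviation toward the alternative level, integrates
that score once more (higher order), and declares a transition when the
integrated score crosses an SNR-dependent threshold. The transition sample is
back-estimated as the point where the first-order score last left zero, which
keeps dwell durations unbiased. A half-amplitude threshold detector with an
optional hysteresis band serves as the simple reference.

Both detectors are exact on noise-free rectangular traces and emit an
:class:`~channelsim.events.EventList` whose censored boundary dwells are
flagged.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .events import EventList

__all__ = ["idealize_hohd", "idealize_half_amplitude", "hohd_threshold"]

_MIN_SAMPLES = 4


@njit(nogil=True)
def _hohd_core(x, mu_c, mu_o, thresh, order, c0, boundaries):
    half = 0.5 * (mu_c + mu_o)
    scale = 0.5 * abs(mu_o - mu_c)
    n = x.size
    c = c0
    g1 = 0.0
    g2 = 0.0
    g3 = 0.0
    last_zero = -1
    m = 0
    for k in range(n):
        if c == 0:
            direction = 1.0 if mu_o > mu_c else -1.0
        else:
            direction = 1.0 if mu_c > mu_o else -1.0
        z = (x[k] - half) * direction / scale
        g1 += z
        if g1 <= 0.0:
            g1 = 0.0
            g2 = 0.0
            g3 = 0.0
            last_zero = k
        else:
            g2 += g1
            g3 += g2
        score = g1 if order == 1 else (g2 if order == 2 else g3)
        if score > thresh:
            b = last_zero + 1
            prev = boundaries[m - 1] if m > 0 else 0
            if b <= prev:  # keep dwells strictly positive
                b = prev + 1
            if b < n:
                boundaries[m] = b
                m += 1
                c = 1 - c
            g1 = 0.0
            g2 = 0.0
            g3 = 0.0
            last_zero = k
    return m


@njit(nogil=True)
def _half_amp_core(x, mu_c, mu_o, hyst_band, c0, boundaries):
    half = 0.5 * (mu_c + mu_o)
    n = x.size
    c = c0
    m = 0
    for k in range(n):
        if c == 0:
            direction = 1.0 if mu_o > mu_c else -1.0
        else:
            direction = 1.0 if mu_c > mu_o else -1.0
        if (x[k] - half) * direction > hyst_band:
            b = k
            prev = boundaries[m - 1] if m > 0 else 0
            if b <= prev:  # keep dwells strictly positive
                b = prev + 1
            if b < n:
                boundaries[m] = b
                m += 1
                c = 1 - c
    return m


def hohd_threshold(snr: float, scale: float = 4.0) -> float:
    """Default detection threshold of the second-order Hinkley score.

    The score is accumulated in units of the half-amplitude, in which the
    noise standard deviation is ``s = 2/snr``. The threshold grows with the
    noise power so that false alarms on correlated (low-pass-filtered) noise
    stay rare while the detection ramp stays short; ``scale`` is the knob.
    """
    s = 2.0 / snr
    return scale * (1.0 + 12.0 * s * s)


def _initial_class(x: np.ndarray, mu_c: float, mu_o: float) -> int:
    x0 = np.median(x[: min(5, x.size)])
    return 0 if abs(x0 - mu_c) <= abs(x0 - mu_o) else 1


def _events_from_boundaries(
    boundaries: np.ndarray, n: int, c0: int, fs: float
) -> EventList:
    edges = np.concatenate([[0], boundaries, [n]])
    durations = np.diff(edges)
    classes = np.where((np.arange(durations.size) + c0) % 2 == 1, "O", "C")
    return EventList(classes, durations, fs)


def idealize_hohd(
    series: np.ndarray,
    level_closed: float,
    level_open: float,
    snr: float,
    sampling_frequency: float,
    order: int = 2,
    threshold: float | None = None,
    threshold_scale: float = 4.0,
) -> EventList:
    """Sequential higher-order Hinkley jump detection.

    ``threshold`` overrides the SNR-derived default
    :func:`hohd_threshold`; ``order`` selects how many times the cumulative
    score is integrated (1 = classic Hinkley/CUSUM, default 2).
    """
    x = np.ascontiguousarray(series, dtype=np.float64)
    if x.size < _MIN_SAMPLES:
        raise ValueError(f"series shorter than the detector window ({_MIN_SAMPLES})")
    if level_closed == level_open:
        raise ValueError("open and closed levels must differ")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if threshold is None:
        threshold = hohd_threshold(snr, threshold_scale)
    c0 = _initial_class(x, level_closed, level_open)
    boundaries = np.empty(x.size, dtype=np.int64)
    m = _hohd_core(x, level_closed, level_open, threshold, order, c0, boundaries)
    return _events_from_boundaries(
        boundaries[:m], x.size, c0, sampling_frequency
    )


def idealize_half_amplitude(
    series: np.ndarray,
    level_closed: float,
    level_open: float,
    hysteresis_fraction: float = 0.0,
    sampling_frequency: float = 1e5,
) -> EventList:
    """Threshold crossing at 50% amplitude with an optional hysteresis band.

    With ``hysteresis_fraction`` h, a class switch requires the signal to
    cross the midline by more than ``h * amplitude`` toward the other level,
    suppressing chatter from noise around the threshold.
    """
    x = np.ascontiguousarray(series, dtype=np.float64)
    if x.size < _MIN_SAMPLES:
        raise ValueError(f"series shorter than the detector window ({_MIN_SAMPLES})")
    if level_closed == level_open:
        raise ValueError("open and closed levels must differ")
    if not 0 <= hysteresis_fraction < 0.5:
        raise ValueError("hysteresis_fraction must lie in [0, 0.5)")
    amp = abs(level_open - level_closed)
    c0 = _initial_class(x, level_closed, level_open)
    boundaries = np.empty(x.size, dtype=np.int64)
    m = _half_amp_core(
        x, level_closed, level_open, hysteresis_fraction * amp, c0, boundaries
    )
    return _events_from_boundaries(
        boundaries[:m], x.size, c0, sampling_frequency
    )
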
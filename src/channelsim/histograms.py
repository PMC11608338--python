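"""Log-binned 2D dwell-time histograms and re-simulation goodness scores.

Adjacent closed/open dwell pairs are accumulated in a logarithmically binned
60x60 histogram spanning 10 us to 10 s at 10 bins per decade. Under detailed
balance (assumed for long stationary recordings) a closed-then-open pair and
an open-then-closed pair carry the same information, so every adjacent duo
contributes one count at (closed-duration bin, open-duration bin) regardless
of temporal order.

For comparing two histograms the occupancies are first compressed,

    a'_ij = 2*log10(a_ij)  if a_ij > 0 else 0,

and the normalized volume deviation is

    V_D(S, M) = sum_ij sqrt(|s_ij^2 - m_ij^2|) / (sum_ij s_ij + sum_ij m_ij),

which is 0 for identical histograms and 1 when their occupied bins are
disjoint. Because a single simulation is itself stochastic, a predicted model
is scored by re-simulating it N times: the mean volume deviation V_D-bar
against the data histogram is gauged against the mean reference deviation
V_R-bar among the N re-simulations, which is the stochastic floor the model
itself cannot beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .events import EventList
from .markov import KineticModel

__all__ = [
    "HistogramSpec",
    "DwellHistogram2D",
    "GoodnessReport",
    "build_histogram",
    "scale_occupancy",
    "difference_histogram",
    "volume_deviation",
    "mean_volume_deviation",
    "reference_deviation",
    "goodness_report",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Binning convention: half-open log bins, lower edge inclusive.

    Bin ``i`` spans ``[t_min * 10^(i/bpd), t_min * 10^((i+1)/bpd))``. The
    default covers 10 us (one sample at 100 kHz) to 10 s in 60 bins per axis.
    Horizontal axis = closed dwell, vertical axis = open dwell.
    """

    t_min: float = 1e-5
    t_max: float = 10.0
    bins_per_decade: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.t_min < self.t_max:
            raise ValueError("require 0 < t_min < t_max")
        n = self.bins_per_decade * np.log10(self.t_max / self.t_min)
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_max/t_min must span a whole number of bins")

    @property
    def n_bins(self) -> int:
        return int(round(self.bins_per_decade * np.log10(self.t_max / self.t_min)))

    def bin_edges(self) -> np.ndarray:
        """The n_bins + 1 bin edges in seconds."""
        i = np.arange(self.n_bins + 1)
        return self.t_min * 10.0 ** (i / self.bins_per_decade)

    def bin_index(self, durations_s: np.ndarray) -> np.ndarray:
        """Bin of each duration; out-of-range dwells clamp to the edge bins."""
        d = np.asarray(durations_s, dtype=float)
        idx = np.floor(
            self.bins_per_decade * np.log10(d / self.t_min)
        ).astype(np.int64)
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class DwellHistogram2D:
    """Counts of adjacent dwell pairs; ``counts[open_bin, closed_bin]``."""

    counts: np.ndarray
    spec: HistogramSpec = field(default_factory=HistogramSpec)
    n_events: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = self.spec.n_bins
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int64)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_pairs == 0

    def scaled(self) -> np.ndarray:
        return scale_occupancy(self)


@dataclass
class GoodnessReport:
    """Re-simulation-based score of one predicted model against one histogram.

    ``v_d_mean`` is the mean volume deviation of the data histogram against N
    re-simulated prediction histograms; ``v_r_mean`` the mean pairwise
    deviation among the re-simulations (the stochastic floor). A prediction is
    acceptable when ``v_d_mean`` does not stand far above ``v_r_mean``.
    ``rate_distributions`` holds the N re-predicted rate vectors (N x n_rates)
    when a rate estimator was supplied.
    """

    v_d_mean: float
    v_r_mean: float
    n_resimulations: int
    seeds: np.ndarray
    rate_distributions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0 <= self.v_d_mean <= 1:
            raise ValueError("v_d_mean must lie in [0, 1]")
        if not np.isnan(self.v_r_mean) and not 0 <= self.v_r_mean <= 1:
            raise ValueError("v_r_mean must lie in [0, 1]")

    @property
    def ratio(self) -> float:
        """v_d_mean / v_r_mean; near 1 indicates a self-consistent prediction."""
        return self.v_d_mean / self.v_r_mean

    def rate_percentiles(
        self, q: Sequence[float] = (10, 25, 50, 75, 90)
    ) -> np.ndarray:
        """Per-rate percentiles (len(q) x n_rates) of the re-predictions."""
        if self.rate_distributions is None:
            raise ValueError("report carries no re-predicted rates")
        return np.percentile(self.rate_distributions, q, axis=0)


def build_histogram(
    events: EventList, spec: HistogramSpec | None = None
) -> DwellHistogram2D:
    """Accumulate adjacent dwell pairs of an idealized series.

    Censored boundary dwells are excluded; among the m retained events every
    adjacent pair (m - 1 of them) adds one count at its (closed bin, open bin)
    coordinate, whichever temporal order the pair has. Fewer than two retained
    events give an empty (flagged) histogram.
    """
    spec = spec or HistogramSpec()
    ev = events.retained()
    n = spec.n_bins
    counts = np.zeros((n, n), dtype=np.int64)
    m = len(ev)
    if m < 2:
        return DwellHistogram2D(counts, spec, n_events=m)
    d = ev.durations_s
    first_is_closed = ev.classes[:-1] == "C"
    closed_d = np.where(first_is_closed, d[:-1], d[1:])
    open_d = np.where(first_is_closed, d[1:], d[:-1])
    oi = spec.bin_index(open_d)
    ci = spec.bin_index(closed_d)
    np.add.at(counts, (oi, ci), 1)
    return DwellHistogram2D(counts, spec, n_events=m)


def scale_occupancy(hist: DwellHistogram2D | np.ndarray) -> np.ndarray:
    """Occupancy compression a' = 2*log10(a) for a > 0, else 0.

    Note that bins holding a single count map to 0 and thus collide with
    empty bins; this is inherent to the transform.
    """
    a = hist.counts if isinstance(hist, DwellHistogram2D) else np.asarray(hist)
    out = np.zeros(a.shape, dtype=float)
    pos = a > 0
    out[pos] = 2.0 * np.log10(a[pos])
    return out


def difference_histogram(x_scaled: np.ndarray, y_scaled: np.ndarray) -> np.ndarray:
    """Signed root-difference z = sign(x^2 - y^2) * sqrt(|x^2 - y^2|).

    Computed on occupancy-scaled histograms; suppresses discrepancies in
    sparsely occupied bins and enhances those in dense ones. Antisymmetric in
    its arguments.
    """
    x = np.asarray(x_scaled, dtype=float)
    y = np.asarray(y_scaled, dtype=float)
    d = x * x - y * y
    return np.sign(d) * np.sqrt(np.abs(d))


def _as_occupancy(h: DwellHistogram2D | np.ndarray, scaled: bool) -> np.ndarray:
    if isinstance(h, DwellHistogram2D):
        return scale_occupancy(h) if scaled else h.counts.astype(float)
    return np.asarray(h, dtype=float)


def volume_deviation(
    s: DwellHistogram2D | np.ndarray,
    m: DwellHistogram2D | np.ndarray,
    scaled: bool = True,
) -> float:
    """Normalized volume deviation between two histograms (0 = identical,
    1 = disjoint occupancy).

    Histogram inputs are occupancy-compressed first when ``scaled`` is true
    (the default, consistent with how histograms are fed to the estimators);
    array inputs are used as given.
    """
    sv = _as_occupancy(s, scaled)
    mv = _as_occupancy(m, scaled)
    if sv.shape != mv.shape:
        raise ValueError("histograms must share one binning spec")
    denom = (sv + mv).sum()
    if denom == 0:
        raise ValueError("volume deviation of two empty histograms is undefined")
    # branch where one side is empty so the limiting values 0 and 1 are exact
    num = np.where(
        mv == 0, sv, np.where(sv == 0, mv, np.sqrt(np.abs(sv * sv - mv * mv)))
    )
    return float(num.sum() / denom)


def mean_volume_deviation(
    g: DwellHistogram2D | np.ndarray,
    hs: Sequence[DwellHistogram2D | np.ndarray],
    scaled: bool = True,
) -> float:
    """Mean of V_D(G, H_n) over the N re-simulated histograms."""
    if len(hs) < 1:
        raise ValueError("need at least one comparison histogram")
    return float(np.mean([volume_deviation(g, h, scaled) for h in hs]))


def reference_deviation(
    hs: Sequence[DwellHistogram2D | np.ndarray], scaled: bool = True
) -> float:
    """Mean V_D over all unordered pairs of the N re-simulated histograms."""
    n = len(hs)
    if n < 2:
        raise ValueError("reference deviation needs at least two histograms")
    vals = [
        volume_deviation(hs[i], hs[j], scaled)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def goodness_report(
    g: DwellHistogram2D,
    predicted: KineticModel,
    config,
    n: int = 100,
    regressor: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    base_seed: Optional[int] = None,
    scaled: bool = True,
) -> GoodnessReport:
    """Score a predicted model against a data histogram by re-simulation.

    N recordings are simulated from ``predicted`` under ``config`` (seeds
    ``base_seed + i``, recorded in the report), idealized with the Hinkley
    detector, and binned with ``g``'s spec. If ``regressor`` is given it is
    called with each re-simulated histogram's scaled occupancy and must return
    a rate vector; the N re-predictions quantify the rate uncertainty.
    """
    from .idealize import idealize_hohd  # local import: avoid cycle at import time

    if n < 1:
        raise ValueError("need at least one re-simulation")
    if base_seed is None:
        base_seed = config.seed + 1
    seeds = base_seed + np.arange(n)
    hists = []
    rates = []
    for si in seeds:
        cfg = replace(config, seed=int(si))
        noisy, _ = _simulate(predicted, cfg)
        ev = idealize_hohd(
            noisy, cfg.level_closed, cfg.level_open, cfg.snr,
            cfg.sampling_frequency,
        )
        h = build_histogram(ev, g.spec)
        hists.append(h)
        if regressor is not None:
            rates.append(np.asarray(regressor(scale_occupancy(h)), dtype=float))
    v_d = mean_volume_deviation(g, hists, scaled)
    v_r = reference_deviation(hists, scaled) if n >= 2 else float("nan")
    return GoodnessReport(
        v_d_mean=v_d,
        v_r_mean=v_r,
        n_resimulations=n,
        seeds=seeds,
        rate_distributions=np.vstack(rates) if rates else None,
    )


def _simulate(model, cfg):
    from .simulate import simulate_recording

    return simulate_recording(model, cfg)
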
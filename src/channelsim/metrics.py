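"""Evaluation metrics for rate regression and topology classification.

Rates span several decades, so rate errors are measured on the log scale with
the root absolute error

    RAE = sqrt(|log10(k_pred) - log10(k_true)|),

which, unlike the mean absolute percentage error, is symmetric in
over-/under-estimation by a given factor (a factor of 10 either way scores 1).
Topology predictions are summarized by a multiclass confusion matrix with
recall/precision on the diagonal and the false-negative / false-discovery
rates off it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import RateRange

__all__ = [
    "rae",
    "mean_rae",
    "mape",
    "random_baseline_rae",
    "ConfusionSummary",
    "confusion_summary",
]


def rae(k_pred, k_true):
    """Root absolute error on the log10 scale; symmetric in its arguments."""
    k_pred = np.asarray(k_pred, dtype=float)
    k_true = np.asarray(k_true, dtype=float)
    if np.any(k_pred <= 0) or np.any(k_true <= 0):
        raise ValueError("rates must be positive")
    out = np.sqrt(np.abs(np.log10(k_pred) - np.log10(k_true)))
    return float(out) if out.ndim == 0 else out


def mean_rae(k_pred: np.ndarray, k_true: np.ndarray) -> float:
    """Model-level score: arithmetic mean of the per-rate RAEs."""
    return float(np.mean(rae(k_pred, k_true)))


def mape(k_pred, k_true):
    """Absolute percentage error |k_pred - k_true| / k_true (as a fraction)."""
    k_pred = np.asarray(k_pred, dtype=float)
    k_true = np.asarray(k_true, dtype=float)
    if np.any(k_true == 0):
        raise ValueError("ground-truth rate must be nonzero")
    out = np.abs(k_pred - k_true) / np.abs(k_true)
    return float(out) if out.ndim == 0 else out


def random_baseline_rae(
    ranges: RateRange, n_draws: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sorted RAE scores of random predictions against random truths.

    Both members of each pair are drawn log-uniform from ``ranges``; the
    resulting cumulative distribution is the no-skill reference any estimator
    must beat.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(ranges.lo), np.log10(ranges.hi)
    u = rng.uniform(lo, hi, size=n_draws)
    v = rng.uniform(lo, hi, size=n_draws)
    return np.sort(np.sqrt(np.abs(u - v)))


@dataclass
class ConfusionSummary:
    """Multiclass confusion counts with derived per-class metrics.

    ``counts[i, j]`` is the number of examples with ground truth ``i``
    predicted as ``j``. Recall ``r_i = n_ii / K_i`` and the false-negative
    rates share the row totals ``K_i``; precision ``p_i = n_ii / L_i`` and the
    false-discovery rates share the column totals ``L_i``. Classes absent from
    the ground truth (or never predicted) get NaN instead of a 0/0.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        self.counts = c

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def truth_totals(self) -> np.ndarray:  # K_i
        return self.counts.sum(axis=1)

    @property
    def predicted_totals(self) -> np.ndarray:  # L_j
        return self.counts.sum(axis=0)

    def _safe_div(self, num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    @property
    def recall(self) -> np.ndarray:
        return self._safe_div(np.diag(self.counts), self.truth_totals)

    @property
    def precision(self) -> np.ndarray:
        return self._safe_div(np.diag(self.counts), self.predicted_totals)

    @property
    def fnr(self) -> np.ndarray:
        """FNR[i, j] = n_ij / K_i; row i sums to 1 for represented classes."""
        return self._safe_div(self.counts, self.truth_totals[:, None])

    @property
    def fdr(self) -> np.ndarray:
        """FDR[i, j]: of the examples predicted as ``i``, the fraction whose
        ground truth is ``j`` (so the diagonal is the precision and row ``i``
        sums to 1 for every predicted class)."""
        return self._safe_div(self.counts.T, self.predicted_totals[:, None])

    @property
    def accuracy(self) -> float:
        return float(np.diag(self.counts).sum() / self.counts.sum())


def confusion_summary(
    truths, predictions, n_classes: int
) -> ConfusionSummary:
    """Tally a confusion matrix from parallel class-index sequences."""
    t = np.asarray(truths, dtype=np.int64)
    p = np.asarray(predictions, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truths and predictions must be equal-length 1-D")
    if t.size and (t.min() < 0 or p.min() < 0 or t.max() >= n_classes or p.max() >= n_classes):
        raise ValueError("class index out of range")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionSummary(counts)
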
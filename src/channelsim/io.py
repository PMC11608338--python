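"""Readers and writers for the package's on-disk formats.

Plain formats throughout: kinetic models as YAML/JSON records, histograms as
NPY count arrays with a JSON sidecar carrying the binning spec, event lists
as two-column CSV, step responses as single-column text or NPY, noise spectra
as two-column (Hz, power) text or NPY, trained estimators as joblib
checkpoints with a JSON provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import joblib
import numpy as np
import yaml

from .histograms import DwellHistogram2D, HistogramSpec
from .inference import HistogramEstimator, NetworkSpec
from .markov import KineticModel
from .simulate import NoiseSpectrum, StepResponse

__all__ = [
    "save_model",
    "load_model",
    "save_histogram",
    "load_histogram",
    "histogram_to_csv",
    "load_step_response",
    "load_noise_spectrum",
    "save_estimator",
    "load_estimator",
]


def save_model(model: KineticModel, path) -> None:
    path = Path(path)
    record = model.to_dict()
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(record, fh)
        else:
            json.dump(record, fh, indent=1)


def load_model(path) -> KineticModel:
    path = Path(path)
    with open(path) as fh:
        record = (
            yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        )
    return KineticModel.from_dict(record)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_histogram(hist: DwellHistogram2D, path) -> None:
    path = Path(path)
    np.save(path, hist.counts)
    meta = dataclasses.asdict(hist.spec) | {"n_events": hist.n_events}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_histogram(path) -> DwellHistogram2D:
    path = Path(path)
    counts = np.load(path.with_suffix(".npy"))
    side = _sidecar(path)
    n_events = 0
    spec = HistogramSpec()
    if side.exists():
        meta = json.loads(side.read_text())
        n_events = meta.pop("n_events", 0)
        spec = HistogramSpec(**meta)
    return DwellHistogram2D(counts, spec, n_events=n_events)


def histogram_to_csv(hist: DwellHistogram2D, path) -> None:
    """Counts as CSV for inspection; rows = open-dwell bins (slow at bottom)."""
    np.savetxt(path, hist.counts, fmt="%d", delimiter=",")


def load_step_response(path) -> StepResponse:
    path = Path(path)
    raw = np.load(path) if path.suffix == ".npy" else np.loadtxt(path)
    return StepResponse.from_raw(np.asarray(raw, dtype=float).ravel())


def load_noise_spectrum(path) -> NoiseSpectrum:
    path = Path(path)
    arr = np.load(path) if path.suffix == ".npy" else np.loadtxt(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("noise spectrum file must hold two columns (Hz, power)")
    return NoiseSpectrum(arr[:, 0], arr[:, 1])


def save_estimator(estimator: HistogramEstimator, path) -> None:
    path = Path(path)
    joblib.dump(estimator, path)
    _sidecar(path).write_text(
        json.dumps(dataclasses.asdict(estimator.spec), indent=1)
    )


def load_estimator(path) -> HistogramEstimator:
    est = joblib.load(path)
    if not isinstance(est, HistogramEstimator):
        raise TypeError(f"{path} does not hold a HistogramEstimator checkpoint")
    return est
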
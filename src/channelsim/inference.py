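"""Two-stage learned inference: topology classification, then rate regression.

Stage one classifies the occupancy-scaled 60x60 dwell-time histogram into one
of the candidate topologies; stage two feeds the histogram to a per-topology
regressor that returns the ``2*(n_states-1)`` transition rates. Both stages
are feed-forward networks trained on simulated histograms whose labels are
known by construction; regression labels are log10-transformed (the rates
span decades) and palindromic topologies are label-canonicalized
(``k_12 > k_{n,n-1}``) so each model has a unique target.

The training protocol is Adam with initial learning rate 1e-3, learning-rate
reduction by 0.1 after 8 epochs without validation improvement and early
stopping after 12, with cross-entropy (classification) or squared error on
the log-rates (regression) as the loss.

A predicted model is finally scored without any ground truth by re-simulating
it and re-predicting the re-simulations (see
:func:`channelsim.histograms.goodness_report`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .histograms import (
    DwellHistogram2D,
    GoodnessReport,
    HistogramSpec,
    build_histogram,
    goodness_report,
    scale_occupancy,
)
from .idealize import idealize_hohd
from .markov import KineticModel, RateRange, Topology, sample_rates
from .simulate import SimulationConfig, simulate_recording

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "PredictionResult",
    "HistogramEstimator",
    "make_training_set",
    "train",
    "predict_topology",
    "predict_rates",
    "uncertainty_quantify",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one estimation stage.

    A fully-connected network on the flattened scaled histogram: the 60x60
    input is small and, after occupancy compression, dense layers of a few
    hundred units capture the dwell-time structure well at the problem sizes
    this package targets. ``n_outputs`` is the number of topology classes
    (classification, softmax head) or of directed rates (regression, linear
    head on log10 rates).
    """

    task: str  # "classification" | "regression"
    n_outputs: int
    hidden_layers: tuple[int, ...] = (512, 256, 128)
    input_shape: tuple[int, int] = (60, 60)

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule settings.

    ``batch_size`` of None picks the task default (4096 classification, 1024
    regression) capped at the training-set size, so toy sets train sensibly.
    """

    learning_rate: float = 1e-3
    batch_size: Optional[int] = None
    lr_factor: float = 0.1
    patience_lr: int = 8
    patience_stop: int = 12
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience_stop <= self.patience_lr:
            raise ValueError("patience_stop must exceed patience_lr")


@dataclass
class PredictionResult:
    """Output of one inference call, with provenance."""

    posterior: Optional[np.ndarray] = None  # classification
    rates: Optional[np.ndarray] = None  # regression, s^-1
    network_id: str = ""
    input_hash: str = ""


@dataclass
class HistogramEstimator:
    """A trained stage: network spec plus the fitted backbone."""

    spec: NetworkSpec
    model: object  # fitted MLPClassifier / MLPRegressor

    @property
    def network_id(self) -> str:
        h = "x".join(map(str, self.spec.hidden_layers))
        return f"{self.spec.task}[{h}]->{self.spec.n_outputs}"

    def _flatten(self, histograms: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(histograms, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"expected histograms of shape {self.spec.input_shape}, got {x.shape}"
            )
        return x.reshape(x.shape[0], -1), single


def _input_hash(x: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(x).tobytes()).hexdigest()[:16]


def make_training_set(
    topologies: Topology | Sequence[Topology],
    ranges: RateRange,
    n_models: int,
    config: SimulationConfig,
    seed: int,
    spec: HistogramSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a labeled dataset of occupancy-scaled histograms.

    Each example runs the full forward pipeline: draw rates log-uniformly
    (label-canonicalized), simulate a noisy recording, idealize it with the
    Hinkley detector, bin the dwell pairs and compress the occupancy. With a
    list of topologies (assigned round-robin, so classes balance) the labels
    are topology indices; with a single topology they are the log10 rate
    vectors. Fully reproducible from ``seed``.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    single_topology = isinstance(topologies, Topology)
    tops = [topologies] if single_topology else list(topologies)
    spec = spec or HistogramSpec()
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_models)
    n = spec.n_bins
    x = np.empty((n_models, n, n), dtype=float)
    if single_topology:
        y = np.empty((n_models, tops[0].n_rates), dtype=float)
    else:
        y = np.empty(n_models, dtype=np.int64)
    for i in range(n_models):
        topo = tops[i % len(tops)]
        model = sample_rates(topo, ranges, rng)
        cfg = replace(config, seed=int(sim_seeds[i]))
        noisy, _ = simulate_recording(model, cfg)
        ev = idealize_hohd(
            noisy, cfg.level_closed, cfg.level_open, cfg.snr,
            cfg.sampling_frequency,
        )
        x[i] = scale_occupancy(build_histogram(ev, spec))
        if single_topology:
            y[i] = np.log10(model.rates)
        else:
            y[i] = i % len(tops)
    return x, y


def _validation_loss(spec: NetworkSpec, model, xv: np.ndarray, yv) -> float:
    if spec.task == "classification":
        proba = model.predict_proba(xv)
        return float(log_loss(yv, proba, labels=model.classes_))
    pred = model.predict(xv)
    return float(np.mean((pred - yv) ** 2))


def train(
    network: NetworkSpec,
    train_set: tuple[np.ndarray, np.ndarray],
    validation_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig | None = None,
) -> tuple[HistogramEstimator, list[dict]]:
    """Fit one stage with LR-on-plateau and early stopping.

    Returns the fitted estimator and a per-epoch history of training loss,
    validation loss and learning rate. The learning rate is multiplied by
    ``lr_factor`` after ``patience_lr`` epochs without validation improvement
    and training stops after ``patience_stop`` stagnant epochs.
    """
    config = config or TrainingConfig()
    xt, yt = train_set
    xv, yv = validation_set
    xt = np.asarray(xt, dtype=float).reshape(len(xt), -1)
    xv = np.asarray(xv, dtype=float).reshape(len(xv), -1)
    default_batch = 4096 if network.task == "classification" else 1024
    if config.batch_size is not None:
        batch = min(config.batch_size, len(xt))
    else:
        # paper-scale default, scaled down so toy sets still get several
        # gradient steps per epoch
        batch = min(default_batch, max(32, len(xt) // 8))
    common = dict(
        hidden_layer_sizes=network.hidden_layers,
        activation="relu",
        solver="adam",
        batch_size=batch,
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
        alpha=0.0,  # no regularization
    )
    if network.task == "classification":
        model = MLPClassifier(**common)
        classes = np.arange(network.n_outputs)
    else:
        model = MLPRegressor(**common)
        classes = None

    history: list[dict] = []
    best = np.inf
    best_params = None
    stagnant = 0
    lr = config.learning_rate
    for epoch in range(1, config.max_epochs + 1):
        if classes is not None:
            model.partial_fit(xt, yt, classes=classes)
        else:
            model.partial_fit(xt, yt)
        if not np.isfinite(model.loss_):
            raise RuntimeError("training diverged (non-finite loss)")
        val = _validation_loss(network, model, xv, yv)
        history.append(
            {"epoch": epoch, "train_loss": float(model.loss_),
             "val_loss": val, "lr": lr}
        )
        if val < best - 1e-12:
            best = val
            stagnant = 0
            best_params = (
                [w.copy() for w in model.coefs_],
                [b.copy() for b in model.intercepts_],
            )
        else:
            stagnant += 1
            if stagnant >= config.patience_stop:
                break
            if stagnant % config.patience_lr == 0:
                lr *= config.lr_factor
                opt = getattr(model, "_optimizer", None)
                if opt is not None and hasattr(opt, "learning_rate_init"):
                    opt.learning_rate_init = lr
    if best_params is not None:  # restore the best validation state
        model.coefs_, model.intercepts_ = best_params
    return HistogramEstimator(network, model), history


def predict_topology(
    estimator: HistogramEstimator, histogram: np.ndarray
) -> PredictionResult:
    """Posterior over topology classes for scaled histogram(s); the argmax is
    the point prediction."""
    if estimator.spec.task != "classification":
        raise ValueError("estimator is not a topology classifier")
    x, single = estimator._flatten(histogram)
    posterior = estimator.model.predict_proba(x)
    if single:
        posterior = posterior[0]
    return PredictionResult(
        posterior=posterior,
        network_id=estimator.network_id,
        input_hash=_input_hash(x),
    )


def predict_rates(
    estimator: HistogramEstimator, histogram: np.ndarray
) -> PredictionResult:
    """Transition rates in s^-1 (the network regresses log10 rates)."""
    if estimator.spec.task != "regression":
        raise ValueError("estimator is not a rate regressor")
    x, single = estimator._flatten(histogram)
    log_rates = estimator.model.predict(x)
    if log_rates.ndim == 1 and estimator.spec.n_outputs == 1:
        log_rates = log_rates[:, None]
    rates = 10.0 ** log_rates
    if single:
        rates = rates[0]
    return PredictionResult(
        rates=rates,
        network_id=estimator.network_id,
        input_hash=_input_hash(x),
    )


def uncertainty_quantify(
    estimator: HistogramEstimator,
    predicted: KineticModel,
    g: DwellHistogram2D,
    config: SimulationConfig,
    n: int = 100,
    base_seed: Optional[int] = None,
) -> GoodnessReport:
    """Goodness scores plus per-rate uncertainty by re-prediction.

    Re-simulates the predicted model ``n`` times, scores the histograms
    against ``g`` and re-predicts each with the rate regressor; the resulting
    per-rate distributions (percentiles via
    :meth:`~channelsim.histograms.GoodnessReport.rate_percentiles`) quantify
    the uncertainty of the prediction. Unconfined distributions flag possible
    non-identifiability.
    """
    if estimator.spec.n_outputs != predicted.topology.n_rates:
        raise ValueError("estimator output size does not match the topology")
    regressor = lambda scaled: predict_rates(estimator, scaled).rates
    return goodness_report(
        g, predicted, config, n=n, regressor=regressor, base_seed=base_seed
    )
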
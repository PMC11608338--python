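# Methods

## The problem

Single-channel patch-clamp recordings show an ion channel switching between
conducting (open, O) and non-conducting (closed, C) conformations as a
step-like current, buried in noise and smeared by the recording system's
low-pass filter. The kinetics are modeled as a hidden Markov model: a linear
chain of states, each labeled C or O, with directed nearest-neighbor
transition rates `k_ij` (s⁻¹). Only the conductance class is observable, so
different states of the same class are hidden behind one current level.

`channelsim` implements the full inverse pipeline: simulate realistic
recordings from candidate models, idealize them into dwell-time sequences,
compress those into log-binned 2D dwell-time histograms, learn topology and
rates from the histograms, and score any predicted model against data by
re-simulation.

## Gating models (`markov`)

A topology is the conductance labeling of a linear n-state chain, identified
up to chain reversal (reading the chain backwards gives the same physical
model). For n = 5 there are 18 such classes; the canonical representative is
the lexicographic minimum of the string and its reversal (C < O), and the
enumeration order of the 18 classes doubles as the classifier's index order.
The interconductance rank — the matrix rank of the closed→open adjacency
block — counts independent C–O links and groups topologies by how much of
their structure is observable.

Rates are laid out edge by edge, `[k_12, k_21, k_23, k_32, …]`, so an n-state
chain has 2(n−1) rates (8 for five states). Rates are sampled log-uniformly,
by default on 10²–10⁵ s⁻¹, the span of typical channel gating. For
palindromic topologies (e.g. COCOC) the same model has two equivalent rate
layouts; the canonical orientation enforces `k_12 > k_{n,n−1}` (reversing the
full array otherwise), which gives regression training a unique target.

The stationary distribution is computed from detailed balance
(`π_i k_{i,i+1} = π_{i+1} k_{i+1,i}`), which is exact on a linear chain, in
log space for numerical safety at widely spread rates.

## Recording synthesis (`simulate`)

1. **Trajectory.** Event-driven competing-exponentials simulation of the
   continuous-time chain, started from the stationary distribution, then
   discretized by sample-and-hold (the state occupying the start of each
   sampling interval is recorded; default 100 kHz). This is exact at any
   rate, including gating much faster than the sampling rate, where short
   dwells simply vanish from the sampled trace as they do in a digitizer.
   The inner loop is numba-compiled; all randomness comes from numpy
   generators whose draws are consumed inside the loop, so a single seed
   reproduces everything.
2. **Filtering.** Each level change of the rectangular current trace is
   replaced by the system's step response via FIR filtering with
   `diff(step)`. The convention is that `step[0]` is the last pre-transition
   sample, so the transition sample already carries `step[1]` and the ideal
   one-sample step `[0, 1]` is the identity; the trace is padded by holding
   the initial level so no transient wraps in. The analytic default is the
   step response of a digital 4-pole low-pass Bessel filter
   (magnitude-normalized, corner 10 kHz), truncated once settled within 1e-4;
   a measured step response can be supplied as a plain file instead.
3. **Noise.** Either white noise passed through the same 4-pole Bessel
   filter, or colored noise synthesized from a measured one-sided power
   spectrum by assigning each positive FFT bin an amplitude ∝ √power and a
   uniform random phase (inverse real FFT guarantees a real, zero-mean
   series). Noise is scaled so that SNR = I/σ holds exactly, with I the
   open–closed amplitude (default levels 22000/20000 AU, so I = 2000 AU) and
   σ the noise standard deviation; SNR = 5 is the default condition.
   One σ serves both levels — open-channel noise is out of scope.

## Idealization (`idealize`)

The workhorse detector is a higher-order Hinkley (cumulative-sum) scheme.
Against the currently hypothesized level, the normalized deviation toward the
alternative level (in half-amplitude units, where the noise std is s = 2/SNR)
is accumulated with the one-sided recursion `g1 ← max(0, g1 + z)`, and `g1`
is integrated once more (`g2 ← g2 + g1`, reset when `g1` hits zero; order 2
by default). A transition is declared when `g2` crosses the threshold
`λ(SNR) = 4·(1 + 12·s²)`, and the transition sample is back-estimated as the
point where `g1` last left zero, which keeps dwell durations unbiased. The
threshold curve was calibrated on filtered-noise simulations so that false
alarms stay below ~10 per 10⁶ samples at SNR 5 while the detection ramp stays
a few samples; both the order and the threshold scale are exposed.

A half-amplitude crossing detector with an optional hysteresis band is
provided as the reference. Both detectors are exact on noise-free rectangular
traces with dwells longer than the ramp, and both flag the censored first and
last dwells so downstream pairing can exclude them.

Known limitation: at SNR ≈ 2 the detector produces a significant rate of
noise-induced events. The downstream analysis tolerates this by design —
training and test data pass through the same detector, so idealization errors
occur on both sides of every comparison — but event lists at SNR 2 should not
be read as literal gating sequences.

## Dwell-time histograms and scores (`histograms`)

Adjacent dwell pairs (excluding censored boundary dwells) are accumulated at
(closed-duration bin, open-duration bin) in a 60×60 histogram, 10 bins per
decade from 10 µs (one sample) to 10 s; out-of-range dwells clamp into the
edge bins so no pair is lost. Under detailed balance — assumed for the long
stationary recordings this method targets — closed→open and open→closed
pairs carry the same information and are pooled. Bins are half-open with the
lower edge inclusive.

Occupancies are compressed as `a' = 2·log10(a)` (0 for empty bins) before
they are fed to the estimators or compared; single counts collide with empty
bins under this transform, an accepted property. The signed root-difference
`z = sign(x²−y²)·√|x²−y²|` visualizes mismatch between two scaled
histograms, and the normalized volume deviation

    V_D(S, M) = Σ √|s² − m²| / (Σ s + Σ m)

scores it: 0 for identity, 1 for disjoint occupancy (both limits are exact by
construction, including in floating point). V_D is computed on scaled
occupancies by default, consistently with the estimators' input; raw-count
mode is available.

Because a single finite recording is itself a random draw, a predicted model
is scored by simulating it N times (default 100, seeds `base_seed + i`,
recorded): V̄_D, the mean deviation of the data histogram from the N
re-simulations, is gauged against V̄_R, the mean pairwise deviation among the
re-simulations themselves — the stochastic floor for that model. V̄_D close
to V̄_R means the prediction explains the data as well as the model explains
itself; V̄_D ≫ V̄_R rejects it. Feeding the N re-simulated histograms back
through the rate regressor yields per-rate distributions whose spread
quantifies uncertainty and whose non-confinement flags non-identifiability.

## Metrics (`metrics`)

Rate errors use the root absolute error `RAE = √|log10 k_pred − log10 k_true|`,
symmetric in over-/under-estimation (a factor of 10 either way scores 1),
unlike MAPE which is also provided for comparison. Model-level scores average
the per-rate RAEs arithmetically. The no-skill reference is the RAE
distribution of independent log-uniform (prediction, truth) pairs.
Classification is summarized by a confusion matrix with recall/FNR sharing
ground-truth row totals and precision/FDR sharing predicted totals (FDR rows
are indexed by predicted class so each row is a posterior over ground truths).

## Learned inference (`inference`)

Stage one classifies the scaled histogram into a topology; stage two applies
the matching per-topology regressor to obtain log10 rates (exponentiated on
output, so predicted rates are positive by construction). Both stages are
fully-connected networks (default 512–256–128 hidden units, ReLU) on the
flattened 60×60 input: at the problem sizes this package targets (hundreds to
thousands of training histograms on a CPU) dense networks train in seconds
and the 3600-pixel input needs no spatial downsampling stack. The training
loop implements Adam at 1e-3, minibatches (1024 regression / 4096
classification by default, scaled down automatically so small sets still get
several gradient steps per epoch), learning-rate reduction ×0.1 after 8
epochs without validation-loss improvement, early stopping after 12, and
restoration of the best validation weights. The regression loss is squared
error on the log-rates; on that scale it behaves like the robust losses
commonly used for this task. Classification uses cross-entropy.

Measured desk-scale behavior (all computed by the test suite): a 3-topology
classifier (CCCCO/COCOC/CCOOO) trained on 500 histograms of 10⁵-sample
series reaches roughly half correct (chance 1/3) — experiments with
ground-truth (noise-free) idealization and with 10× longer series show the
binding constraints are the information content of a 1-second recording over
the full 10²–10⁵ s⁻¹ rate range and the estimator's capacity at this
training-set size, not the simulator or detector. A COCOC rate regressor at
the same scale beats the random baseline decisively (median RAE ≈ 0.75
vs ≈ 0.94). Accuracy improves with series length and training-set size, which
is the intended scaling direction of the method.

## Command line (`cli`)

`channelsim simulate | histogram | make-dataset | train | predict` are thin
wrappers over the library, driven by one YAML file. A single `--seed` drives
every stage through per-stage substreams
(`SeedSequence([seed, stage_id])`), so outputs are bit-reproducible; every
command appends seeds and output hashes to a JSON-lines run log.
`predict --goodness` emits V̄_D, V̄_R, per-rate percentiles (10/25/50/75/90)
and a difference histogram against the first re-simulation.

## What the synthetic data does and does not emulate

The simulator reproduces the statistics that drive this analysis: exponential
dwell mixtures of a hidden chain, filter-limited rise times, and
SNR-controlled stationary noise (white-filtered or spectrum-matched). It does
not model open-channel noise, baseline drift, capacitive artifacts, seal
breakdown, or amplifier nonlinearity. Tests passing on synthetic data
therefore validate the method under ideal stationarity; on real recordings
the idealization step additionally depends on preprocessing quality, and a
measured step response and noise spectrum should be supplied to close the
realism gap.

## Numerical choices

- Dwell binning: `floor(10·log10(d/t_min))`, clamped to [0, 59]; exact edges
  land in the upper bin.
- Detector ties: transition samples are forced strictly increasing so dwells
  stay positive even under pathological chatter; a detection whose
  back-estimate precedes the previous boundary is placed one sample after it.
- Initial detector class: nearest level to the median of the first five
  samples.
- V_D of two empty histograms is undefined and raises; a histogram with
  fewer than two retained events is returned empty and flagged, not an error.
- Stationary distribution requires strictly positive rates (an absorbing or
  disconnected chain raises).
- Training restores the weights of the best validation epoch; a non-finite
  loss raises immediately.
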
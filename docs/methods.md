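# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `mlecg`, and what the synthetic-data experiments do and
do not demonstrate.

## Signal model and the synthetic generator

Each synthetic beat is a sum of five Gaussians — P, Q, R, S, T — placed at
fixed offsets relative to the R apex. Defaults (amplitude mV, offset s,
width s): P (0.15, −0.20, 0.025), Q (−0.10, −0.04, 0.012), R (1.0, 0, 0.015),
S (−0.15, +0.04, 0.012), T (0.30, +0.30, 0.06) — typical lead-II magnitudes
for a normal adult rhythm. The single base waveform is projected onto the 12
leads by scalar gains spanning 0.2–1.5 (lead II = 1.0, aVR and aVL negative),
which reproduces the strong cross-lead correlation of clinical records
without a torso/dipole model. RR intervals receive multiplicative Gaussian
jitter (default relative SD 0.02, clipped at ±3σ). Three noise processes are
injected independently per lead: a sub-0.5 Hz sinusoid (plus optional random
walk) for baseline wander, a mains-frequency sinusoid with random phase, and
white Gaussian noise band-passed to 20–150 Hz and rescaled to the requested
standard deviation for EMG. Default records are 10 s at 500 Hz.

Because the clean waveform is analytic, the generator emits the exact sample
index of every R apex. What the generator does **not** emulate: pathological
morphology (ST shifts, widened QRS, P-wave absence), ectopic beats,
electrode pops, inter-patient variability, or realistic class imbalance.
Passing tests on this data therefore demonstrate that the pipeline and the
network recover structure that is present by construction — correctness and
learnability — not clinical performance.

## Preprocessing

* **Baseline removal.** The per-lead running median over a window of
  `round(0.9·fs)` samples (forced odd; 451 at 500 Hz) is subtracted. The
  0.9 s parameter is interpreted as the window length in seconds: a window
  longer than one beat at normal rates makes the median track drift rather
  than QRS energy. Edges use reflect padding.
* **FIR band-limiting.** Hamming-window FIR low-pass at 40 Hz and high-pass
  at 2 Hz, order 8 (9 taps), applied forward–backward per lead so the net
  group delay is zero and R-peak positions are not displaced. An order-8
  high-pass at 2 Hz/500 Hz is deliberately weak — the median stage carries
  most of the baseline removal; the order is configurable.
* **R-peak detection.** 5-level Haar DWT (symmetric extension for
  non-dyadic lengths, reconstruction truncated to the input length); only
  detail bands 4 and 5 are kept in the inverse transform. Candidates are
  local maxima of the absolute detection sequence above 0.5× its maximum
  (a relative threshold, so detection is scale-equivariant), separated by a
  200 ms refractory period (physiological ceiling of 300 bpm), then refined
  to the argmax of the original signal within ±0.05 s. Detection runs on
  lead II; the annotation is shared across leads. Q and S are the
  minimum-amplitude extrema within 0.1 s before/after each apex; windows
  clipped by the record edge are clamped and flagged.
* **EMG removal with QRS protection.** Every [Q, S] interval (overlaps
  merged) is zeroed and stashed; the remaining signal is tracked by a scalar
  random-walk Kalman filter (state x_t = x_{t−1} + w, observation
  y_t = x_t + v; process variance 1e−4 mV², measurement variance 1e−2 mV²).
  Each non-QRS segment is filtered independently with the state
  re-initialised at its first sample, so zeroed regions cannot bleed
  transients into the output; the stashed QRS samples are then restored
  bit-exact. The filter is causal by default; an RTS smoothing pass is
  available by configuration. The random-walk model is the minimal state
  space consistent with "suppress broadband noise between beats"; its
  steady-state gain K = M/(M+R) with M = (Q + √(Q²+4QR))/2 is exposed and
  used as a closed-form oracle in the tests.
* **Rate conversion and trim.** Polyphase rational resampling (2/5 for
  500→200 Hz) with built-in anti-aliasing, then 50 samples dropped from each
  end, leaving 12×1900 for a 10 s record.

## The cross-masked convolution

Two readings of the cross support are shipped. `full_cross` (default) keeps
the whole centre row and centre column of a k×k kernel (2k−1 weights);
`strict_n4` keeps only the centre and its four orthogonal neighbours
(5 weights). They coincide at k=3; for k≥5 only `full_cross` gives larger
kernels additional reach, which is why it is the default. Masking is
implemented by summing shifted tensor contractions over the active offsets
only — numerically identical (to machine precision) to a dense convolution
with elementwise-masked weights, which serves as the independent oracle in
the tests. Gradients at masked positions are zeroed and the weights
re-masked after every optimiser step, so off-cross weights are exactly zero
at all times.

## Network, fusion and training

The layer stack is NumPy with explicit, finite-difference-verified backward
passes; everything runs in float64 on one CPU, bit-deterministically given
the seed. Choices where the design was genuinely open:

* The BiLSTM reduces its sequence by concatenating the final forward and
  final backward hidden states (256-d for 128 hidden units per direction);
  mean-pooling over time is available by configuration. Standard LSTM gate
  equations are used, with a forget-gate bias of 1.
* The fully-connected head ends in a linear projection 64→n_classes with
  softmax; the 64-d post-ReLU activation before that projection is the
  record's feature vector, exposed by `featurize`.
* The loss is categorical cross-entropy (mean negative log-probability of
  the true class), which reduces to the binary form at n_classes = 2.
* α is stored unconstrained and initialised at 0.7; a sigmoid
  reparameterisation is available by configuration. It receives the
  gradient Σ ∂L/∂v · (v₁ − v₂).
* Dropout rate defaults to 0.5 (0.1 in the reduced configuration); one
  integer seed drives initialisation, shuffling and dropout.
* Batch-norm uses batch statistics during training and running statistics
  (momentum 0.1) for prediction.
* Plain-CNN (mask disabled) and single-channel (CNN-only / BiLSTM-only)
  ablations are configuration flags.

## Problem sizes for desk-scale experiments

The `ModelConfig.small()` variant (conv maps 4/8/16, 32-d channel features,
16 hidden LSTM units per direction, head 64/32/16, batch 20, 30 epochs)
trains on 40 synthetic records — two classes differing in heart rate
(60 vs 150 bpm) and R amplitude (1.0 vs 0.5 mV) under mixed noise — in
about a minute on one CPU. These are the sizes used by the test suite and
the acceptance script; the full-size architecture is exercised forward-only.

## Numerical conventions

All sample indices are 0-based; QRS regions are closed intervals [Q, S].
Max-pooling drops trailing odd rows/columns (12→6→3→1, 1900→950→475→237)
and routes gradients to the first maximum on ties. Metric display uses
half-up rounding to two decimals with full precision retained internally;
SE/SP are flagged undefined (not NaN) for empty positive/negative classes.
Macro averages are taken over the classes where a metric is defined.

## Known limitations

* The five-Gaussian beat model makes Q/S delineation easier than on
  clinical morphologies with slurred or notched complexes.
* The directional behaviour of the learned α (rhythm-dominant classes
  pulling it down, morphology-dominant classes pulling it up) is **not**
  stable in the scaled-down regime: with fully separable two-class data the
  network can reach zero loss before α moves appreciably, and the drift
  direction varies with the seed. The tests therefore assert α's
  learnability (it moves from its initialisation under backpropagation),
  not a drift direction.
* The causal Kalman filter introduces a small tracking lag on steep
  non-QRS slopes (T-wave flanks); the RTS option removes it at the cost of
  a second pass.
* Training at clinical scale (10⁵ records, 100 epochs, full widths) is out
  of reach of this CPU implementation; the package targets correctness and
  small-scale experimentation, not throughput.
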
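# Methods

## Model

One dual-channel module couples two ladders. Per channel c, Conv Blocks
compute C_k^c = ConvBlock_k(C_{k−1}^c) with C_0^c the raw `(3000, 1)` epoch;
a Conv Block is two same-padded stride-1 1-D convolutions (ReLU) followed by
temporal max-pool (size 2, stride 2, floor) and dropout 0.2. The Bi-LSTM
ladder consumes B_1 = BiLSTMBlock_1(concat[C_1^1, C_1^2]) and, for k ≥ 2,
B_k = BiLSTMBlock_k(concat[C_k^1, C_k^2, B_{k−1}]); a Bi-LSTM Block is a
bidirectional LSTM (per-step outputs kept), the same pooling, and dropout.
Because both ladders floor-halve the time axis once per level, the
concatenations align by construction (conv lengths 1500/750/375/187, coupled
outputs 750/375/187/93). The head flattens B_4 (93 × 256 = 23,808 features
at default scale) into a dense five-way softmax.

Interpretation choices, made where the architecture description is textual
rather than machine-readable, all surfaced as configuration:

- **Coupling topology.** "Conv features coupled with the input at every
  level" is realized as feature-axis concatenation of both channels' level-k
  conv outputs with the pooled level-(k−1) Bi-LSTM output. The dimension
  pairing 2u_k = m_k (16/32 → 32/64 → …) is enforced at spec construction;
  it is what makes the level-k concatenation width m_k + m_k + 2u_{k−1}
  well-formed all the way up the ladder.
- **Kernel size.** Not specified by the architecture ladder; default 5 taps,
  stride 1, same padding, so pooling alone controls sequence length.
- **Bi-LSTM merge.** The per-step merge activation is the identity: the
  output is the plain concatenation of forward and re-reversed backward
  hidden states (the conventional bidirectional merge).
- **Head.** Flatten of the last Bi-LSTM block into a single dense softmax
  layer; no intermediate dense layers.
- **Weight sharing.** The two channels' conv streams do not share weights.
- **Fusion.** The fused model concatenates the two modules' flatten-level
  feature vectors (2 × 23,808 = 47,616 at default scale) under a fresh dense
  head. With the backbones frozen, only the head's 238,085 parameters train.

## Training procedure

Two stages, fixed epoch counts, no early stopping, no learning-rate
schedule, no class weighting: pre-train each dual-channel module
(default 80 epochs), freeze every backbone parameter, fuse, retrain the head
(default 40 epochs). Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7), learning rate
0.001, batch size 256, categorical cross-entropy on one-hot stage labels.
Mini-batches are reshuffled every epoch from the run seed; the last short
batch is kept. The "validation" curve recorded per epoch is computed on the
held-out 15% test partition — a deliberate mirror of common practice in this
literature, noted here as a methodological quirk rather than endorsed.

Frozen backbones are treated as fixed inference-mode feature extractors
during fusion retraining: dropout is inactive inside them and no gradients
flow through them. This is both the faithful reading of "parameters kept
unchanged" and a large compute saving — the backbone features of the
training set are extracted once and the head trains on the cached matrix.

Prediction is the argmax of the softmax probabilities, ties broken toward
the lowest stage code; inference is deterministic (dropout off), so repeated
forward passes are bit-identical.

## Preprocessing

- **Label mapping.** Sleep-EDF dialect strings map W→0, stage 1→1, stage
  2→2, stages 3 and 4→3 (merged slow-wave class), R→4; movement time and
  unknown are excluded and never enter an epoch set. The alias table is
  configurable.
- **Epoching.** Half-open 30 s windows anchored at annotation onsets; an
  annotation spanning k epoch lengths tiles into k consecutive epochs;
  trailing partials are dropped. All channels must share one rate first:
  the 1 Hz EMG is upsampled by zero-order hold (a tonic envelope reading;
  block-mean downsampling is the inverse), giving every channel the
  `(3000, 1)` epoch shape.
- **Normalization.** Per-channel min-max, x_N = (x − x_min)/(x_max − x_min),
  with extrema fitted on the training partition only and applied unchanged
  to the test partition (leakage avoidance; the fitting scope is our
  choice). Training extrema map to exactly {0, 1}; out-of-range test values
  are not clipped. A constant channel maps to 0 with a logged warning.
- **Splitting.** Stratified per-class 85/15 with `round(0.85·n_c)` training
  epochs per class, seeded. Stratification is chosen because published
  per-class train/test counts sit at ≈85/15 within every class; a global
  (unstratified) split is available.

## Synthetic data

The generator emulates the *discriminative spectral structure* of the five
stages, not their physiology: W = alpha (8–13 Hz) + beta with frequent EOG
deflections and high EMG tone; S1 = theta with attenuated alpha; S2 = theta
background + 12–14 Hz spindle bursts + biphasic K-complex transients;
S3 = high-amplitude delta (0.75–3.5 Hz); REM = saw-tooth train + large EOG
deflections + minimal EMG tone. Band frequencies are drawn uniformly within
each band per epoch; events are Poisson-counted with Gaussian envelopes;
Gaussian noise is added (sd 5 µV at "easy" separability, 6× at "hard"). All
amplitudes are invented fixture values tuned once so the classes are
separable by spectral energy alone. EMG is synthesized at 1 Hz and
zero-order-held, so the 1 Hz fixture storage round-trips exactly.

What passing tests therefore show: the architecture, optimizer, freezing
contract, and metric pipeline are correct, and the model can learn cleanly
separable spectral classes. What they do not show: performance on real PSG,
which has inter-subject variability, artifacts, stage transitions within
epochs, and severe class imbalance that these recipes do not model.

EDF fixtures are written with per-channel physical ranges padded 0.5% around
the observed extrema; the 16-bit quantization error is span/65534 per
channel, and the round trip (write → read → resample → segment) reproduces
labels exactly and samples within one quantization step.

## Numerical choices

- Compute is single precision by default (`sleepfusion._nn.DTYPE`); the
  engine is verified in double precision against finite differences
  (relative error ~1e-6 across the full coupled architecture).
- Parameters initialize fan-based uniform (Glorot) from the build seed;
  LSTM forget-gate biases start at 1 (the standard recurrent-initialization
  practice), all other biases at 0.
- Convolution is evaluated as k time-shifted GEMMs in flattened
  batch-time coordinates; the bidirectional LSTM runs both directions in one
  fused loop with the input projection hoisted out of the recurrence, and
  backpropagation through time is hand-derived.
- Pooling floors odd lengths; both ladders floor identically, preserving
  alignment. Pool ties route to the earlier sample.
- Metric degeneracies (zero denominators, e.g. a class absent from truth
  and predictions) yield 0 with a `degenerate` flag, never an exception.
- Cohen's kappa defaults to the standard form (P_o = trace/N). A literal
  variant substituting the mean one-vs-rest accuracy for P_o — a formulation
  that appears in parts of the sleep-staging literature — is selectable as
  `variant="literal_avg_acc"` but never default, since it is not a chance-
  corrected agreement in Cohen's sense.

## Problem sizes used by the test suite and acceptance script

End-to-end checks run a quarter-scale model (filters 8/16/32/64, units
4/8/16/32) on 500 easy-separability epochs (100 per class; 425/75 split),
5 pre-training + 3 fusion epochs, batch 64 — sizes chosen as the package's
reduced study conditions so the full two-stage procedure, including
freezing, executes in minutes on one CPU core. Batch 64 (rather than the
full-scale 256) gives the short schedule enough optimizer steps to learn;
the learning rate stays at 0.001. Across seeds 1–5 this configuration
reaches 96–100% test accuracy against a 20% majority-class baseline.

## Limitations

- No artifact rejection, AASM re-scoring, subject-wise splitting, or
  cross-validation; epoch length is configurable but only 30 s is exercised.
- The NumPy engine targets clarity and CPU-scale experiments; full-scale
  (filters 32–256) training on whole-night corpora is out of its intended
  range.
- The EDF writer covers the standard 16-bit layout and one annotation
  channel — sufficient for fixtures and Sleep-EDF-style files, not a general
  EDF+ authoring tool.
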
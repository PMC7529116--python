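# Methods

## Problem and pipeline

Myoelectric prosthetic control needs a movement label every few hundred
milliseconds from surface-EMG, on hardware with little memory and no
floating-point luxury. The package implements a single-channel recognition
pipeline whose computational footprint is reduced at two points: the
classifier *input* (keep only local extrema of each analysis window) and the
classifier *storage* (share trained fully connected weights through a
codebook). Everything else is a conventional small 1-D CNN used one-vs-all
in a serial cascade.

Processing order: record (or synthesize) → segment into 250 ms windows with
50% overlap → normalize with training-set statistics → Min/Max compress →
train K binary CNNs → share FC weights offline → cascade classify →
report metrics and operation counts.

## Synthetic data generator

No recordings ship with the package; a seeded generator emulates the
acquisition protocol: per session, 5 s of rest followed by 4 trials of 10 s
task activity at 1000 Hz; two sessions per subject (one when emulating
amputated participants, `sessions=1`). Labels are exact by construction:
the first 5000 samples are rest (0), each trial block carries its class
index and 1-based trial id.

The signal model is amplitude-modulated band-limited noise:
zero-mean Gaussian noise, band-passed with a zero-phase 4th-order
Butterworth and rescaled to unit variance, multiplied by a smooth burst
envelope, plus a baseline noise floor (std 0.05 a.u.) that alone makes up
the rest periods. The envelope is a plateau at 60% of the class amplitude
with Hann-shaped bursts up to 100%, at the class's burst rate — a held
contraction with rhythmic modulation. In-trial variance therefore exceeds
rest variance by a wide margin (the generator's tests require > 3×).

Class statistics (`make_class_params`) make the K classes separable on three
axes, chosen once and seeded:

- envelope amplitude: log-spaced, `0.75 · 1.55^i` a.u. with ±5%
  multiplicative jitter — amplitude is the classical single-channel cue
  (RMS-type features), and a geometric grid keeps *relative* spacing
  constant across classes. For many classes the dynamic range grows
  accordingly, which 16-bit acquisition headroom accommodates.
- burst rate: 1–4 bursts/s, cycling, ±0.2 jitter.
- spectral band: ±60 Hz around centers spread linearly over 80–380 Hz —
  different movements recruit tissue with different dominant frequency
  content at a fixed electrode.

What the generator does **not** model: motor-unit physiology, electrode
cross-talk, inter-channel correlation (channels are independent when more
than one is requested), electrode shift, fatigue, or inter-subject
variability beyond the seeded jitter. A green end-to-end test therefore
establishes that the pipeline's machinery works and that its compression
stages cost little accuracy *in a world whose class structure survives
extrema subsampling* — it is not evidence about any real recording.

All randomness flows through explicit `numpy` SeedSequences keyed by
(seed, class, subject, session); no global RNG state, bit-reproducible.

## Windowing and normalization

W = round(window_ms · fs / 1000) samples (round-half-up; 250 ms → 250
samples at 1000 Hz), hop = round(W·(1−overlap)). Windows are emitted only
inside maximal runs of constant (label, trial), so no window straddles a
task boundary; rest windows are dropped by default. Normalization is pooled
zero-mean/unit-variance fitted on training windows only and applied
unchanged to validation data; the default split holds out trial 2 and
trains on trials 1, 3, 4, mirroring the trial-wise protocol. A single
global normalizer (not per-subject) is used, matching training that pools
all subjects.

## Min/Max compression

A sample is an extremum iff strictly greater than both neighbours (max) or
strictly smaller (min) — the two-comparator rule; plateau members and
endpoints never qualify. The retained values, in original order, are tail
zero-padded or head-kept truncated to L = round(0.584·W) (146 for W=250,
117 for W=200). The variable-length policy is not dictated by the
reference design (146 is likely a dataset average); zero-padding was chosen
as the least information-adding completion, and both L and the policy sit
in the API rather than being hard-coded. The entropy diagnostic uses 32
equal-width bins over the window's own range — few enough bins for stable
estimates from 250 samples.

## The binary CNN

Topology (defaults): conv(7 filters × 5, stride 1, valid) → ReLU →
maxpool 2 → dropout 0.5 → conv(7 × 5 on 7 maps) → ReLU → maxpool 2 →
dropout 0.5 → flatten → 2-way softmax. Valid padding is used because the
streaming hardware pipeline naturally shrinks feature maps; pooling is
non-overlapping with floor on odd lengths. Under these rules a 250-sample
input flattens to 413 features and a 146-sample input to 231.

A historically reported figure of 213 fully connected neurons for the
compressed model cannot be reproduced from these shapes under any standard
padding (231 under valid padding, and 213 is not divisible by the 7 feature
maps); the package defaults to the derived shapes and exposes `fc_hidden`
for readers who interpret the figure as an extra hidden dense width.

Training: categorical cross-entropy, RMSprop (lr 0.001, ρ 0.9, ε 1e-7),
batch 15, at most 50 epochs, no early stopping (validation is monitored for
reporting only). Dropout is active only in training, so trained-model
inference is deterministic. Class imbalance of the one-vs-all framing is
surfaced through precision/recall/F1 reporting; an inverse-frequency
`class_weight` option exists but defaults off. `shuffle_labels` is a
permutation control that destroys the signal/label association — useful as
a null in selection experiments and tests.

The network is implemented directly in numpy (im2col-style convolution via
stride tricks, exact backprop, RMSprop); no deep-learning framework is
required, and training is bit-reproducible given a seed. Gradients were
verified against central finite differences during development.

## Weight sharing

`share_weights` keeps the local extrema of a weight sequence and assigns
every other position the value of its nearest extremum by index distance,
ties to the left — the minimal rule that turns the triangular-looking
trained weight sequence into the square-wave-looking shared one, given that
no explicit interval length is available. The rule is isolated behind a
single function so alternatives can be swapped without touching callers.

The extremum set used for the *partition* is the non-strict one
(≥/≤ both neighbours). On real-valued trained weights, where exact ties
have probability zero, this coincides with the strict comparator rule; the
non-strict form is what makes sharing exactly idempotent — under a
strict-only rule, a single-point plateau of the output (an extremum whose
two neighbours are themselves extrema) would remain a strict extremum and
collapse further on a second pass.

Sharing is applied offline, row-wise: each output neuron's incoming FC
weight vector is one sequence (a `flat` mode concatenating the whole matrix
exists). Convolution weights and all biases are untouched. Storage
accounting at b-bit words: unshared `n·b`; shared `v·b + n·ceil(log2 v)`
for v distinct values — the comparison is reported per model, never
assumed, because small models can lose (index overhead > value savings).

## Cascade and evaluation

Classifiers are tried strictly in task order; the first with task
probability ≥ 0.5 (the argmax of the 2-way softmax) labels the window, and
a window that fires no classifier is rest. This mirrors serial hardware
weight loading; an option to order by validation precision exists but
defaults off for fidelity. The batch path evaluates all models per batch
for speed but is asserted (in tests) to agree with the serial short-circuit
semantics.

Metrics: accuracy from the (K+1)-class confusion matrix, macro
precision/recall/F1 over task classes, and ROC AUC — binary from a score
vector, multi-class as the macro average of per-task one-vs-rest AUCs from
the per-classifier probability matrix. Metric computation is delegated to
scikit-learn; the test suite cross-checks AUC against an exhaustive
Mann-Whitney pair-statistic oracle.

Hyper-parameter selection uses nested k-fold cross-validation grouped at
the trial level: the inner loop scores each grid point by mean inner-fold
validation accuracy on outer-training trials only, the winner is retrained
and scored once on the held-out outer fold, and fold records carry the
provenance tags needed to assert leak-freedom. Grid points that fail to
build or train are logged and excluded rather than aborting the search.

## Complexity accounting

Per convolution layer, M = O_V·F_V·K·N multiplications and
A = O_V·(F_V−1)·K·N additions — the accumulations inside each per-map
kernel dot product; cross-map partial-sum merges belong to the pipelined
adder stage and are excluded, as are pooling/ReLU/softmax comparisons
(listed separately). Dense layers are reported in the same units as
in·out multiplications with out·(in−1) accumulations plus bias adds.
Multi-channel scaling multiplies conv/pool costs by n and widens the
flatten (hence dense input) n-fold, with both totals re-derivable from the
per-layer parts — an identity asserted on every report.

## Numerical and design notes

- Rounding of W and hop is round-half-up (integral anyway at 1000/2000 Hz
  for 250/200 ms).
- Softmax is computed with max-subtraction; cross-entropy adds 1e-12 inside
  the log.
- Glorot-uniform initialization, seeded separately from the shuffling /
  dropout stream so `shuffle_labels` does not perturb initial weights.
- `max_epochs=0` returns the initialized, untrained model with empty
  history (useful as a null).
- Degenerate configs (a layer shrinking below one sample) raise shape
  errors naming the offending layer.
- The end-to-end acceptance test trains 8 binary models for 50 epochs each
  (4 tasks × {raw, compressed}) — about 3 minutes on one CPU; everything
  else in the suite runs in seconds.

## Known limitations

- The CNN supports stride > 1 in the forward pass but training assumes the
  default stride 1 (the only configuration used).
- Multi-channel complexity scaling is analytical only; the generator can
  produce independent channels but the trainer consumes one channel.
- The rest class is never trained explicitly: rest is the cascade's
  fall-through, and rest windows are excluded from training by default
  (`drop_rest`), with inclusion available as a flag.
- Synthetic separability is by construction; none of the headline accuracy
  figures obtained on real recordings can be reproduced or checked here.
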
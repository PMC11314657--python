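# Methods

## Problem setting

The package implements a subject-dependent EEG emotion-recognition
pipeline for DEAP-structured recordings: per subject, 40 trials of 40
channels (the leading 32 are scalp EEG in the 10-20 montage) sampled at
128 Hz for 63 s, of which the first 3 s precede the stimulus; each trial
carries continuous valence and arousal ratings on a 1-9 scale.  Ratings
are binarized at 5 into high/low valence and arousal and crossed into
four affect quadrants.  Because the DEAP recordings themselves are
access-restricted, the pipeline ships with a synthetic generator that
reproduces exactly this structure, and every empirical claim the test
suite makes is a claim about that generator's output.

## Feature extraction

Each trial is decomposed into theta (3-8 Hz), alpha (8-14 Hz), beta
(14-31 Hz) and gamma (31-45 Hz) with a 4th-order Butterworth filter
applied forward-backward (zero phase, so window boundaries are not
phase-shifted).  The filter order is this package's choice; only the
family is prescribed.  The filtered trial is cut into non-overlapping
0.5 s windows (64 samples), and each window of each band of each channel
is summarized by four scalars:

* **Differential entropy** `DE = 1/2 ln(2*pi*e*sigma^2)`, with `sigma^2`
  the window's sample variance (ddof = 1); natural log, since the
  Gaussian closed form requires a consistent base.  A zero-variance
  window is a degenerate-input error rather than `-inf`.
* **Power spectral density**: the autocorrelation (Wiener-Khinchin)
  spectrum evaluated at the DFT frequencies and averaged over them.  The
  average over frequencies of that spectrum equals the window's mean
  squared amplitude (Parseval), i.e. the average band power, which is
  what the feature is meant to capture; the implementation uses the
  periodogram identity `P(w_k) = |X(k)|^2 / M`, and the test suite holds
  it to the literal O(M^2) lag double sum at 1e-8.
* **Nonlinear energy**: `mean(y^2 + H[y]^2)` where `y` is the window's
  first difference and `H` the Hilbert transform (imaginary part of the
  analytic signal of `y`).  Edge samples participate; the sinusoid
  oracle in the tests tolerates the resulting ~1% edge effect.  The mean
  runs over the M-1 samples of the differenced signal.
* **Petrosian fractal dimension**
  `FD = log10(N) / (log10(N) + log10(N / (N + 0.4 N_delta)))` with
  `N_delta` the number of sign changes between consecutive raw samples.
  This form satisfies the sanity limits FD = 1 iff `N_delta` = 0 and
  strict monotonicity in `N_delta`.  Counting on raw samples keeps the
  FD = 1 limit exact for sign-constant monotone signals; in the pipeline
  the operator only ever sees band-passed, hence zero-mean, windows, so
  a DC offset cannot suppress the count in practice.

Baseline correction subtracts the mean feature vector of the six 0.5 s
baseline windows from every stimulus window, per (band, feature,
channel); the corrected series holds stimulus windows only.  Features
are then z-scored per subject over all stimulus windows of all trials,
per (band, feature, channel) slot — per-subject scope matches the
subject-dependent evaluation protocol.  Slots with zero spread (up to
rounding) are set to zero with a warning.

## Spatial mapping and fusion

Per-channel scalars are scattered onto an 8 x 9 flattening of the 10-20
montage; cells without an electrode stay zero.  The exact cell
assignment is the conventional arrangement used by 3D/4D EEG-CNN work
and ships as an editable YAML resource (`catm/data/grid_8x9.yaml`) —
it is a documented convention, not a measured fact, so it is kept out of
the code.  The four band maps stack into a 4 x 8 x 9 block per feature,
and the four feature blocks fuse by concatenation into 16 planes
(default), or elementwise addition / multiplication (4 planes) for the
fusion ablations.  Channel-subset experiments (18 and 5 emotion-relevant
electrodes) zero out the masked electrodes.

## Network

Frames (planes x 8 x 9) pass through:

1. a 1 x 1 stem convolution lifting the planes to 80 channels;
2. two blocks of **CSAM + FTM**.  CSAM runs 1 x 1, 3 x 3 and 5 x 5
   convolutions to 128 channels each plus a 3 x 3 same-padding max pool
   keeping 80, every branch with batch norm + ReLU, concatenated to 464
   channels, then gated by **FSAM**: per-channel weights from the
   spatially pooled average through a bottleneck MLP (reduction 8) plus
   a standalone bias term, sigmoid-squashed; then per-location weights
   from the channel-max map through a 3 x 3 convolution, ReLU and
   sigmoid.  FTM (batch norm, 1 x 1 reduction to 80, 3 x 3 same-padding
   max pool, ReLU) returns the block to 80 channels; all spatial
   operations preserve the 8 x 9 grid.
3. flattening (80 x 72 = 5760), a linear projection to 1414, a
   bidirectional LSTM with 35 units per direction over the 6-window
   (3 s) sequence, and a fusion linear 70 -> 128;
4. a deep classifier 128 -> 64 -> 32 -> classes with ReLU and dropout
   0.5 between layers.

### How the open sizes were fixed

The published description pins the CSAM widths (80 in, 3 x 128 + 80 =
464 out), the classifier (128/64/32), dropout 0.5, and a total of
9,478,504 trainable parameters, but leaves open the stem transition,
block count, projection width, recurrent size, and attention internals.
We searched those jointly for configurations whose per-layer counts
(PyTorch counting conventions: affine batch norm = 2C, biases on convs
and linears, LSTM with both input and recurrent biases) sum to the
published total exactly.  No configuration with a 64-unit-per-direction
LSTM feeding the classifier directly achieves it; adding a fusion linear
between the Bi-LSTM's concatenated output and the 128-wide classifier
input frees the hidden size, and the unique solution closest to the
described structure keeps two CSAM+FTM blocks, attention reduction 8, a
3 x 3 spatial-attention kernel, attention in every block, and a binary
head, with projection 1414 and hidden size 35.  The parameter-budget
test verifies the count against an independent closed-form per-layer
sum.

### Ablation variants

Model 1 removes the convolutional blocks (stem straight to the temporal
stage); Model 2 removes FSAM, which the tests show is equivalent to
clamping every attention multiplier at 1; Model 3 replaces the temporal
stage by a per-frame linear to 128 and a temporal mean; Model 4 replaces
the deep head by a single linear layer.  Single-scale variants replace
the four CSAM branches by one k x k convolution (k in {1, 3, 5}) to 128
channels.  Models 1, 3 and 4 are strictly smaller than the full model in
parameters, a structural claim the suite asserts.

## Numerical substrate

The network, backpropagation and Adam run on a compact reverse-mode
autodiff engine over numpy arrays (`catm.nn`): convolutions are
same-padding/stride-1 via im2col and BLAS matmuls, pooling and batch
norm have hand-derived backward passes, and every layer is checked
against central finite differences in float64.  The engine computes in
float32 by default for speed; batch norm uses batch statistics during
training and running averages (momentum 0.1) at evaluation.  There is no
hidden global randomness — initialization, shuffling and dropout all
draw from explicitly passed seeded generators, and repeated runs are
bit-identical.

## Training and evaluation

Adam with learning rate 1e-3, cross-entropy plus an L2 penalty
(coefficient 1e-4; the protocol names L2 but no value), dropout 0.5,
batch size 128, a 50-epoch budget with best-epoch selection on training
loss — all defaults in `TrainConfig`.  Evaluation is per-subject
ten-fold cross-validation; a sample is a sequence of six consecutive
0.5 s stimulus windows of one trial, labeled by the trial.  By default
folds shuffle samples directly, matching the published protocol of
dividing each participant's dataset; `block_by_trial` keeps whole trials
on one side of the split, and with per-sample labels the blocked split
is stratified so each class's trials spread evenly over folds.  Metrics
are accuracy, precision, recall and F1 computed exactly from the fold's
confusion matrix (class 1 positive for binary tasks; one-vs-rest macro
averages for the four-class task, where only the binary forms are
prescribed).  Ratings of exactly 5 go to the high class — the
binarization rule only covers strictly above/below 5 — and the tie rule
is configurable.

## Synthetic data: what it does and does not show

Each trial is a sum of four band-limited oscillations (carrier drawn
inside each band's edges, away from the boundaries so the filter bank
separates them cleanly) with base amplitudes 4/3/2/1.5 (theta through
gamma, falling with frequency), plus half white / half 1/f-shaped
Gaussian noise of unit scale.  Emotion classes modulate band amplitudes
multiplicatively in named scalp regions — the standard planted effect
doubles frontal gamma for high arousal and parietal/occipital beta for
high valence — and only during the stimulus segment, so baseline
correction provably removes none of the class signal.  Ratings are drawn
with balanced high/low halves per dimension, guaranteeing non-empty
strata.  The eight auxiliary channels carry noise only.

The generator emulates DEAP's geometry and a clean, strongly localized
band-power code.  It does not emulate artifacts, non-stationarity,
volume conduction, inter-subject variability, or any temporal structure
in the class signal, so passing the learnability checks demonstrates the
pipeline is wired correctly and can recover a planted spectral-spatial
code — not that the architecture attains any particular accuracy on real
EEG.

## Reduced-scale study conditions

The end-to-end statistical checks run at a scale chosen for desk-side
reproducibility: four subjects, 20 trials each (10 per class per
dimension), 12 s of stimulus (four 6-window sequences per trial, 80
samples per subject), the toy network widths (`ModelConfig.toy`: stem 8,
branch 8, one block, projection 64, hidden 16; the classifier keeps its
full 128/64/32 widths because dropout 0.5 over a handful of units makes
a tiny head collapse-prone under aggressive optimization), batch size
16, 20 epochs.  At these widths and sample counts the optimizer uses a
3e-3 step instead of the full-scale 1e-3 to converge within the
20-epoch budget.  Learnability folds are trial-blocked and stratified: with ten
folds and ten trials per class, every fold holds out exactly one trial
of each class, so the training set stays balanced and the null
condition sits at chance.  Window-level splitting would instead let the
network recognize a test window's trial from training windows of the
same trial — real leakage that inflates null accuracy; the blocked
split is the honest measurement of whether the signal carries the
label.  The ablation-direction check repeats a paired full-vs-ablated
comparison on one subject and one held-out fold over ten seeds and
counts how often the ablated model fails to beat the full one; it
checks the direction of the published ordering, not its magnitudes.

## Known limitations

* Headline accuracies on real DEAP data are out of reach by design; the
  synthetic benchmarks bound only the pipeline's correctness.
* The electrode-to-cell table reproduces a community convention; if the
  original grid differs in a few cells, spatial attention maps would
  shift accordingly (the YAML resource makes this a data edit).
* The engine is CPU-only and optimized for the 8 x 9 grids used here;
  it is not a general-purpose deep-learning framework.
* Cross-subject generalization is explicitly out of scope.
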
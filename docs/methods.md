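# Methods

## Model

The classifier is a fully convolutional/recurrent many-to-many network over
channel-major series `x ∈ R^{w_in × L}` sampled at a fixed rate. Its unit of
composition, the FilterNet layer module (FLM), applies, in order: channel
dropout (whole input channels dropped with probability `p_drop`, train mode
only, survivors rescaled by 1/(1−p)); either a same-padded 1-D convolution
with ReLU (kernel `k`, odd) or a bidirectional LSTM (hidden size `w_out/2`
per direction, outputs concatenated); average pooling with kernel = stride =
`s`; and per-channel batch normalization (statistics over batch × time,
running statistics in eval mode). Same-padding plus kernel-matched pooling
makes the module *coverage preserving*: output sample `j` summarizes input
span `[j·s, (j+1)·s)`, so `L_out = ceil(L_in / s)`, exact division whenever
`s | L_in` (the training path only uses such lengths; otherwise the series
is right-padded with zeros before pooling).

Convolutions carry no additive bias when a batch-norm follows — the shift is
redundant and this convention is what reproduces the reference parameter
counts (e.g. 113·100·5 + 2·100 = 56,700 for the full-resolution layer). The
output module, which has no batch-norm, carries a bias (100·18 + 18 = 1,818).
For the bidirectional LSTM module the package reports its true trainable
count, `2·[4H(w_in + H) + 8H] + 2·w_out` with `H = w_out/2` (61,000 for the
reference 100-wide module including batch-norm); the conventionally quoted
figure for that module (80,500) is not reproduced by any standard
bias-inclusive accounting we know of, and is deliberately not asserted.

### Component architecture and reference variants

Components: **A** full-resolution CNN; **B** pooling stack 1 (`n_p1 = 3`
stride-2 layers ⇒ output stride ratio 8); **C** pooling stack 2, widths
halving layer-to-layer by `w_i = ceil(w_{i−1}/2)` (100 → 50, 25, 13, 7; the
final layer keeps `s = 1`); **D** linear-interpolation resampling of every C
output to the network output length, concatenated with the last B output
(100 + 50 + 25 + 13 + 7 = 195 channels at reference widths); **E** a `k = 1`
bottleneck CNN; **F** bidirectional LSTM stack; **G** a `k = 1` output CNN
with softmax. Variants: `b_lstm` = F+G (stride 1), `p_cnn` = A+B+G,
`p_cl` = A+B+F+G, `ms_cnn` = A+B+C+D+E+G, `ms_cl` = all. Width scaling
multiplies every width by a factor (rounded to nearest, floor 1, kept even
for LSTMs); class count never scales.

Interpolation in D uses the align-ends convention (first/last output sample
coincide with first/last input sample), which preserves constant series
exactly — the property the tests pin. When a C output has a single sample it
is broadcast.

### Region of influence

Two quantities are deliberately distinguished:

- `roi_after_stack` implements the conventional ROI recurrence
  `ROI_i = ROI_{i−1} + (k_i − 1)·Π_{j≤i} s_j`, the form that reproduces the
  reference tables (5, 13, 29, 61, 125, 253, 509, 765 for the multi-scale
  conv stack; 61 for the pooled stack). This is the number quoted when
  comparing architectures.
- `exact_receptive_field` composes pre-images back-to-front
  (`R → R·s + (k−1)`) and gives the exact maximal number of input samples
  that can influence one output sample of a conv→pool stack (40 for the
  pooled stack, 576 for the multi-scale stack).

The two coincide exactly when every stride is 1; for strided stacks the
conventional metric is an upper bound (it accrues each kernel's reach at the
*post*-pooling scale). The empirical perturbation probe in the test suite
verifies equality on unstrided stacks and (probe = exact formula ≤ ROI
metric) on strided ones. Any LSTM makes the region the entire input; the
package represents that with an infinite sentinel.

## Windowed inference

Long inputs are segmented by a sliding window (default 512 samples, 50 %
overlap); windows start at multiples of the step with the final window
right-aligned, and inputs shorter than one window are zero-padded (padding
discarded from the output). Two reassembly rules:

- **Hanning overlap-add** (default, works for every architecture): output
  sample = weight-normalized average of the covering windows' logits, with
  Hanning weights on the output-sample axis floored at 1e−6 so samples
  covered by a single window (the global ends) reduce to the raw window
  output. Averaging acts on logits — consistent with fold ensembling — and
  probabilities are recomputed afterwards. The taper suppresses window-edge
  effects rather than removing them: within ~ROI/2 of an interior window
  boundary, the contaminated window retains relative weight sin²(πd/L_w),
  leaving residuals of order 1e−3 in the logits; everywhere else the
  reconstruction matches the unsegmented forward pass to numerical precision.
- **ROI-trim** (CNN-only networks, overlap ≥ ROI): windows are concatenated
  after discarding half of each overlap. This is *exactly* identical to the
  unsegmented pass outside ROI/2 of the global ends, and is the efficient
  choice for finite-ROI networks.

Windows are batched so one forward pass holds ≈50k input samples.

## Training

Defaults (and the ranges they were designed for): max 100 epochs, Adam
(RMSProp available) at initial learning rate 1e−3 decayed ×0.95 per epoch,
L2 weight decay 1e−4, 512-sample training windows stepped by 16 *output*
samples (the step is interpreted on the output axis so window starts stay
aligned with output bins), batches of round(5000/512) = 10 windows, patience
10. The loss is cross-entropy over every output sample; the null class is an
ordinary class. Per-output-sample training labels are the *mode* of the
input labels in each stride-ratio-wide bin (ties to the smaller label):
majority voting preserves short events better than plain subsampling, which
the label-downsampling tests exercise.

Early stopping uses a checkpoint metric built for noisy validation curves:
`raw_e = l_v / F1w_v` (validation loss over validation weighted F1, floored
at 1e−6), smoothed by an EWMA with half-life 3 epochs
(`α = 1 − 2^{−1/3} ≈ 0.2063`, initialized at the first raw value, no bias
correction), plus an instability penalty — the population standard deviation
of the most recent ≤5 raw values (0 at the first epoch). A checkpoint is
recorded whenever the sum reaches a new minimum; training stops once
(current epoch − last checkpoint epoch) ≥ patience, and the checkpointed
weights (including batch-norm running statistics) are restored. With a
monotone noise-free history, checkpoints recur every epoch once the
5-epoch window has filled; before that the filling window can inflate the
instability term.

Determinism: a single integer seed drives weight initialization, window
shuffling and dropout through one NumPy generator; two runs with the same
seed produce bit-identical histories on a single CPU thread.

## Ensembling

`make_folds(L, n)` splits the pooled train+validation range into `n`
contiguous folds whose lengths differ by at most one sample (remainder to
the leftmost folds). Sub-model `i` validates on fold `i` and trains on the
concatenation of the rest; sub-models share architecture and schedule and
differ only by fold and a seed offset (`seed + i`). Fold boundaries may
split an event; each part stays in its fold. At inference the sub-models'
logit series are averaged elementwise and the softmax is applied once to the
mean, so an ensemble of identical models reproduces a single model exactly.

## Metrics

Sample-based: per-class F1 from confusion counts; `F1m` = unweighted mean
over non-null classes (classes absent from both truth and prediction score 0
and are excluded; if no non-null class occurs at all, `F1m = 0` by
convention); `F1w` = support-weighted mean over *all* classes; `F1w_nn` =
support-weighted mean over non-null classes.

Event-based: per non-null class, maximal runs with probability strictly
above 0.5 become detected events (an exact 0.5 is not an event); intervals
are half-open and touching intervals do not overlap; matching is per class.
Each actual event is Correct, Deleted (no overlapping detection), Fragmented
(>1 overlapping detections; Fragmented-and-Merged if a fragment also merges),
or Merged (its single detection spans other actuals); detected events are
categorized dually (Correct', Insertion', Fragmenting', Merging', both).
Category counts partition each side and C = C′ always. With TP = C,
FN = D+F+M+FM, FP = I′+F′+M′+FM′ summed over classes,
`F1e = 2TP/(2TP+FP+FN)` (0 when all counts are 0). Events count once
regardless of duration.

## Synthetic data

The generator emulates the statistical regime the method targets — not the
biomechanics. Defaults: 12 channels, 6 classes including null, 30 Hz,
30k samples, 0.6 expected events per 1000 samples per class with uniform
durations of 20–100 samples (so the null class holds ≈80 % of samples),
unit-variance Gaussian background, and per-class signatures = a DC offset
plus a sinusoid (amplitude and offset drawn once per class from [1, 2],
frequencies spread over ~1.5–10 Hz, random phase per event) injected into a
fixed random third of the channels. Events of any class never touch
(one-sample margin), so the label series round-trips through event
extraction. Missing data arrives in geometric bursts (mean length 5) at 2 %
of samples per channel. Generation is infeasible (error) when the expected
labeled occupancy exceeds 80 %.

What passing tests do and do not show: the signatures are band-limited and
stationary within events, channels are independent Gaussian, and event
boundaries are crisp — so parameter recovery here demonstrates that the
training loop, architecture wiring and metrics work end-to-end, not that the
defaults would suffice for real accelerometry with inter-subject variation,
drift, or label noise.

Preprocessing mirrors the standard pipeline: linear interpolation of missing
samples (edges held constant), then per-channel standardization using the
*training* split's mean/sd (zero-variance channels floored at 1e−8 with a
warning). Applying the returned statistics to held-out series preserves
shifts in standardized units, and re-preprocessing an already standardized
series is a no-op.

## Problem sizes used in the shipped experiments

The parameter-recovery experiment trains a quarter-width `ms_cnn` (14,290
parameters) on a 3-class, 8-channel, 40k-sample synthetic series (24k train /
8k validation / 8k test) for up to 20 epochs; it reaches F1m ≈ 0.94 while a
label-shuffled control stays near chance. The ensembling experiment trains
3 folds of the same architecture for up to 8 epochs. These sizes were chosen
as the smallest at which the qualitative phenomena (learnability, ensemble
benefit, stopping dynamics) are stable across seeds.

## Known limitations

- Batched LSTM execution is a Python loop over time steps; fine at the
  shipped scales, slow for reference-width LSTMs on long series.
- The conventional ROI metric overstates the exact receptive field of
  strided stacks (see above); both numbers are exposed.
- Multi-output heads, multi-label/regression outputs, GRUs, dilation and
  streaming (unidirectional) variants are out of scope; the config surface
  leaves room for them but nothing is implemented.
- The benchmark-dataset adapter follows the de-facto challenge column
  selection and split composition but is exercised only by its error paths
  in the test suite (the data requires an external download).
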
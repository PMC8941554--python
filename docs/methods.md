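# Methods

## Problem setting

`sigcpc` classifies fixed-length physiological signal *epochs* — e.g. 30 s
windows of single-channel EEG at 100 Hz (3000 samples, five sleep stages
W/N1/N2/N3/REM) or resampled ECG beats (AAMI classes N/S/V) — under the
realistic constraint that only a small fraction of epochs carries an expert
label. The package implements a two-step scheme based on contrastive
predictive coding (CPC):

1. a **self-supervised pretext task** trains an epoch encoder on
   *constructed* labels that need no annotation, and
2. a **lightweight supervised classifier** reuses that encoder, so the
   scarce real labels only have to fit a small head.

## Pair construction

The pretext supervision comes from *sample pairs* of 8 epochs arranged
4 + 4:

* **positive pair** (label 1): 8 distinct epochs of one class, split into a
  left block (the "training set" half) and a right block (the "waiting
  training set" half);
* **negative pair** (label 0): 4 distinct epochs of one class on the left,
  4 distinct epochs of a *different* class on the right.

Within a pair no epoch repeats; across pairs epochs recur freely, which is
what lets a modest dataset supply thousands of training iterations per
epoch of optimization. Batches are balanced (positive fraction 0.5 by
default) so that chance-level loss is ln 2 and chance pair accuracy 50%.
Positive classes are drawn uniformly over classes; negative class pairs
uniformly over ordered unequal pairs. Note that constructing pairs consumes
class labels — the pretext task is *self-supervised with respect to the
downstream loss* (no label enters a gradient through the softmax head), and
the label-fraction study below is the operational test of label efficiency.

## Pretext model

* **Encoder `g_enc`** — four identical blocks (dense → batch-norm → ReLU)
  with widths 256, 128, 128, 128, then a dense output layer to a latent of
  width `d_z = 64`. Batch-norm uses batch statistics (momentum 0.9 running
  updates) during training and running statistics at inference, so encoding
  is deterministic in infer mode.
* **Context `g_ar`** — a GRU with hidden width `d_c = 64` consumes the four
  left-block latents in order; its final hidden state is the context `c`.
* **Multistep prediction head** — per-step linear maps `W_k : R^{d_c} →
  R^{d_z}`, `k = 1..4`, score each right-block latent by inner product,
  `s_k = ⟨W_k c, z_k^W⟩`; the pooled score `s = mean_k s_k` is squashed to a
  pair probability `p = σ(s)`.
* **Loss** — mean binary cross-entropy between `p` and the pair label:
  `L = −(1/N) Σ_i [y_i log p_i + (1−y_i) log(1−p_i)]`, probabilities
  clipped at machine-epsilon bounds. This is the minimal CPC-consistent
  head compatible with a scalar binary target; an InfoNCE-style softmax
  loss over in-batch negatives (each context scored against every pair's
  right block, diagonal targets) is available via `loss="infonce"` for
  comparison, but the binary objective is the default and the one all
  results use.

Training: Adam at learning rate 1e-3 (the downstream default; the pretext
rate is otherwise unconstrained), default 20 epochs × 1000 iterations of
32-pair batches. Pair accuracy is `1[p > 0.5]` against the pair label,
evaluated each epoch on fixed held-out pair sets.

All layers (dense, batch-norm, GRU, 1-D conv, Adam) are implemented
directly in numpy with hand-written backpropagation in float64; gradient
correctness is verified end to end by finite-difference tests through both
composed models.

## Downstream classifier

Each input epoch is replicated four times (`[x, x, x, x]`) so the encoder
sees the same length-4 block layout it was pretrained on; since the four
copies are identical the implementation encodes once and tiles the latent,
which is mathematically identical (duplicated rows leave batch statistics
unchanged). The latent sequence then passes through two *different* 1-D
convolutions — conv1 (64 filters, kernel 3) and conv2 (32 filters, kernel
2), valid padding, so the time axis shrinks 4 → 2 → 1 — global average
pooling, and a dense softmax over the classes. Loss is categorical
cross-entropy on one-hot targets.

The learning rate starts at 1e-3 and is reduced to 1/3 whenever validation
loss fails to improve for 2 consecutive epochs ("improve" = lower than the
best so far by ≥ 1e-4; the wait counter resets after each reduction; floor
1e-6 to avoid underflow after many plateaus). Early stopping is not
applied; `max_epochs` bounds training. The encoder is fine-tuned by default
(`encoder_trainable=True` — its parameters are loaded, not frozen); a
freeze flag supports linear-probe comparisons.

## Evaluation

`confusion_matrix` uses rows = true class, columns = predicted class.
Per-class precision = 100·diag/column-sum, recall = 100·diag/row-sum, F1
their harmonic mean; macro F1 is the unweighted mean of per-class F1 (this
definition — not the F1 of macro precision/recall — is what reproduces the
published table); accuracy = 100·trace/total. Values are carried at full
precision and rounded half-up to two decimals only for display. A class
never predicted (zero column) or never present (zero row) gets 0 for the
undefined ratio with a degenerate-class warning — needed for tiny synthetic
runs.

The shipped five-stage benchmark confusion matrix (42,308 epochs) is used
as a fixture: the metric code must reproduce all 15 per-stage percentages,
overall accuracy 88.70% and macro F1 88.09 exactly at two decimals, and its
row sums must match the per-stage epoch totals.

Because the published full-dataset table was computed by feeding the entire
dataset to the classifier, the label-fraction harness supports both
evaluation scopes (`heldout`, `full`, or `both`) and labels each row of its
results accordingly; held-out is the default.

## Synthetic data generator

Real downloads are out of scope, so the generator emulates the one premise
the method rests on: same-class epochs share latent structure. Class `c`
produces `amp_c · sin(2π f_c t + φ) + ε`, with a fresh uniform phase per
epoch and i.i.d. Gaussian noise. Defaults: 5 classes, frequencies
(10, 5, 13, 1.5, 7.5) Hz loosely mirroring alpha/theta/sigma/delta/mixed
sleep rhythms, amplitudes (1.0, 0.8, 1.2, 2.0, 0.9) with the slow delta
class largest, noise sd 0.3 ("moderate": about a third of the typical
signal amplitude), 100 epochs per class. With `noise_sd=0` the classes are
perfectly separable by the dominant DFT bin, which tests use as an
independent oracle.

What the generator does **not** emulate: real EEG/ECG morphology
(spindles, K-complexes, QRS shapes), nonstationarity within an epoch,
class imbalance, inter-subject variability, or label noise. Passing the
synthetic studies therefore shows that the pipeline's machinery works and
that pretraining transfers signal structure to the classifier — not that
the published benchmark numbers would be reproduced on real recordings.

## Study problem sizes

The synthetic studies run at a reduced scale chosen as the package's
standard desk-scale configuration: 500 epochs of length 256 (5 classes ×
100), a 9:1 stratified train/test split, pretext training of 5 epochs ×
200 iterations of 32-pair batches, and downstream fine-tuning for up to 30
epochs with batches of 16. The label-efficiency comparison uses the 10%
point of the canonical fraction grid (10/30/50/70/100%) over three seeds,
with a 20% validation split of the labeled subset feeding the plateau
monitor. Under these conditions the pretext task reaches ≈100% held-out
pair accuracy and the pretrained classifier holds ≈97% test accuracy at
10% labels versus ≈72–84% from scratch (seed-dependent).

## Numerical and design choices

* Float64 throughout; loss probabilities clipped at machine epsilon;
  softmax and sigmoid use max-shifted / two-branch stable forms.
* Splitting is stratified (simple random splitting would add class-balance
  variance to small runs); `label_mask` rounds per class and errors if any
  class would receive zero labels.
* The GRU block length `t = 4` matches the pair half-size and is
  configurable.
* Conv specs, pooling, encoder widths and `d_z = d_c = 64` are the
  package's own choices — large enough to separate five classes, small
  enough for CPU training.
* Resampling (e.g. 128 Hz → 251 Hz for ECG beats) uses polyphase filtering
  with a rational approximation of the rate ratio.
* Epoch-matrix text files carry `#`-prefixed `key=value` headers and one
  `label amplitude...` row per epoch; the `.npz` dialect round-trips
  bit-exactly. Checkpoints embed a format-version field plus the producing
  run configuration and seed.

## Known limitations

* Training is single-threaded numpy; the default 20 × 1000 pretext regime
  is minutes-scale on one CPU for length-256 epochs but slow for raw
  3000-sample epochs — reduce widths or iterations, or pre-decimate.
* No class-imbalance handling (oversampling is deliberately out of scope).
* No sequence-of-epochs context modeling: each epoch is classified alone.
* Raw EDF/WFDB parsing is excluded; users export epoch matrices with their
  own tooling (any array library can write the text dialect).
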
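# sigcpc

Contrastive-predictive-coding (CPC) pretraining and label-efficient
classification for fixed-length physiological signal epochs — EEG sleep
stages, ECG beats, and any other "epoch matrix" of windows with integer
class labels.

Expert labels for medical sensor data are expensive; unlabeled recordings
are not. `sigcpc` implements a two-step scheme: a self-supervised *pretext
task* first trains an epoch encoder on constructed pair labels, then a
lightweight convolutional classifier reuses that encoder so the scarce real
labels only need to fit a small head. The package is pure
numpy/scipy/scikit-learn (the networks and backpropagation are implemented
in-repo) and ships a synthetic-data generator so everything is testable
without downloads.

## Method in brief

A *sample pair* is 8 epochs arranged 4 + 4: positive (label 1) when all 8
share one class, negative (label 0) when the two halves come from two
classes. An encoder `g_enc` (4 × dense–batchnorm–ReLU blocks + dense
output, latent width d_z) maps each epoch to `z`; a GRU `g_ar` summarizes
the left-block latents into a context `c`; per-step linear maps `W_k` score
the right-block latents by inner product, `s_k = ⟨W_k c, z_k^W⟩`, and the
pooled score yields the pair probability `p = σ(mean_k s_k)`. The pretext
loss is mean binary cross-entropy

    L = −(1/N) Σ_i [ y_i log p(y_i) + (1 − y_i) log(1 − p(y_i)) ]

The downstream classifier replicates each epoch four times (matching the
encoder's pretrained block layout), encodes, applies two different 1-D
convolutions (64 filters/kernel 3, then 32 filters/kernel 2), pools and
classifies with a softmax under categorical cross-entropy; the learning
rate starts at 1e-3 and drops to 1/3 after two epochs without validation
improvement. Evaluation reports the confusion matrix, per-class
precision/recall/F1, macro-averaged F1 (MF1) and accuracy (ACC).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from sigcpc import (
    SynthConfig, generate_dataset, split_dataset, label_mask,
    PretextConfig, train_pretext,
    TrainConfig, build_classifier, train_classifier,
    evaluate_classifier,
)

# 5 classes x 100 epochs of length 256, class-specific oscillations + noise
data = generate_dataset(SynthConfig(n_classes=5, n_per_class=100,
                                    epoch_length=256, seed=42))
train, test = split_dataset(data, test_fraction=0.1, seed=42)   # 9:1, stratified

# step 1: self-supervised pretraining on sample pairs
model, hist = train_pretext(train, test,
                            PretextConfig(epochs=5, iterations_per_epoch=200, seed=0))
print(f"pretext pair accuracy  train {hist.train_accuracy[-1]:.2f}  "
      f"test {hist.test_accuracy[-1]:.2f}")

# step 2: fine-tune a classifier using only 10% of the training labels
labeled = train.subset(label_mask(train, 0.1, seed=0))
fit, val = split_dataset(labeled, 0.2, seed=0)
clf = build_classifier(model.encoder, n_classes=5, seed=0)
clf, _ = train_classifier(clf, fit, val, TrainConfig(max_epochs=30, seed=0))
report = evaluate_classifier(clf, test)
print(report.to_text())
```

Output (seed 42/0):

```
pretext pair accuracy  train 1.00  test 1.00
true\pred       W      N1      N2      N3     REM   PR(%)   RE(%)   F1(%)
       W      10       0       0       0       0  100.00  100.00  100.00
      N1       0      10       0       0       0  100.00  100.00  100.00
      N2       0       0      10       0       0  100.00  100.00  100.00
      N3       0       0       0      10       0  100.00  100.00  100.00
     REM       0       0       0       0      10  100.00  100.00  100.00
Macro avg                                                          100.00
     ACC  100.00%
```

The pretrained encoder separates the five synthetic classes so well that
the 10%-label classifier (45 labeled epochs) classifies the held-out test
set perfectly here; the identical architecture trained from scratch on the
same 45 labels lands around 72–92% depending on the seed — that gap is the
label-efficiency benefit the pretext task exists to deliver. (`label_fraction_experiment` runs the
full 10/30/50/70/100% grid over seeds and both modes and returns a tidy
table.)

## Command line

```sh
sigcpc simulate --classes 5 --per-class 100 --epoch-length 256 --out epochs.txt --seed 1
sigcpc pretrain --input epochs.txt --out encoder.npz --epochs 5 --iterations 200 --seed 1
sigcpc train    --input epochs.txt --encoder encoder.npz --out model.npz --seed 1
sigcpc evaluate --input epochs.txt --model model.npz --out report.tsv
sigcpc label-fraction --input epochs.txt --out grid.tsv --seed 1
```

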
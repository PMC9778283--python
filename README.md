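# ecgdelin

Self-supervised delineation of ECG fiducial points.

Clinically, reading an electrocardiogram starts from the *fiducial*
(characteristic) points of each heartbeat: the onset, peak and
termination of the P wave, the QRS complex and the T wave. `ecgdelin`
implements a self-supervised deep-learning pipeline that locates eight
such points — P-on, P-peak, P-off, QRS-on, R-peak, QRS-off, T-peak,
T-off — on single-lead beat windows, for researchers who want accurate
delineation without large expert-annotated corpora.

## Method

**Pretext stage.** Beats are cut around the R peak (1.2 s windows,
resampled to 300 samples) and each beat spawns four training samples:
the original signal (pseudo-label 0) and its noise-added (1),
amplitude-scaled (2) and time-inverted (3) versions. A network trained
with cross-entropy (Adam, 5-fold cross-validation) to recognize which
transformation a signal underwent learns beat morphology with **no
human annotations**.

**Backbone.** A 1D DenseNet: each dense layer computes
`X_t = H([X_0; X_1; …; X_{t−1}])` (BN → ReLU → 1×1 bottleneck → BN →
ReLU → 3×1 conv, concatenated onto its input). After each dense block a
convolutional block attention module (CBAM) reweights the feature map:
channel attention `M_c = σ(W_1 W_0 X_avg^c + W_1 W_0 X_max^c)` followed
by spatial attention `M_s = σ(f_3([X_avg^s; X_max^s]))`. Transition
layers (1×1 conv + stride-2 average pooling) halve channels and length.
The head applies feature-pyramid pooling: the final (20, 128) map plus
its 2× and 4× average-pooled versions are each flattened and projected
to 256, concatenated (768) and passed through fully connected layers to
the output. With growth rate 32 and (8, 4, 2) layers per block the
channel sequence is 64 → 320 → 160 → 288 → 144 → 208 → 104 on lengths
324 → 162 → 81 → 40 → 20.

**Downstream stage.** The convolutional backbone (including batch-norm
statistics) is transferred and frozen; the fully connected layers are
He-reinitialized and fine-tuned with L1 loss (SGD, lr 0.001, momentum
0.9, 8:2 train/test split, cross-validated early stopping) to regress
the eight fiducial coordinates.

**Evaluation.** Signed deviations between predicted and reference
positions, mapped back to source samples and milliseconds (1 sample =
4 ms at 250 Hz), reported per point as m ± sd with the R peak excluded
(it anchors the window); plus the mean absolute error of the per-point
mean deviations, Bland–Altman 95% limits of agreement and regression of
predicted on annotated positions. For two-lead records each lead is
processed independently and the lead with the smaller mean absolute
deviation is selected per recording.

A synthetic-beat generator (Gaussian P/Q/R/S/T waves with known
onset/peak/offset ground truth, RR jitter, noise and baseline wander)
makes the whole pipeline testable without downloading any database; a
minimal WFDB-compatible reader/writer covers PhysioNet-style record
directories (format-16 signals, MIT annotation format).

## Worked example

```python
import numpy as np
from ecgdelin import (generate_population, PretextClassifier,
                      FiducialRegressor)
from ecgdelin.preprocess import prepare_downstream
from ecgdelin.nn import NetConfig
from ecgdelin.training import TrainConfig

beats = generate_population(300, seed=1)          # synthetic, known truth
raw = np.stack([b.samples for b in beats])        # (300, 300) at 250 Hz

pre = PretextClassifier.from_beats(
    raw, seed=2,
    net_config=NetConfig.reduced(input_len=300, head="pretext"),
).fit(TrainConfig(epochs=20, folds=2, patience=8, seed=2))
print(pre.summary())

X, Y = [], []
for b in beats:
    x, y, _ = prepare_downstream(b.samples, [100], [b.truth], fs=250.0)
    X.append(x); Y.append(y)
X, Y = np.concatenate(X), np.concatenate(Y)

res = FiducialRegressor(X, Y, net_config=NetConfig.reduced(),
                        pretrained=pre).fit(
    TrainConfig(epochs=60, folds=2, lr=0.001, patience=20, seed=3))
print(res.summary())
```

This prints (exact numbers reproducible with these seeds):

```
Pretext transformation-recognition results
============================================
samples: 1200   folds: 2
fold 0: validation accuracy 0.992
fold 1: validation accuracy 0.990
mean validation accuracy: 0.991

Fiducial delineation results (held-out beats)
========================================================
beats: 300   held out: 60   pretrained backbone: yes (frozen)
validation L1: 2.082 samples   test L1: 2.231 samples

  point  mean_ms  sd_ms  abs_mean_ms  abs_sd_ms
   P-on     0.02  10.78         8.85       6.04
 P-peak    -0.75  10.46         8.26       6.37
  P-off    -0.91  12.03         9.38       7.49
 QRS-on     0.54  11.11         8.78       6.73
QRS-off    -1.69  11.73         9.38       7.13
 T-peak    -2.44  11.56         8.97       7.61
  T-off    -4.08  15.53        11.68      10.92

MAE of mean deviation: 1.49 ms
```

The near-perfect pretext accuracy says the four transformation classes
are cleanly separable, i.e. the backbone has learned beat morphology
without labels. The delineation table shows per-point biases of a few
ms (around one source sample at 4 ms) with beat-to-beat standard
deviations of ~3 samples, dominated by the generator's own timing
jitter. `res.plot_regression("T-peak")` and
`res.plot_bland_altman("T-peak")` draw the corresponding agreement
panels.

The same pipeline runs from the shell on WFDB-style directories:

```bash
ecgdelin simulate --out-dir data --name synth01 --n-beats 50 --seed 0
ecgdelin pretrain --records-dir data --out pretext.npz --seed 0
ecgdelin finetune --records-dir data --checkpoint pretext.npz --out model.npz
ecgdelin evaluate --records-dir data --model model.npz --out-dir reports
ecgdelin delineate --records-dir data --model model.npz --out points.csv
```

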
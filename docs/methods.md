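# Methods

## Problem and model

The package locates eight fiducial points on single-lead heartbeat
windows: P onset/peak/offset, QRS onset, R peak, QRS offset, T
peak/offset, in that strict temporal order. The estimator is a 1D
convolutional network trained in two stages.

### Pretext stage (self-supervised)

Beats are cut in a 1.2 s window around the R peak — 0.4 s before and
0.8 s after, converted to the source sampling rate — and resampled to
300 samples. Each beat yields four classification samples with
automatically generated pseudo-labels: 0 original, 1 noise-added,
2 amplitude-scaled, 3 time-inverted, in that fixed order. Training uses
cross-entropy, the Adam optimizer and k-fold cross-validation; the
reported pretext accuracy is the mean of the per-fold validation
accuracies and the retained checkpoint is the backbone of the best
fold.

Transformation parameters (nowhere fixed by the task definition) are
package defaults: noise at 15 dB SNR — visible but
morphology-preserving, with the drawn noise rescaled so the empirical
SNR is exact — and scaling factors drawn per beat uniformly from
[0.5, 0.8] ∪ [1.25, 2.0], bounded away from 1 so the class is
learnable. Beats on the pretext path are **not** amplitude-normalized;
per-beat z-normalization would make the scaling class unlearnable.

### Backbone

* Stem: kernel-7 convolution to 64 channels, BN + ReLU, kernel-3
  stride-2 max pooling.
* Three dense blocks with (8, 4, 2) layers, growth rate k = 32; each
  dense layer is BN → ReLU → 1×1 conv (bottleneck 4k) → BN → ReLU →
  3×1 conv producing k channels concatenated onto its input. The block
  layer counts and growth rate are fixed by the channel arithmetic
  64 + 8·32 = 320, 160 + 4·32 = 288, 144 + 2·32 = 208.
* A CBAM after each dense block, before its transition. Channel
  attention: shared two-layer perceptron (reduction ratio r = 8, no
  biases) applied to length-averaged and length-maxed descriptors,
  outputs summed and passed through a sigmoid. Spatial attention:
  channel-average and channel-max maps concatenated, kernel-3
  convolution to one channel, sigmoid. Both weights multiply the
  feature map sequentially, so CBAM is elementwise contractive.
* Transition layers: 1×1 convolution halving channels (floor), then
  stride-2 average pooling halving length (floor): 162 → 81 → 40 → 20.
* Tail: a stride-1 kernel-2 average pool with symmetric padding
  (20 → 21) followed by a valid kernel-2 convolution to 128 channels
  (21 → 20). The reference layer plan's length-increasing
  (20, 104) → (21, 104) pooling row is interpreted as exactly this
  padded pooling feeding the final convolution.
* Head: feature-pyramid pooling. The (20, 128) map, its 2× and its 4×
  average-pooled versions are flattened (2560 / 1280 / 640), each
  projected to 256 with ReLU, concatenated (768), then FC-256 → output
  (8 coordinates, or 4 logits for the pretext head). Dropout 0.2 sits
  between the backbone and the head.

The network input length is 324: it halves exactly down the transition
chain (324 → 162 → 81, unlike the alternative convention of 325) and
yields the (20, 128) backbone endpoint all head dimensions derive
from. Label mapping uses the same length, so the choice is
self-consistent end to end.

### Downstream stage (transfer)

Downstream windows take 100 samples before and 200 after the annotated
R peak (1.2 s at 250 Hz), after denoising, and are linearly resampled
to 324 samples; fiducial labels ride through the same affine map,
rounded half-away-from-zero, identically at train and evaluation time.
Beats whose window or labels fall off the record, or whose labels
collide after rounding, are skipped.

The convolutional backbone — weights *and* batch-norm running
statistics — is loaded from the pretext checkpoint and frozen: only
fully connected parameters receive updates, and backbone batch-norm
stays in inference mode, so frozen parameters are bit-identical across
the whole fine-tuning run. Fully connected layers are He-reinitialized.
Because the frozen backbone is deterministic, its features over the
training set are computed once and the head trains on the cache — the
same computation, orders of magnitude cheaper on CPU.

Optimization: L1 loss on the eight coordinates, SGD with fixed learning
rate 0.001 and momentum 0.9, 8:2 train/test split by beat, k-fold
cross-validation inside the training portion for early stopping
(patience 10 by default), best-validation model retained. The output
layer's bias is initialized to the mean training-set positions: with an
L1 loss and a small fixed learning rate the head then learns per-beat
residuals instead of spending the entire budget moving the bias across
the 0–324 coordinate range. Weight initialization remains He.

Input normalization is off by default in both stages: the pretext task
requires raw amplitudes, and a transferred backbone must see the same
input distribution it was pretrained on (its frozen batch-norm
statistics encode that distribution). Per-beat z-normalization remains
available (`normalize=True`) for single-stage supervised use.

## Evaluation

Deviations are computed in resampled coordinates, mapped back to source
samples by the factor 300/324, and converted to milliseconds by
1000/fs, so one source sample at 250 Hz is exactly 4 ms (the
back-mapping is the default; the alternative of treating one resampled
sample as 4 ms is exposed via `back_map=False`). The R peak is excluded
from reports since it anchors the window. Aggregates are per-point
mean ± sd of signed and of absolute deviations; the scalar comparison
statistic is the mean of absolute per-point mean deviations, averaged
over available points when a method does not report all seven, and
rounded to two decimals for reporting. Bland–Altman limits of agreement
are mean difference ± 1.96 × sample standard deviation (ddof = 1);
regression fits predicted on annotated positions by least squares with
|slope − 1| + |intercept| as the identity-closeness summary. For
two-lead recordings, leads are evaluated independently and the lead
with the smaller overall mean absolute deviation is selected per
recording, with ties going deterministically to the first lead
(per-beat selection would be lookahead-prone).

## Synthetic data

Each wave (P, Q, R, S, T) is a Gaussian bump `a·exp(−(t−μ)²/(2b²))`.
Ground truth: peaks at the Gaussian centres of P, R, T; onsets/offsets
at μ ∓ 3b of the outermost P/QRS/T Gaussians (beyond 3σ a Gaussian
retains < 0.3 % of its peak value, so the definition is deterministic
and clipping-safe); positions rounded half-away-from-zero and beats
whose 3σ supports would invert the ordering are rejected. The default
template (R at 0.4 s in a 1.2 s window at 250 Hz, P at 0.20 s,
T at 0.75 s, amplitudes 0.15/−0.10/1.00/−0.15/0.30 mV) matches a
normal-morphology beat under the downstream windowing convention.
Records concatenate beats with Gaussian-jittered RR intervals (clipped
at the template span), optional white noise and an optional < 0.5 Hz
baseline-wander sinusoid. Beat populations jitter amplitudes (±15 %),
widths (±10 %) and the P/T centres (σ = 12 ms) around the template
while keeping the R anchor fixed, so landmark regression is non-trivial
but learnable; default additive noise is 0.02 mV.

What the generator does **not** emulate: pathological morphologies
(ectopy, ST deviation, atrial fibrillation), inter-patient variability,
electrode artefacts, non-Gaussian wave shapes and realistic coloured
noise. Passing the synthetic recovery tests therefore demonstrates that
the pipeline is implemented correctly and can learn the mapping; it
does not certify clinical-grade accuracy on real ECGs.

## Denoising

Discrete wavelet transform with the db6 mother wavelet, 8-level
decomposition (capped at the maximum level the signal length allows);
the deepest approximation band (baseline wander) and the two finest
detail bands (high-frequency noise) are zeroed before reconstruction.
The wavelet is fixed by the method; the level/sub-band recipe is the
standard ECG choice and is exposed in the configuration.

## Desk-scale study conditions

The end-to-end benchmark (tests and `scripts/acceptance.py`) runs on
300 synthetic beats with a reduced architecture (stem 16, growth 8,
blocks (2, 2, 1), 64-wide head) — the full-scale architecture is
exercised by the shape and forward tests — with 20 pretext epochs /
2 folds and 60 downstream epochs / 2 folds, patience 8/20. These sizes
keep a full run to minutes on a single CPU while every stage still has
to learn: pretext validation accuracy must exceed 0.9 and held-out
landmark error must stay under 5 resampled samples per point. The
self-supervised-vs-scratch comparison trains both arms with identical
epoch/fold/early-stopping budgets on identical splits and compares
median best-validation L1 over three derived seeds; "equal budget" is
counted in epochs, which favours the scratch arm (it updates every
parameter per step, the transfer arm only the head). On this clean,
low-variability synthetic task the two arms typically land within a few
hundredths of a sample of each other, so the check establishes that
transfer from the pretext task is *not worse* than supervised training
— plus a large convergence-speed advantage — rather than a large
accuracy advantage; accuracy gains from self-supervision are a
real-data question outside what synthetic tests can show.

## Numerical choices

* All computation is float64 on a small reverse-mode autodiff core;
  runs are bit-reproducible given the seed.
* Batch-norm: eps 1e−5, momentum 0.1, biased variance in
  normalization, unbiased in the running estimate.
* Max-pooling splits gradient equally among tied maxima; padded
  max-pooling pads with −inf, average-pooling with zeros.
* Label rounding is half-away-from-zero everywhere.
* Adam uses (0.9, 0.999, 1e−8); early stopping requires improvement
  > 1e−9 to reset patience.
* The 8:2 downstream split is by beat (record-level splitting is the
  stricter alternative and can be composed by the caller feeding
  per-record beat sets).

## Known limitations

* The WFDB reader implements the format-16 subset (plus the MIT
  annotation byte format with SKIP escapes); real PhysioNet databases
  stored in format 212 require conversion before ingestion.
* Fine-tuning with an unfrozen backbone retrains batch-norm statistics
  on the downstream distribution; mixing that with the cached-feature
  path is deliberately not supported (the cache requires a frozen
  backbone).
* The pretext network's fully connected dimensions depend on the input
  length (300) and are discarded at transfer; only the convolutional
  backbone moves to the 324-length downstream network.
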
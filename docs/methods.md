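# Methods

## The model

`ednet` implements a compact convolutional classifier for seven-category
eye-disease photographs (Bulging_Eyes, Cataracts, Crossed_Eyes,
Diabetic_retinopathy, Glaucoma, Uveitis, Normal). The network is a stack of
seven blocks:

| block | content | channels |
|---|---|---|
| ED_Conv | 7×7 conv, stride 2, BN, swish6 | 3 → 64 |
| ED_Resnet | 1×1 → depthwise 3×3 → 1×1, BN each, swish6 at end, additive skip | 64 → 64 |
| ED_Xception | 3×3, 5×5, 7×7 same-channel convs, then channel-doubling 1×1 with swish6 | 64 → 128 |
| ED_Xception | same | 128 → 256 |
| ED_Resnet | same bottleneck pattern | 256 → 256 |
| ED_Xception | same | 256 → 512 |
| ED_Linear | global average pool + linear | 512 → 7 |

Only the stem is strided; all other convolutions use "same" padding
(`padding = (k−1)/2`), so a 224×224 input runs at 112×112 until the global
pool. The head emits logits; `predict_proba` applies a max-shifted softmax so
each row is a probability vector summing to 1.

### swish6

The activation is `swish(x) = x·σ(βx)` with the output fixed at 6 once the
input reaches 6, in the spirit of ReLU6's cap. The cap is implemented
literally as a piecewise function: `swish(x)` for `x < 6`, exactly 6 for
`x ≥ 6` (the boundary point is assigned to the cap branch to make the
function total). Because `swish(6) = 6σ(6β) < 6`, this form has a jump of
`6 − 6σ(6β)` (≈0.0148 at β=1) at the threshold; the continuous alternative
`min(swish(x), 6)` is available as `mode="min"`. β defaults to 1 and is
non-trainable; the derivative used in backprop is `σ(βx) + βx·σ(βx)(1−σ(βx))`
below the cap and 0 on it.

### Structural readings and the frozen interpretation

The structure table under-determines three choices, each exposed as a config
flag and all eight combinations measurable with
`ednet.complexity.interpretation_sweep()`:

* `separable_xception` — whether the ED_Xception k×k convolutions are dense
  or depthwise-separable (depthwise k×k + pointwise 1×1, each followed by
  BN, the Xception idiom);
* `xception_projection_skip` — whether each ED_Xception block carries a
  1×1-projected additive shortcut;
* `resnet_dw_kernel` — 3×3 (structure table) or 5×5 (block diagram) for the
  ED_Resnet depthwise convolution.

The sweep ranks each reading by mean relative error against the published
complexity row for this architecture (2.68 M parameters, 0.16 G MACs at
224×224). No reading reaches those cells: the dense reading gives
≈7.40 M / ≈92.7 G and the separable reading ≈0.56 M / ≈6.87 G. The published
MACs-to-parameters ratio (≈60 spatial positions) is inconsistent with the
constant 112×112 trajectory the table implies, which suggests the original
implementation downsampled between blocks and/or used a convolution mix the
table does not describe. The package freezes the sweep winner —
`separable_xception=True`, no projection skips, 3×3 depthwise — as the
default and reports its honestly computed totals; the counter itself is
validated exactly against the standard VGG16 reference graph
(138.36 M / 15.5 G) and against brute-force weight enumeration.

### Complexity conventions

One MAC (multiply-accumulate) is reported as one "FLOP". Dense convs count
`k²·cin·cout` weights, depthwise `k²·c`, BN `2c` parameters and zero MACs,
linear `cin·cout + cout`. Biases exist only where no normalization follows
(so the VGG fixture, which has no BN, counts biases; the BN-everywhere
classifier does not). MACs are weights-without-bias × output positions,
evaluated at 224×224 unless overridden. Pooling and activations cost zero.

## Training recipe

SGD with classical (non-Nesterov) momentum 0.9, L2 weight decay 4e-4 coupled
into the gradient, batch size 64, 100 epochs, initial learning rate 0.01
multiplied by 0.95 each epoch. The decay is per-epoch: a per-batch reading
of "95% each iteration" would collapse the rate to ~0.95^5400 ≈ 0 over a
full run and extinguish learning. The loss is mean softmax cross-entropy
computed via log-sum-exp. There is no validation split in the emulated
protocol, so the loop checkpoints the weights with the best test accuracy
and restores them at the end. BN scale/shift and biases are excluded from
weight decay, the usual convention.

Everything is implemented in NumPy: convolutions lower windows to columns
(im2col) and call one BLAS matmul; depthwise convolutions use a
strided-window einsum; each layer implements its own backward pass, checked
end-to-end against central finite differences in the test suite. Given the
same seed and BLAS backend, initialization, batching and updates are
bit-reproducible.

## Synthetic data generator

The generator emulates the *statistical* shape of the emulated collection —
seven classes, 3,451 train / 1,149 test images with heavy imbalance (24
Bulging_Eyes vs 823 Diabetic_retinopathy training images) — not any clinical
appearance. Each class has a procedural motif on a stylised eye (enlarged
eccentric sclera; lens opacity; displaced pupil; fundus-like field with
scattered bright lesions; enlarged pale disc; red ring; clean eye).
Separability `s ∈ [0,1]` blends motif against the class-neutral base
(`s=0` makes classes identical up to noise), and `σ ∈ [0,1]` adds Gaussian
pixel noise. Defaults: the emulated per-class counts, 224 px, `s=1`,
`σ=0.1` (mild sensor-like noise). Per-image jitter (eye centre, lesion
placement, gaze direction) comes from one seeded generator, so output is
byte-identical across runs.

Passing tests on this generator show that the architecture, gradients and
recipe can fit a cleanly separable image task; they say nothing about
performance on real fundus/external photographs, which differ in texture,
acquisition artefacts and intra-class variability.

## Desk-scale training conditions

The learning tests run a structurally identical network at width multiplier
1/8 (stem width 8), 48×48 input, on a balanced noise-free fully-separable
synthetic set of 60 train / 15 test images per class, batch size 8, 5
epochs, optimizer hyperparameters unchanged. These sizes keep a full run
around a minute on one CPU while leaving every architectural element
(residual skips, separable stacks, swish6, BN) exercised. At batch 8 the
default BN running-statistic momentum of 0.1 tracks the batch statistics too
slowly and makes eval-mode accuracy erratic, so the desk-scale configuration
uses `bn_momentum=0.3`; full-scale defaults keep 0.1.

## Numerical choices and degenerate inputs

* Network arithmetic is float32; losses and the pure activation module are
  float64.
* softmax and cross-entropy use max-shift / log-sum-exp; non-finite inputs
  and logits raise immediately (training aborts with a diagnostic on a
  non-finite loss).
* Pooling primitives reject odd spatial dimensions rather than invent a
  padding convention.
* The ED_Resnet bottleneck requires an even channel count; width scaling
  rounds the stem width to an even integer and derives the rest by the
  doubling chain, so arbitrary multipliers cannot produce an inconsistent
  channel chain.
* The residual shortcut resolves to elementwise addition (the only form
  under which the table's channel arithmetic balances); a
  concatenate-then-1×1 variant exists behind `resnet_skip="concat"`.
* Weight init is Kaiming fan-in normal from a seeded generator; BN starts at
  scale 1, shift 0, running stats (0, 1).

## Known limitations

* The published 91.66% real-data test accuracy is out of desk scope: it
  requires the external image collections and GPU-scale training.
* The published 2.68 M / 0.16 G complexity row is not reproduced by any
  reading of the printed structure table (see above); the package reports
  its own exact totals instead.
* The NumPy training stack is single-threaded BLAS-bound and intended for
  desk-scale experiments, not full 224×224 training runs.
* No augmentation, LR warm-up or validation protocol is implemented, since
  the emulated recipe specifies none.
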
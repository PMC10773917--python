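# ednet

A compact convolutional network for classifying photographs of seven common
eye conditions — Bulging_Eyes, Cataracts, Crossed_Eyes, Diabetic_retinopathy,
Glaucoma, Uveitis and Normal — together with exact architecture-complexity
accounting, a synthetic dataset generator, and a from-scratch NumPy training
stack. It is aimed at people studying efficient medical-image classifiers:
every structural element is declarative, countable and testable at desk
scale on one CPU, without the original image collections.

## The model

The classifier stacks seven blocks:

```
ED_Conv      7×7 conv, stride 2          3 → 64
ED_Resnet    1×1 ↓, depthwise 3×3, 1×1 ↑, additive skip   64 → 64
ED_Xception  3×3, 5×5, 7×7 convs, then doubling 1×1       64 → 128
ED_Xception                                               128 → 256
ED_Resnet                                                 256 → 256
ED_Xception                                               256 → 512
ED_Linear    global average pool + linear                 512 → 7
```

Every convolution is followed by batch normalization; rows marked *swish6*
use the clipped-swish activation `x·σ(βx)`, pinned to exactly 6 for inputs
`x ≥ 6` (a swish analogue of ReLU6's cap). Class probabilities come from a
max-shifted softmax, `P(z_i) = e^{z_i} / Σ_j e^{z_j}`.

Training follows the published recipe: SGD, momentum 0.9, weight decay
4e-4, batch size 64, 100 epochs, learning rate `0.01 · 0.95^epoch`, softmax
cross-entropy loss, best-test-accuracy checkpointing.

The complexity module counts parameters and multiply-accumulates (MACs,
reported as "FLOPs") exactly for any layer graph, validated against the
canonical VGG16 figures (138.36 M parameters, 15.5 G MACs at 224×224). The
structure table leaves three choices open (dense vs separable ED_Xception
convolutions, projection skips, depthwise kernel size); an interpretation
sweep measures all eight readings and the package freezes the one closest to
the published complexity row — see `docs/methods.md` for why none of them
reproduces that row exactly.

## Worked example

`examples/04_train_desk_scale.py` trains a width-1/8 network for 5 epochs on
the noise-free, fully-separable synthetic set (60 train / 15 test images per
class at 48×48) and prints:

```
dataset: 525 images at 48px (420 train)
network: width x0.125, 15,339 parameters
epoch   0  lr 0.01000  loss 1.7025  train acc 0.314  test acc 0.429
epoch   1  lr 0.00950  loss 1.0845  train acc 0.579  test acc 0.743
epoch   2  lr 0.00903  loss 0.8071  train acc 0.726  test acc 0.286
epoch   3  lr 0.00857  loss 0.4881  train acc 0.914  test acc 1.000
epoch   4  lr 0.00815  loss 0.3703  train acc 0.924  test acc 0.886

best-checkpoint held-out accuracy: 1.000
```

The learning rate column is the closed-form schedule `0.01·0.95^epoch`; the
loss falls monotonically and the best checkpoint (epoch 3) classifies all
held-out synthetic images. This demonstrates that the architecture, hand-written
gradients and recipe learn a cleanly separable image task — it says nothing
about accuracy on real fundus photographs, which are out of desk scope.

The other examples show the activation/pooling primitives
(`01_activations.py`), the complexity report and interpretation sweep
(`02_complexity.py`), and the synthetic generator's class structure
(`03_synthetic_data.py`).

## Command line

```bash
ednet generate-data --out data/ --seed 0          # synthetic 3451/1149 split
ednet summarize --sweep                           # layer table + complexity
ednet train --data data/ --out runs/ --seed 0
ednet evaluate --data data/ --checkpoint runs/checkpoint.npz
ednet predict --checkpoint runs/checkpoint.npz img1.png img2.png
```

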
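"""The clipped-swish activation and the pooling primitives.

Evaluates swish and swish6 at a few instructive points and runs the
2x2 pooling operators on a small feature map.
"""

import numpy as np

from ednet import avg_pool_2x2, max_pool_2x2, softmax, swish, swish6

xs = np.array([-5.0, 0.0, 1.0, 3.0, 5.9, 6.0, 10.0])
print("x      :", xs)
print("swish  :", np.round(swish(xs), 4))
print("swish6 :", np.round(swish6(xs), 4))
# swish6 follows swish below 6 and is pinned to exactly 6 from the threshold
# on -- the cap keeps activations bounded deep in the network.

grid = np.array([
    [5, 1, 10, 2],
    [0, 3, 4, 6],
    [9, 2, 7, 1],
    [8, 0, 3, 5],
], dtype=float)
print("\n4x4 feature map:\n", grid)
print("2x2 max pool  :", max_pool_2x2(grid).ravel())   # [5, 10, 9, 7]
print("2x2 avg pool  :", avg_pool_2x2(grid).ravel())
# each output pixel summarises one non-overlapping 2x2 window.

logits = np.array([1.0, -0.5, 0.3, 2.0, 0.0, -1.2, 0.7])
p = softmax(logits)
print("\nsoftmax(logits) =", np.round(p, 4), " sum =", p.sum())
# the 7 entries are class probabilities; the largest logit keeps the
# largest probability.
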
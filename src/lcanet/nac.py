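"""Nodule-adaptive convolution: input-weighted mixture of dilated branches.

Four parallel branches — a 1x1 convolution and three 3x3 convolutions with
dilation rates 2, 3 and 5 — give effective receptive fields of 1, 5, 7 and
11 pixels.  A small head (global average pool, one fully connected layer,
softmax) predicts a convex weight for each branch from the input itself, so
the block leans on small kernels for small or peripheral targets and on
large effective kernels for big central ones.  The weighted sum of branch
outputs passes through a 1x1 fusion convolution.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as onp

from . import ops
from .ops import conv2d, global_avg_pool, mish, softmax

DEFAULT_KERNELS = (1, 3, 3, 3)
DEFAULT_DILATIONS = (1, 2, 3, 5)


def effective_kernel_extent(kernel: int, dilation: int) -> int:
    """Spatial extent of a dilated kernel: (kernel - 1) * dilation + 1."""
    if not isinstance(kernel, (int, onp.integer)) or kernel < 1:
        raise ValueError(f"kernel must be a positive integer, got {kernel!r}")
    if not isinstance(dilation, (int, onp.integer)) or dilation < 1:
        raise ValueError(f"dilation must be a positive integer, got {dilation!r}")
    return (kernel - 1) * dilation + 1


def init_nac_block(rng, channels: int, kernels=DEFAULT_KERNELS,
                   dilations=DEFAULT_DILATIONS):
    """Parameters for the NAC block (branch convs, BN, weight head, fusion)."""
    if len(kernels) != len(dilations):
        raise ValueError("kernels and dilations must have equal length")
    k = len(kernels)
    return {
        "branches": [
            {
                "w": ops.he_conv(rng, channels, channels, ks, ks),
                "bn_gamma": onp.ones(channels),
                "bn_beta": onp.zeros(channels),
            }
            for ks in kernels
        ],
        "fc_w": ops.he_linear(rng, channels, k),
        "fc_b": onp.zeros(k),
        "w_fuse": ops.he_conv(rng, channels, channels, 1, 1),
        "bn_gamma": onp.ones(channels),
        "bn_beta": onp.zeros(channels),
    }


def branch_weights(params, x):
    """Convex branch weights alpha(x): GAP -> FC -> softmax over K branches.

    Rows lie on the probability simplex by construction (each in [0, 1],
    summing to one).
    """
    pooled = global_avg_pool(x)  # (N, C)
    logits = ops.linear(pooled, params["fc_w"], params["fc_b"])
    return softmax(logits, axis=-1)


def nac_forward(params, x, state, key, train=False,
                dilations=DEFAULT_DILATIONS, force_alphas=None):
    """NAC forward pass; spatial dims and channel count are preserved.

    y' = sum_k alpha_k(x) * mish(BN(f_k(x)));  y = mish(BN(g(y')))

    ``force_alphas`` (test hook) bypasses the weight head with fixed weights,
    e.g. a one-hot vector to isolate a single branch.
    """
    alphas = branch_weights(params, x) if force_alphas is None else force_alphas
    y = None
    for i, (br, d) in enumerate(zip(params["branches"], dilations)):
        h = conv2d(x, br["w"], dilation=d)
        h = ops.batch_norm(h, br["bn_gamma"], br["bn_beta"], state,
                           f"{key}.br{i}", train)
        h = mish(h)
        a = anp.reshape(alphas[:, i], (-1, 1, 1, 1))
        y = a * h if y is None else y + a * h
    y = conv2d(y, params["w_fuse"])
    y = ops.batch_norm(y, params["bn_gamma"], params["bn_beta"], state,
                       f"{key}.out", train)
    return mish(y)
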
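"""Backbone residual block built from factorized 7x1 / 1x7 large kernels.

A k x k kernel costs k^2 weights per channel pair; the factorized pair
(k x 1 followed by 1 x k) costs 2k, so at k=7 the large-kernel weights shrink
from 49 C^2 to 14 C^2 — a reduction of roughly 72% — while keeping the same
7 x 7 receptive field.  The block is residual: batch-norm, a 1x1 bottleneck
pair around a Mish nonlinearity, and an element-wise skip back to the input.
"""

from __future__ import annotations

import numpy as onp

from . import ops
from .ops import conv2d, mish


def param_reduction_percent(k: int) -> float:
    """Weight-count reduction (%) of a (k x 1, 1 x k) pair vs one k x k kernel.

    Counts kernel weights only (biases excluded) at fixed channel widths:
    100 * (1 - 2k / k^2).  k=7 gives ~71.4%.
    """
    if not isinstance(k, (int, onp.integer)) or k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {k!r}")
    return 100.0 * (1.0 - (2.0 * k) / (k * k))


def init_factorized_large_kernel(rng, channels: int, k: int = 7, bias: bool = True):
    """Parameters for the consecutive (k x 1) then (1 x k) convolution pair."""
    p = {
        "w_kx1": ops.he_conv(rng, channels, channels, k, 1),
        "w_1xk": ops.he_conv(rng, channels, channels, 1, k),
    }
    if bias:
        p["b_kx1"] = onp.zeros(channels)
        p["b_1xk"] = onp.zeros(channels)
    return p


def factorized_large_kernel(params, x):
    """Apply the k x 1 then 1 x k convolution pair with same padding."""
    y = conv2d(x, params["w_kx1"], params.get("b_kx1"))
    y = conv2d(y, params["w_1xk"], params.get("b_1xk"))
    return y


def init_backbone_block(rng, channels: int, k: int = 7):
    """Parameters for the full residual backbone block.

    The large-kernel pair feeds a batch-norm, then two 1x1 convolutions
    bracketing a Mish; biases are dropped where a following batch-norm
    would absorb them.
    """
    return {
        "fk": init_factorized_large_kernel(rng, channels, k=k, bias=False),
        "bn_gamma": onp.ones(channels),
        "bn_beta": onp.zeros(channels),
        "w_pw1": ops.he_conv(rng, channels, channels, 1, 1),
        "b_pw1": onp.zeros(channels),
        "w_pw2": ops.he_conv(rng, channels, channels, 1, 1),
        "b_pw2": onp.zeros(channels),
    }


def backbone_forward(params, x, state, key, train=False):
    """Residual backbone block; output has the same shape as the input.

    y' = f_1x7(f_7x1(x)); y = pw2(mish(pw1(BN(y')))) + x
    """
    y = factorized_large_kernel(params["fk"], x)
    y = ops.batch_norm(y, params["bn_gamma"], params["bn_beta"], state, key, train)
    y = conv2d(y, params["w_pw1"], params["b_pw1"])
    y = mish(y)
    y = conv2d(y, params["w_pw2"], params["b_pw2"])
    return y + x
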
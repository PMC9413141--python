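"""Segmentation losses: the class-imbalance (LCA) loss plus BCE and Dice.

Probability maps carry the class axis at position -3 (``(..., 2, H, W)``),
matching the network head; ground truth is one-hot over the same axis.

The LCA loss rescales the per-pixel cross-entropy argument from the
true-class probability p to ``g(p) = p(1-p)^2 + p^2/2``: the focal-style
factor ``(1-p)^2`` damps the contribution of already-confident pixels and
the ``p^2/2`` term keeps the argument strictly increasing in p (the
derivative ``3p^2 - 3p + 1`` is positive on [0, 1]).  Note ``g(1) = 1/2``,
so the loss floor is ``log 2`` rather than zero — the curve is offset but
its minimiser is unchanged.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as onp
from autograd.tracer import getval

CLAMP_EPS = 1e-7     # lower clamp on any log argument
DICE_SMOOTH = 1.0    # smoothing added to soft-dice numerator and denominator


class ConfigurationError(ValueError):
    pass


def _check_pair(p, r):
    pv, rv = getval(p), getval(r)
    if pv.shape != rv.shape:
        raise ValueError(f"shape mismatch: prediction {pv.shape} vs truth {rv.shape}")
    if pv.ndim < 3:
        raise ValueError("expected (..., classes, H, W) maps")
    csum = onp.sum(pv, axis=-3)
    if not onp.allclose(csum, 1.0, atol=1e-5):
        raise ValueError("class probabilities must sum to 1 at every pixel")
    if not onp.all((rv == 0) | (rv == 1)) or not onp.allclose(
        onp.sum(rv, axis=-3), 1.0
    ):
        raise ValueError("truth must be one-hot over the class axis")


def _pixel_count(p):
    # number of (batch x spatial) positions; Eq-style normalisation is by
    # H*W, extended by the batch size for batched input
    shape = getval(p).shape
    n = shape[-1] * shape[-2]
    for d in shape[:-3]:
        n *= d
    return n


def lca_loss(p, r, eps: float = CLAMP_EPS, variant: str = "half_square",
             validate: bool = True):
    """Class-imbalance loss: -mean_x,y sum_c R * log(p(1-p)^2 + p^2/2).

    ``variant='half_square'`` reads the trailing 2 as a denominator on the
    fine-tuning term only (the default); ``variant='all_half'`` divides the
    whole inner expression by 2.  The log argument is clamped below at
    ``eps`` so the loss and its gradient stay finite at p = 0.
    """
    if validate:
        _check_pair(p, r)
    if variant == "half_square":
        inner = p * (1 - p) ** 2 + p ** 2 / 2.0
    elif variant == "all_half":
        inner = (p * (1 - p) ** 2 + p ** 2) / 2.0
    else:
        raise ConfigurationError(f"unknown lca variant {variant!r}")
    inner = anp.maximum(inner, eps)
    return -anp.sum(r * anp.log(inner)) / _pixel_count(p)


def bce_loss(p, r, eps: float = CLAMP_EPS, validate: bool = True):
    """Pixel-mean cross-entropy: -mean_x,y sum_c R * log p."""
    if validate:
        _check_pair(p, r)
    return -anp.sum(r * anp.log(anp.maximum(p, eps))) / _pixel_count(p)


def dice_loss(p, r, smooth: float = DICE_SMOOTH, validate: bool = True):
    """1 - soft-dice of the foreground probability channel vs the truth.

    Soft dice = (2 * sum(pf * rf) + smooth) / (sum(pf) + sum(rf) + smooth),
    pooled over the whole batch.
    """
    if validate:
        _check_pair(p, r)
    pf = p[..., 1, :, :]
    rf = r[..., 1, :, :]
    num = 2.0 * anp.sum(pf * rf) + smooth
    den = anp.sum(pf) + anp.sum(rf) + smooth
    return 1.0 - num / den


_LOSSES = {"lca": lca_loss, "bce": bce_loss, "dice": dice_loss}


def loss_factory(name: str):
    """Return the loss callable registered under ``name``."""
    try:
        return _LOSSES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown loss {name!r}; choose from {sorted(_LOSSES)}"
        ) from None


def one_hot(mask, num_classes: int = 2):
    """Binary (..., H, W) mask to one-hot (..., classes, H, W) truth."""
    m = onp.asarray(mask)
    if not onp.all((m == 0) | (m == 1)):
        raise ValueError("mask entries must be exactly 0 or 1")
    out = onp.zeros(m.shape[:-2] + (num_classes,) + m.shape[-2:])
    out[..., 0, :, :] = 1 - m
    out[..., 1, :, :] = m
    return out
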
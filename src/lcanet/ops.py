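"""Differentiable array primitives used by every network block.

All functions here take and return plain ``numpy`` arrays but are written
against :mod:`autograd.numpy`, so reverse-mode gradients flow through them
when they are called inside an ``autograd.grad`` trace.  Layout convention
throughout the package is NCHW: ``(batch, channels, height, width)``.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as onp
from autograd.extend import defvjp, primitive
from autograd.tracer import getval


# ---------------------------------------------------------------------------
# activations


def softplus(x):
    """Numerically stable ln(1 + e^x)."""
    return anp.logaddexp(0.0, x)


def mish(x):
    """Mish activation: x * tanh(softplus(x)).

    Smooth, non-monotone below zero with a global minimum near -0.30884,
    and asymptotically the identity for large positive inputs.
    """
    return x * anp.tanh(softplus(x))


def softmax(x, axis=-1):
    """Softmax along ``axis`` with max-subtraction for stability.

    The subtracted max is treated as a constant (it shifts logits uniformly,
    so the softmax gradient is unaffected), which keeps the backward pass
    free of argmax bookkeeping.
    """
    m = onp.max(getval(x), axis=axis, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# padding


def zero_pad2d(x, pad_h, pad_w):
    """Zero-pad the two trailing spatial axes of an NCHW array."""
    if pad_h == (0, 0) and pad_w == (0, 0):
        return x
    return anp.pad(x, ((0, 0), (0, 0), pad_h, pad_w), mode="constant")


def _symmetric_indices(n, before, after):
    """Index vector realising symmetric (edge-including reflect) padding."""
    return onp.pad(onp.arange(n), (before, after), mode="symmetric")


def reflect_pad2d(x, pad_h, pad_w):
    """Reflect-style (symmetric) padding of the spatial axes.

    Implemented as an index gather so it stays differentiable; symmetric
    indexing allows pad widths up to the axis length itself.
    """
    if pad_h == (0, 0) and pad_w == (0, 0):
        return x
    ridx = _symmetric_indices(x.shape[2], *pad_h)
    cidx = _symmetric_indices(x.shape[3], *pad_w)
    return x[:, :, ridx][:, :, :, cidx]


# ---------------------------------------------------------------------------
# convolution


def _conv_raw(x, w, dilation):
    """Plain-numpy 'same'-padded convolution as a sum of shifted slices.

    Each kernel tap is contracted with a BLAS ``tensordot``; for the small
    kernels used here (1, 3 or 7 taps per axis) this is simple and fast.
    """
    dh, dw = dilation
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = (kh - 1) * dh // 2, (kw - 1) * dw // 2
    H, W = x.shape[2], x.shape[3]
    xp = onp.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = None
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, :, u * dh : u * dh + H, v * dw : v * dw + W]
            term = onp.tensordot(xs, w[:, :, u, v], axes=([1], [1]))
            out = term if out is None else out + term
    return onp.ascontiguousarray(onp.moveaxis(out, 3, 1))


@primitive
def _conv2d_p(x, w, dilation=(1, 1)):
    return _conv_raw(x, w, dilation)


def _conv2d_vjp_x(ans, x, w, dilation=(1, 1)):
    # gradient wrt input = same-padded convolution of the cotangent with the
    # spatially flipped, channel-transposed kernel (stride-1 transposed conv)
    wt = onp.ascontiguousarray(onp.transpose(w, (1, 0, 2, 3))[:, :, ::-1, ::-1])
    return lambda g: _conv_raw(g, wt, dilation)


def _conv2d_vjp_w(ans, x, w, dilation=(1, 1)):
    dh, dw = dilation
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = (kh - 1) * dh // 2, (kw - 1) * dw // 2
    H, W = x.shape[2], x.shape[3]
    xp = onp.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

    def vjp(g):
        dwout = onp.empty_like(w)
        for u in range(kh):
            for v in range(kw):
                xs = xp[:, :, u * dh : u * dh + H, v * dw : v * dw + W]
                dwout[:, :, u, v] = onp.tensordot(
                    g, xs, axes=([0, 2, 3], [0, 2, 3])
                )
        return dwout

    return vjp


defvjp(_conv2d_p, _conv2d_vjp_x, _conv2d_vjp_w)


def conv2d(x, w, b=None, dilation=1):
    """2-D convolution (cross-correlation) with 'same' zero padding.

    Parameters
    ----------
    x : (N, C, H, W) input.
    w : (O, C, kh, kw) kernel (odd sizes).
    b : optional (O,) bias.
    dilation : int or (dh, dw) dilation of the kernel taps.
    """
    if isinstance(dilation, int):
        dilation = (dilation, dilation)
    out = _conv2d_p(x, w, dilation=dilation)
    if b is not None:
        out = out + anp.reshape(b, (1, -1, 1, 1))
    return out


def linear(x, w, b=None):
    """Affine map on the trailing axis: x @ w + b."""
    y = anp.dot(x, w)
    if b is not None:
        y = y + b
    return y


# ---------------------------------------------------------------------------
# normalisation


def layer_norm(x, gamma, beta, eps=1e-5):
    """Layer normalisation over the channel axis at each pixel (NCHW)."""
    mu = anp.mean(x, axis=1, keepdims=True)
    var = anp.var(x, axis=1, keepdims=True)
    xh = (x - mu) / anp.sqrt(var + eps)
    return anp.reshape(gamma, (1, -1, 1, 1)) * xh + anp.reshape(beta, (1, -1, 1, 1))


def batch_norm(x, gamma, beta, state, key, train, momentum=0.1, eps=1e-5):
    """Batch normalisation over (N, H, W) per channel with running statistics.

    ``state`` is a plain dict of running moments mutated in place (outside
    the autograd trace); ``key`` namespaces this layer's entries.
    """
    if train:
        mu = anp.mean(x, axis=(0, 2, 3))
        var = anp.var(x, axis=(0, 2, 3))
        n = x.shape[0] * x.shape[2] * x.shape[3]
        unbiased = getval(var) * (n / max(n - 1, 1))
        state[key + ".mean"] = (1 - momentum) * state.get(
            key + ".mean", onp.zeros(x.shape[1])
        ) + momentum * getval(mu)
        state[key + ".var"] = (1 - momentum) * state.get(
            key + ".var", onp.ones(x.shape[1])
        ) + momentum * unbiased
    else:
        mu = state.get(key + ".mean", onp.zeros(x.shape[1]))
        var = state.get(key + ".var", onp.ones(x.shape[1]))
    xh = (x - anp.reshape(mu, (1, -1, 1, 1))) / anp.sqrt(
        anp.reshape(var, (1, -1, 1, 1)) + eps
    )
    return anp.reshape(gamma, (1, -1, 1, 1)) * xh + anp.reshape(beta, (1, -1, 1, 1))


# ---------------------------------------------------------------------------
# resampling

def _pool_reshape(x):
    N, C, H, W = x.shape
    return x.reshape(N, C, H // 2, 2, W // 2, 2)


@primitive
def _max_pool_2x2_p(x):
    return _pool_reshape(x).max(axis=(3, 5))


def _max_pool_vjp(ans, x):
    up = onp.repeat(onp.repeat(ans, 2, axis=2), 2, axis=3)
    mask = x == up
    counts = _pool_reshape(mask).sum(axis=(3, 5))  # ties share the gradient
    scale = mask / onp.repeat(onp.repeat(counts, 2, axis=2), 2, axis=3)
    return lambda g: onp.repeat(onp.repeat(g, 2, axis=2), 2, axis=3) * scale


defvjp(_max_pool_2x2_p, _max_pool_vjp)


def max_pool_2x2(x):
    """2x2 max pooling with stride 2; spatial dims must be even."""
    H, W = x.shape[2], x.shape[3]
    if H % 2 or W % 2:
        raise ValueError(f"max_pool_2x2 needs even spatial dims, got {H}x{W}")
    return _max_pool_2x2_p(x)


@primitive
def upsample_nearest_2x(x):
    """Duplicate every pixel into a 2x2 block."""
    return onp.repeat(onp.repeat(x, 2, axis=2), 2, axis=3)


defvjp(
    upsample_nearest_2x,
    lambda ans, x: lambda g: _pool_reshape(g).sum(axis=(3, 5)),
)


def upsample_nearest(x, size):
    """Nearest-neighbour resize of an NCHW array to spatial ``size``."""
    H, W = x.shape[2], x.shape[3]
    th, tw = size
    if (th, tw) == (H, W):
        return x
    if (th, tw) == (2 * H, 2 * W):
        return upsample_nearest_2x(x)
    ridx = onp.floor(onp.arange(th) * (H / th)).astype(int)
    cidx = onp.floor(onp.arange(tw) * (W / tw)).astype(int)
    return x[:, :, ridx][:, :, :, cidx]


def global_avg_pool(x):
    """Mean over the spatial axes: (N, C, H, W) -> (N, C)."""
    return anp.mean(x, axis=(2, 3))


# ---------------------------------------------------------------------------
# parameter initialisation


def he_conv(rng, c_out, c_in, kh, kw):
    """He-normal initialised convolution kernel."""
    fan_in = c_in * kh * kw
    return rng.normal(0.0, onp.sqrt(2.0 / fan_in), size=(c_out, c_in, kh, kw))


def he_linear(rng, d_in, d_out):
    return rng.normal(0.0, onp.sqrt(2.0 / d_in), size=(d_in, d_out))


def count_parameters(params) -> int:
    """Total number of scalars in a (nested) parameter container."""
    if isinstance(params, dict):
        return sum(count_parameters(v) for v in params.values())
    if isinstance(params, (list, tuple)):
        return sum(count_parameters(v) for v in params)
    return int(onp.size(params))
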
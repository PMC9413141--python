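"""Windowed cross-attention with relative position bias.

The block projects a feature map to query/key/value embeddings with layer
normalisation and 1x1 convolutions, partitions the query map into
non-overlapping 8x8 windows and the key/value maps into overlapping 10x10
windows moved with stride ``s``, and attends every query pixel to key-value
pixels with a learned bias that depends only on the 2-D offset between the
two pixels.  Two scopes are provided:

* ``global`` — every flattened query pixel (M1 of them) attends to every
  pixel of every key-value window (M2), exactly the dense formulation; the
  logit matrix is M1 x M2, so this is reserved for small maps.
* ``paired`` — each 8x8 query window attends only to its aligned 10x10
  key-value window (the query window plus a 1-pixel halo), giving linear
  cost in the number of windows and the same bias semantics.

In the encoder the block self-attends; in the decoder the query comes from
the encoder skip connection while key/value come from the deeper decoder
feature (upsampled to the skip resolution when needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as onp

from . import ops
from .ops import conv2d, layer_norm, reflect_pad2d, softmax

QUERY_WINDOW = 8
KV_WINDOW = 10


@dataclass
class AttentionConfig:
    """Hyperparameters of the context-attention block."""

    s: int = 1                 # key-value window stride
    query_window: int = QUERY_WINDOW
    kv_window: int = KV_WINDOW
    radius: int = 15           # relative-offset clipping radius of the bias table
    mode: str = "auto"         # 'auto' | 'global' | 'paired'
    global_max_hw: int = 16    # 'auto': use global scope for padded maps up to this size
    embed_ratio: float = 0.5   # C1' = max(1, round(C1 * embed_ratio))


@dataclass
class PatchSet:
    """Partitioned windows of one feature map, channels-last and flattened.

    ``patches`` has shape (batch, N, window^2, C'); ``rows``/``cols`` give the
    absolute padded-map coordinates of every flattened element, in the same
    window-major, row-major-within-window order as ``patches``.
    """

    patches: object
    window: int
    stride: int
    grid: tuple
    padded_hw: tuple
    orig_hw: tuple
    rows: onp.ndarray = field(repr=False, default=None)
    cols: onp.ndarray = field(repr=False, default=None)

    @property
    def patch_count(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def flattened_length(self) -> int:
        return self.patch_count * self.window * self.window

    @property
    def embed_dim(self) -> int:
        return self.patches.shape[-1]

    def flat(self):
        """(batch, M, C') view of the patches."""
        b = self.patches.shape[0]
        return anp.reshape(self.patches, (b, self.flattened_length, self.embed_dim))


def padded_size(n: int, window: int = QUERY_WINDOW, minimum: int = None) -> int:
    """Smallest size >= n that is a multiple of ``window`` and >= ``minimum``."""
    return max(minimum or window, -(-n // window) * window)


def kv_padded_size(n: int, window: int = KV_WINDOW) -> int:
    """Key-value maps are padded only up to the window size (>= 10)."""
    return max(n, window)


def _pad_to(x, size):
    H, W = x.shape[2], x.shape[3]
    return reflect_pad2d(x, (0, size - H), (0, size - W))


def attention_scope_size(h: int, w: int) -> int:
    """Effective padded size governing the cost of global attention."""
    return max(padded_size(max(h, w)), kv_padded_size(max(h, w)))


def split_query(q, window: int = QUERY_WINDOW) -> PatchSet:
    """Tile a feature map into non-overlapping query windows.

    The map is padded (reflect-style) so both spatial dims are multiples of
    the window; N1 = (Hp/8) * (Wp/8) and M1 = N1 * 64.
    """
    B, C, H, W = q.shape
    P = padded_size(max(H, W), window)
    qp = _pad_to(q, P)
    nh = nw = P // window
    t = anp.reshape(qp, (B, C, nh, window, nw, window))
    t = anp.transpose(t, (0, 2, 4, 3, 5, 1))  # (B, nh, nw, win, win, C)
    patches = anp.reshape(t, (B, nh * nw, window * window, C))
    ii, jj, wr, wc = onp.meshgrid(
        onp.arange(nh), onp.arange(nw), onp.arange(window), onp.arange(window),
        indexing="ij",
    )
    order = (0, 1, 2, 3)  # already window-major, row-major within window
    rows = (ii * window + wr).transpose(order).ravel()
    cols = (jj * window + wc).transpose(order).ravel()
    return PatchSet(patches, window, window, (nh, nw), (P, P), (H, W), rows, cols)


def split_kv(x, s: int = 1, window: int = KV_WINDOW) -> PatchSet:
    """Extract overlapping key-value windows at stride ``s``.

    On the padded P x P map, N2 = (floor((P - 10)/s) + 1)^2 and
    M2 = N2 * 100.
    """
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    B, C, H, W = x.shape
    P = kv_padded_size(max(H, W), window)
    xp = _pad_to(x, P)
    starts = onp.arange(0, P - window + 1, s)
    n = len(starts)
    rr = starts[:, None] + onp.arange(window)  # (n, window)
    xw = xp[:, :, rr, :]                  # (B, C, n, window, P)
    xw = xw[:, :, :, :, rr]               # (B, C, n, window, n, window)
    xw = anp.transpose(xw, (0, 2, 4, 3, 5, 1))  # (B, n, n, win, win, C)
    patches = anp.reshape(xw, (B, n * n, window * window, C))
    ii, jj, wr, wc = onp.meshgrid(
        onp.arange(n), onp.arange(n), onp.arange(window), onp.arange(window),
        indexing="ij",
    )
    rows = (starts[ii] + wr).ravel()
    cols = (starts[jj] + wc).ravel()
    return PatchSet(patches, window, s, (n, n), (P, P), (H, W), rows, cols)


def materialize_bias(table, q_rows, q_cols, k_rows, k_cols, radius: int):
    """Gather the (M1, M2) relative-position bias from the learned table.

    ``table`` has shape (2*radius+1, 2*radius+1); offsets are clipped to
    [-radius, radius] so arbitrarily distant pairs share the edge entries.
    """
    dr = onp.clip(q_rows[:, None] - k_rows[None, :], -radius, radius) + radius
    dc = onp.clip(q_cols[:, None] - k_cols[None, :], -radius, radius) + radius
    return table[dr, dc]


def scaled_attention(qp: PatchSet, kp: PatchSet, vp: PatchSet, bias_table,
                     radius: int = 15, return_weights: bool = False):
    """Dense softmax attention of all query pixels over all key-value pixels.

    logits = q k^T / sqrt(C') + phi, row-softmax over the M2 axis, output is
    the convex combination of value rows: shape (batch, M1, C').
    """
    q, k, v = qp.flat(), kp.flat(), vp.flat()
    c = q.shape[-1]
    phi = materialize_bias(bias_table, qp.rows, qp.cols, kp.rows, kp.cols, radius)
    logits = (anp.matmul(q, anp.transpose(k, (0, 2, 1))) + phi) / anp.sqrt(c * 1.0)
    if not onp.all(onp.isfinite(ops.getval(logits))):
        raise FloatingPointError(
            "non-finite attention logits "
            f"(M1={qp.flattened_length}, M2={kp.flattened_length}, C'={c})"
        )
    weights = softmax(logits, axis=-1)
    out = anp.matmul(weights, v)
    if return_weights:
        return out, weights
    return out


def fold_query(flat, qp: PatchSet):
    """Inverse of :func:`split_query`: (B, M1, C') back to (B, C', H, W)."""
    B = flat.shape[0]
    C = flat.shape[-1]
    nh, nw = qp.grid
    w = qp.window
    t = anp.reshape(flat, (B, nh, nw, w, w, C))
    t = anp.transpose(t, (0, 5, 1, 3, 2, 4))
    full = anp.reshape(t, (B, C, nh * w, nw * w))
    H, W = qp.orig_hw
    return full[:, :, :H, :W]


def _window_coverage(P: int, s: int, window: int) -> onp.ndarray:
    """How many stride-``s`` windows of ``window`` pixels cover each position."""
    starts = onp.arange(0, P - window + 1, s)
    cov = onp.zeros(P, dtype=int)
    for st in starts:
        cov[st:st + window] += 1
    return cov


def _global_attention_dense(q, k, v, bias_table, radius, s,
                            kv_window=KV_WINDOW):
    """Global attention over all M1 x M2 window-pixel pairs, computed densely.

    For a fixed query pixel, a key pixel contributes the *same* logit from
    every overlapping window that contains it (same content, same relative
    offset), so the softmax over the M2 duplicated entries equals a softmax
    over unique pixels with log-multiplicity added to the logits.  This is
    an exact algebraic rewrite of :func:`scaled_attention` on the same
    padded map, at O(P^4) instead of O(P^2 * M2) cost.
    """
    B, C, H, W = q.shape
    Pq = padded_size(max(H, W))
    Pk = kv_padded_size(max(H, W), kv_window)
    qf = anp.reshape(anp.transpose(_pad_to(q, Pq), (0, 2, 3, 1)), (B, Pq * Pq, C))
    kf = anp.reshape(anp.transpose(_pad_to(k, Pk), (0, 2, 3, 1)), (B, Pk * Pk, C))
    vf = anp.reshape(anp.transpose(_pad_to(v, Pk), (0, 2, 3, 1)), (B, Pk * Pk, C))
    q_rows, q_cols = onp.repeat(onp.arange(Pq), Pq), onp.tile(onp.arange(Pq), Pq)
    k_rows, k_cols = onp.repeat(onp.arange(Pk), Pk), onp.tile(onp.arange(Pk), Pk)
    phi = materialize_bias(bias_table, q_rows, q_cols, k_rows, k_cols, radius)
    cov = _window_coverage(Pk, s, kv_window)
    mult = (cov[k_rows] * cov[k_cols]).astype(float)
    log_mult = onp.where(mult > 0, onp.log(onp.maximum(mult, 1.0)), -1e30)
    logits = (anp.matmul(qf, anp.transpose(kf, (0, 2, 1))) + phi) / anp.sqrt(
        C * 1.0
    ) + log_mult[None, None, :]
    out = anp.matmul(softmax(logits, axis=-1), vf)  # (B, Pq*Pq, C)
    full = anp.transpose(anp.reshape(out, (B, Pq, Pq, C)), (0, 3, 1, 2))
    return full[:, :, :H, :W]


def _paired_attention(q, k, v, bias_table, radius, window=QUERY_WINDOW):
    """Each query window attends to its aligned halo-padded 10x10 kv window."""
    B, C, H, W = q.shape
    P = padded_size(max(H, W), window, minimum=window)
    qpad = _pad_to(q, P)
    nh = P // window
    t = anp.reshape(qpad, (B, C, nh, window, nh, window))
    qw = anp.reshape(anp.transpose(t, (0, 2, 4, 3, 5, 1)),
                     (B, nh * nh, window * window, C))

    def kv_windows(x):
        xp = reflect_pad2d(_pad_to(x, P), (1, 1), (1, 1))
        starts = onp.arange(nh) * window  # window origin in padded-by-1 coords
        rr = starts[:, None] + onp.arange(window + 2)
        xw = xp[:, :, rr, :][:, :, :, :, rr]
        xw = anp.transpose(xw, (0, 2, 4, 3, 5, 1))
        return anp.reshape(xw, (B, nh * nh, (window + 2) ** 2, C))

    kw, vw = kv_windows(k), kv_windows(v)
    wr, wc = onp.meshgrid(onp.arange(window), onp.arange(window), indexing="ij")
    kr, kc = onp.meshgrid(onp.arange(window + 2) - 1, onp.arange(window + 2) - 1,
                          indexing="ij")
    phi = materialize_bias(bias_table, wr.ravel(), wc.ravel(),
                           kr.ravel(), kc.ravel(), radius)
    c = qw.shape[-1]
    logits = (anp.matmul(qw, anp.transpose(kw, (0, 1, 3, 2))) + phi) / anp.sqrt(c * 1.0)
    out = anp.matmul(softmax(logits, axis=-1), vw)  # (B, N, 64, C)
    t = anp.reshape(out, (B, nh, nh, window, window, c))
    t = anp.transpose(t, (0, 5, 1, 3, 2, 4))
    full = anp.reshape(t, (B, c, P, P))
    return full[:, :, :H, :W]


# ---------------------------------------------------------------------------
# the full block


def init_context_attention(rng, channels: int, cfg: AttentionConfig = None,
                           zero_output: bool = False):
    """Parameters of one context-attention block for ``channels`` input maps.

    ``zero_output`` zero-initialises the two output projections, making the
    freshly built block an exact identity (pure residual) — useful as a test
    hook and a gentle start for training.
    """
    cfg = cfg or AttentionConfig()
    ce = max(1, int(round(channels * cfg.embed_ratio)))
    side = 2 * cfg.radius + 1

    def proj(c_out, c_in):
        return {"w": ops.he_conv(rng, c_out, c_in, 1, 1), "b": onp.zeros(c_out)}

    p = {
        "ln_q": {"gamma": onp.ones(channels), "beta": onp.zeros(channels)},
        "ln_kv": {"gamma": onp.ones(channels), "beta": onp.zeros(channels)},
        "q": proj(ce, channels),
        "k": proj(ce, channels),
        "v": proj(ce, channels),
        "bias_table": onp.zeros((side, side)),
        "out": proj(channels, ce),
        "ln2": {"gamma": onp.ones(channels), "beta": onp.zeros(channels)},
        "g2": proj(channels, channels),
    }
    if zero_output:
        p["out"]["w"] = onp.zeros_like(p["out"]["w"])
        p["g2"]["w"] = onp.zeros_like(p["g2"]["w"])
    else:
        # small output projections keep the residual path dominant at init
        p["out"]["w"] = p["out"]["w"] * 0.1
        p["g2"]["w"] = p["g2"]["w"] * 0.1
    return p


def qkv_project(params, q_src, kv_src=None, normalize: bool = True):
    """Layer-norm then 1x1-convolve into query/key/value embeddings.

    Spatial dims are unchanged; all three outputs have the embedding channel
    count C1'.  ``normalize=False`` is a test hook that skips the layer
    normalisation.
    """
    if kv_src is None:
        kv_src = q_src
    hq, hk = q_src, kv_src
    if normalize:
        hq = layer_norm(q_src, params["ln_q"]["gamma"], params["ln_q"]["beta"])
        hk = layer_norm(kv_src, params["ln_kv"]["gamma"], params["ln_kv"]["beta"])
    q = conv2d(hq, params["q"]["w"], params["q"]["b"])
    k = conv2d(hk, params["k"]["w"], params["k"]["b"])
    v = conv2d(hk, params["v"]["w"], params["v"]["b"])
    return q, k, v


def context_attention_forward(params, x, skip=None, cfg: AttentionConfig = None):
    """Forward pass of the context-attention block.

    Encoder variant (``skip is None``): self-attention on ``x``.  Decoder
    variant: ``skip`` supplies the query source, ``x`` the key-value source
    (upsampled to the skip resolution first).  Output shape equals the query
    source shape; two residual stages follow the attention:

        y1' = g_out(attention) + q_src
        y1  = g2(LN(y1')) + y1'
    """
    cfg = cfg or AttentionConfig()
    q_src = x if skip is None else skip
    kv_src = x
    if kv_src.shape[2:] != q_src.shape[2:]:
        kv_src = ops.upsample_nearest(kv_src, (q_src.shape[2], q_src.shape[3]))
    if kv_src.shape[1] != q_src.shape[1]:
        raise ValueError(
            f"query/key-value channel mismatch: {q_src.shape[1]} vs {kv_src.shape[1]}"
        )
    H, W = q_src.shape[2], q_src.shape[3]
    if max(H, W) < 2:
        raise ValueError(f"spatial dims too small for attention: {H}x{W}")

    q, k, v = qkv_project(params, q_src, kv_src)

    mode = cfg.mode
    if mode == "auto":
        mode = ("global" if attention_scope_size(H, W) <= cfg.global_max_hw
                else "paired")
    if mode == "global":
        y = _global_attention_dense(q, k, v, params["bias_table"], cfg.radius,
                                    cfg.s, cfg.kv_window)
    elif mode == "paired":
        y = _paired_attention(q, k, v, params["bias_table"], cfg.radius,
                              cfg.query_window)
    else:
        raise ValueError(f"unknown attention mode {cfg.mode!r}")

    y1p = conv2d(y, params["out"]["w"], params["out"]["b"]) + q_src
    h = layer_norm(y1p, params["ln2"]["gamma"], params["ln2"]["beta"])
    y1 = conv2d(h, params["g2"]["w"], params["g2"]["b"]) + y1p
    return y1
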
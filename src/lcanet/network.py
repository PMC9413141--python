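"""LCA-Net: U-shaped encoder-decoder assembled from the three blocks.

The encoder starts with two plain 3x3 convolutions at full resolution (the
input port cares about fine texture), then each deeper stage is a 2x2 max
pool, a 3x3 channel-lift convolution, a backbone block and — at levels whose
spatial size allows it — a context-attention block.  The bottleneck ends
with the nodule-adaptive convolution block.  The decoder mirrors the
encoder: nearest-neighbour upsampling with a 1x1 projection, a decoder
context-attention block whose query comes from the same-level encoder skip,
and a backbone block; the head is a 1x1 convolution with a per-pixel
two-class softmax.

All three bespoke blocks can be switched off independently (the ablation
axes); with everything off the model degrades to a plain 3x3 U-shaped
baseline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as onp

from . import attention, blocks, nac, ops
from .attention import AttentionConfig
from .ops import conv2d, mish


class ConfigurationError(ValueError):
    """Raised for inconsistent network or training configuration."""


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``attn_max_hw`` caps the level size at which context-attention blocks are
    inserted; within that, maps whose padded size is at most
    ``global_attn_hw`` use the dense global attention scope and larger ones
    the paired-window scope (when ``attn_mode='auto'``).
    """

    depth: int = 5
    widths: tuple = (16, 32, 64, 128, 256)
    in_channels: int = 1
    num_classes: int = 2
    input_size: int = 256
    attn_max_hw: int = 32
    global_attn_hw: int = 16
    attn_mode: str = "auto"
    s: int = 1
    embed_ratio: float = 0.5
    bias_radius: int = 15
    use_backbone: bool = True
    use_attention: bool = True
    use_nac: bool = True

    def __post_init__(self):
        self.widths = tuple(self.widths)
        if len(self.widths) != self.depth:
            raise ConfigurationError(
                f"widths length {len(self.widths)} != depth {self.depth}"
            )
        if any(w <= 0 for w in self.widths) or self.depth < 2:
            raise ConfigurationError("widths must be positive and depth >= 2")
        if self.input_size % (2 ** (self.depth - 1)):
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^{self.depth - 1}"
            )

    def attention_cfg(self) -> AttentionConfig:
        return AttentionConfig(
            s=self.s, mode=self.attn_mode, global_max_hw=self.global_attn_hw,
            embed_ratio=self.embed_ratio, radius=self.bias_radius,
        )

    def attention_levels(self):
        """Encoder levels (1..depth-1) that receive a context-attention block."""
        if not self.use_attention:
            return []
        return [
            i for i in range(1, self.depth)
            if self.input_size // (2 ** i) <= self.attn_max_hw
        ]


def _double_conv(rng, c_in, c_out):
    return {
        "w1": ops.he_conv(rng, c_out, c_in, 3, 3), "b1": onp.zeros(c_out),
        "w2": ops.he_conv(rng, c_out, c_out, 3, 3), "b2": onp.zeros(c_out),
    }


class LCANet:
    """The segmentation model: configuration, parameters and BN state.

    Parameters live in a nested dict of numpy arrays so ``autograd`` can
    differentiate straight through :meth:`forward`; batch-norm running
    moments live in the separate ``state`` dict.
    """

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        self.attn_cfg = cfg.attention_cfg()
        self.state = {}
        self.params = self._init_params(onp.random.default_rng(seed))

    # -- construction -----------------------------------------------------

    def _init_params(self, rng):
        cfg = self.cfg
        w = cfg.widths
        attn_levels = set(cfg.attention_levels())
        p = {"enc0": _double_conv(rng, cfg.in_channels, w[0])}
        for i in range(1, cfg.depth):
            stage = {"lift": {
                "w": ops.he_conv(rng, w[i], w[i - 1], 3, 3), "b": onp.zeros(w[i])
            }}
            if cfg.use_backbone:
                stage["backbone"] = blocks.init_backbone_block(rng, w[i])
            else:
                stage["conv2"] = {
                    "w": ops.he_conv(rng, w[i], w[i], 3, 3), "b": onp.zeros(w[i])
                }
            if i in attn_levels:
                stage["attn"] = attention.init_context_attention(
                    rng, w[i], self.attn_cfg
                )
            p[f"enc{i}"] = stage
        if cfg.use_nac:
            p["nac"] = nac.init_nac_block(rng, w[-1])
        for i in range(cfg.depth - 2, -1, -1):
            stage = {"up": {
                "w": ops.he_conv(rng, w[i], w[i + 1], 1, 1), "b": onp.zeros(w[i])
            }}
            if i in attn_levels:
                stage["attn"] = attention.init_context_attention(
                    rng, w[i], self.attn_cfg
                )
            if i == 0:
                stage["conv"] = _double_conv(rng, w[0], w[0])
            elif cfg.use_backbone:
                stage["backbone"] = blocks.init_backbone_block(rng, w[i])
            else:
                stage["conv2"] = {
                    "w": ops.he_conv(rng, w[i], w[i], 3, 3), "b": onp.zeros(w[i])
                }
            p[f"dec{i}"] = stage
        p["head"] = {
            "w": ops.he_conv(rng, cfg.num_classes, w[0], 1, 1),
            "b": onp.zeros(cfg.num_classes),
        }
        return p

    # -- forward ----------------------------------------------------------

    def forward(self, params, x, train: bool = False):
        """Compute per-pixel class probabilities, shape (N, 2, H, W)."""
        cfg = self.cfg
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ConfigurationError(f"expected NCHW input, got shape {x.shape}")
        if x.shape[2] % (2 ** (cfg.depth - 1)) or x.shape[3] % (2 ** (cfg.depth - 1)):
            raise ConfigurationError(
                f"spatial dims {x.shape[2:]} must be divisible by "
                f"2^{cfg.depth - 1}"
            )
        st = self.state
        h = mish(conv2d(x, params["enc0"]["w1"], params["enc0"]["b1"]))
        h = mish(conv2d(h, params["enc0"]["w2"], params["enc0"]["b2"]))
        skips = [h]
        for i in range(1, cfg.depth):
            stage = params[f"enc{i}"]
            h = ops.max_pool_2x2(h)
            h = mish(conv2d(h, stage["lift"]["w"], stage["lift"]["b"]))
            if "backbone" in stage:
                h = blocks.backbone_forward(stage["backbone"], h, st,
                                            f"enc{i}.bb", train)
            else:
                h = mish(conv2d(h, stage["conv2"]["w"], stage["conv2"]["b"]))
            if "attn" in stage:
                h = attention.context_attention_forward(
                    stage["attn"], h, cfg=self.attn_cfg
                )
            skips.append(h)
        if "nac" in params:
            h = nac.nac_forward(params["nac"], h, st, "nac", train)
        for i in range(cfg.depth - 2, -1, -1):
            stage = params[f"dec{i}"]
            h = ops.upsample_nearest_2x(h)
            h = mish(conv2d(h, stage["up"]["w"], stage["up"]["b"]))
            if "attn" in stage:
                a = attention.context_attention_forward(
                    stage["attn"], h, skip=skips[i], cfg=self.attn_cfg
                )
                h = a + h
            else:
                h = h + skips[i]
            if i == 0:
                h = mish(conv2d(h, stage["conv"]["w1"], stage["conv"]["b1"]))
                h = mish(conv2d(h, stage["conv"]["w2"], stage["conv"]["b2"]))
            elif "backbone" in stage:
                h = blocks.backbone_forward(stage["backbone"], h, st,
                                            f"dec{i}.bb", train)
            else:
                h = mish(conv2d(h, stage["conv2"]["w"], stage["conv2"]["b"]))
        logits = conv2d(h, params["head"]["w"], params["head"]["b"])
        return ops.softmax(logits, axis=1)

    # -- inference --------------------------------------------------------

    def predict_proba(self, images):
        """Eval-mode probabilities for (H,W), (N,H,W) or (N,1,H,W) input."""
        x = onp.asarray(images, dtype=float)
        squeeze = False
        if x.ndim == 2:
            x, squeeze = x[None, None], True
        elif x.ndim == 3:
            x = x[:, None]
        probs = self.forward(self.params, x, train=False)
        return probs[0] if squeeze else probs

    def predict_mask(self, image):
        """Binary nodule mask by per-pixel argmax (foreground = class 1)."""
        probs = self.predict_proba(image)
        if probs.ndim == 3:
            if probs.shape[0] != self.cfg.num_classes:
                raise ConfigurationError("unexpected class channel count")
            return onp.argmax(probs, axis=0).astype(onp.uint8)
        return onp.argmax(probs, axis=1).astype(onp.uint8)

    def count_parameters(self) -> int:
        return ops.count_parameters(self.params)

    # -- serialisation ----------------------------------------------------

    def save(self, path):
        leaves = dict(_flatten_tree(self.params))
        payload = {f"p::{k}": v for k, v in leaves.items()}
        payload.update({f"s::{k}": v for k, v in self.state.items()})
        payload["config_json"] = onp.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=onp.uint8
        )
        onp.savez(path, **payload)

    @classmethod
    def load(cls, path):
        with onp.load(path) as z:
            cfg_dict = json.loads(bytes(z["config_json"]).decode())
            model = cls(NetConfig(**cfg_dict), seed=0)
            for key in z.files:
                if key.startswith("p::"):
                    _assign_leaf(model.params, key[3:], z[key])
                elif key.startswith("s::"):
                    model.state[key[3:]] = z[key]
        return model


def build_lca_net(cfg: NetConfig, seed: int = 0) -> LCANet:
    """Build an LCA-Net with freshly initialised parameters."""
    return LCANet(cfg, seed=seed)

# ---------------------------------------------------------------------------
# nested parameter-tree helpers


def _flatten_tree(tree, prefix=""):
    if isinstance(tree, dict):
        for k, v in tree.items():
            yield from _flatten_tree(v, f"{prefix}{k}/")
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from _flatten_tree(v, f"{prefix}{i}/")
    else:
        yield prefix[:-1], onp.asarray(tree)


def _assign_leaf(tree, path, value):
    keys = path.split("/")
    node = tree
    for k in keys[:-1]:
        node = node[int(k)] if isinstance(node, (list, tuple)) else node[k]
    last = keys[-1]
    if isinstance(node, (list, tuple)):
        node[int(last)] = value
    else:
        node[last] = value
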
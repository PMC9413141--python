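"""Training, evaluation and ablation driver.

The protocol: random rotation/flip augmentation applied with probability
10/11, a choice of LCA/BCE/Dice loss, SGD/Adam/AdaBound optimizers, cosine
annealing of the learning rate over the full run, fixed epoch count with the
best-validation-Dice checkpoint kept.  A "desk preset" scales the same
pipeline to a single CPU: a depth-4 net on 64x64 phantoms.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten
from scipy import ndimage

from . import metrics as metrics_mod
from .losses import loss_factory, one_hot
from .network import ConfigurationError, LCANet, NetConfig
from .optim import cosine_annealing, optimizer_factory
from .phantom import PhantomSpec, generate_dataset

__version__ = "0.1.0"


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the full-scale recipe)."""

    loss: str = "lca"
    loss_variant: str = "half_square"
    optimizer: str = "adabound"
    lr: float = 1e-3
    final_lr: float = 0.1        # AdaBound terminal (SGD-like) rate
    batch_size: int = 16
    epochs: int = 200
    scheduler: str = "cosine"    # 'cosine' | 'constant'
    augment_prob: float = 10 / 11
    rotation_range_deg: float = 10.0
    hflip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.augment_prob <= 1 and 0 <= self.hflip_prob <= 1):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ConfigurationError("lr, batch_size and epochs must be positive")
        if self.scheduler not in ("cosine", "constant"):
            raise ConfigurationError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class TrainResult:
    model: LCANet
    history: list = field(repr=False)
    best_epoch: int = -1
    best_val_dice: float = float("nan")


def augment(sample, cfg: TrainConfig, rng):
    """Jointly augment an (image, mask) pair.

    With probability ``augment_prob``: rotate by theta ~ U(-range, range)
    degrees (bilinear for the image, nearest for the mask, zero fill), then
    horizontally flip with probability ``hflip_prob``.  The mask stays
    binary and both arrays receive identical geometry.
    """
    image, mask = sample
    if rng.uniform() >= cfg.augment_prob:
        return image, mask
    theta = rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg)
    img = ndimage.rotate(image, theta, reshape=False, order=1,
                         mode="constant", cval=0.0)
    msk = ndimage.rotate(mask, theta, reshape=False, order=0,
                         mode="constant", cval=0)
    if rng.uniform() < cfg.hflip_prob:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    return np.ascontiguousarray(np.clip(img, 0.0, 1.0)), \
        np.ascontiguousarray(msk.astype(mask.dtype))


def _as_pairs(samples):
    """Accept PhantomSample objects or raw (image, mask) tuples."""
    out = []
    for s in samples:
        if hasattr(s, "image"):
            out.append((np.asarray(s.image, dtype=float), np.asarray(s.mask)))
        else:
            out.append((np.asarray(s[0], dtype=float), np.asarray(s[1])))
    return out


def _batched_masks(model, images, chunk=16):
    preds = []
    for i in range(0, len(images), chunk):
        x = np.stack(images[i:i + chunk])[:, None]
        probs = model.forward(model.params, x, train=False)
        preds.extend(np.argmax(probs, axis=1).astype(np.uint8))
    return preds


def _validation_pass(model, pairs, loss_fn, variant_kw):
    images = [p[0] for p in pairs]
    masks = [p[1] for p in pairs]
    losses = []
    for i in range(0, len(pairs), 16):
        x = np.stack(images[i:i + 16])[:, None]
        r = one_hot(np.stack(masks[i:i + 16]).astype(np.uint8))
        probs = model.forward(model.params, x, train=False)
        losses.append(float(loss_fn(probs, r, validate=False, **variant_kw))
                      * len(x))
    preds = _batched_masks(model, images)
    dices = []
    for pm, tm in zip(preds, masks):
        rep = metrics_mod.compute_metrics(
            metrics_mod.confusion_counts(pm, tm.astype(np.uint8))
        )
        if not math.isnan(rep.dice):
            dices.append(rep.dice)
    val_dice = float(np.mean(dices)) if dices else float("nan")
    return sum(losses) / len(pairs), val_dice


def train(train_samples, val_samples, net_cfg: NetConfig,
          cfg: TrainConfig = None, out_dir=None) -> TrainResult:
    """Train an LCA-Net from scratch and keep the best-validation epoch.

    All randomness (initialisation, shuffling, augmentation) is seeded from
    ``cfg.seed``.  Per-epoch train/validation loss and validation Dice are
    logged; with ``out_dir`` set, a manifest, a CSV log and the best
    checkpoint are written there.
    """
    cfg = cfg or TrainConfig()
    train_pairs = _as_pairs(train_samples)
    val_pairs = _as_pairs(val_samples)
    if not train_pairs or not val_pairs:
        raise ConfigurationError("need non-empty train and validation sets")

    rng = np.random.default_rng(cfg.seed)
    model = LCANet(net_cfg, seed=cfg.seed)
    loss_fn = loss_factory(cfg.loss)
    variant_kw = {"variant": cfg.loss_variant} if cfg.loss == "lca" else {}
    opt_kwargs = {}
    if cfg.optimizer == "adabound":
        opt_kwargs = {"final_lr": cfg.final_lr, "base_lr": cfg.lr}
    opt = optimizer_factory(cfg.optimizer, **opt_kwargs)

    flat, unflatten = flatten(model.params)
    history = []
    best_flat, best_state = None, None
    best_dice, best_epoch = -np.inf, -1

    for epoch in range(cfg.epochs):
        lr = (cosine_annealing(cfg.lr, epoch, cfg.epochs)
              if cfg.scheduler == "cosine" else cfg.lr)
        order = rng.permutation(len(train_pairs))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, msks = [], []
            for j in idx:
                im, mk = augment(train_pairs[j], cfg, rng)
                imgs.append(im)
                msks.append(mk)
            x = np.stack(imgs)[:, None]
            r = one_hot(np.stack(msks).astype(np.uint8))

            def objective(params):
                probs = model.forward(params, x, train=True)
                return loss_fn(probs, r, validate=False, **variant_kw)

            value, grads = value_and_grad(objective)(model.params)
            value = float(value)
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss {value} at epoch {epoch}, step "
                    f"{start // cfg.batch_size} (loss={cfg.loss}, lr={lr:g})"
                )
            gflat, _ = flatten(grads)
            flat = opt.step(flat, gflat, lr)
            model.params = unflatten(flat)
            epoch_loss += value * len(idx)
            seen += len(idx)

        val_loss, val_dice = _validation_pass(model, val_pairs, loss_fn,
                                              variant_kw)
        history.append({
            "epoch": epoch, "lr": lr, "train_loss": epoch_loss / seen,
            "val_loss": val_loss, "val_dice": val_dice,
        })
        if not math.isnan(val_dice) and val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_flat = flat.copy()
            best_state = {k: np.copy(v) for k, v in model.state.items()}

    if best_flat is not None:
        model.params = unflatten(best_flat)
        model.state = best_state

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "checkpoint.npz")
        with open(out / "history.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(history[0]))
            w.writeheader()
            w.writerows(history)
        manifest = {
            "package_version": __version__,
            "train_config": asdict(cfg),
            "net_config": asdict(net_cfg),
            "n_train": len(train_pairs), "n_val": len(val_pairs),
            "best_epoch": best_epoch, "best_val_dice": best_dice,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return TrainResult(model=model, history=history,
                       best_epoch=best_epoch, best_val_dice=best_dice)


def evaluate(model, samples, mode: str = "per-image-mean",
             out_csv=None, out_json=None):
    """Per-image metric table plus an aggregate summary for a dataset.

    ``model`` is an :class:`LCANet` (or any object exposing ``params`` and
    ``forward(params, x, train)``) or a checkpoint path.  Returns
    ``(rows, summary)`` where rows are (image_id, MetricsReport) pairs.
    """
    if isinstance(model, (str, Path)):
        model = LCANet.load(model)
    pairs = _as_pairs(samples)
    if not pairs:
        raise ValueError("empty dataset")
    shapes = {p[0].shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError(f"images have mismatched sizes: {sorted(shapes)}")
    preds = _batched_masks(model, [p[0] for p in pairs])
    rows = []
    mask_pairs = []
    for i, ((_, tm), pm) in enumerate(zip(pairs, preds)):
        tm = tm.astype(np.uint8)
        rows.append((i, metrics_mod.compute_metrics(
            metrics_mod.confusion_counts(pm, tm))))
        mask_pairs.append((pm, tm))
    summary = metrics_mod.aggregate_metrics(mask_pairs, mode=mode)
    if out_csv:
        metrics_mod.write_report_csv(out_csv, rows)
    if out_json:
        metrics_mod.write_summary_json(out_json, summary,
                                       extra={"n_images": len(rows),
                                              "aggregation": mode})
    return rows, summary


def run_ablation(grid: dict, train_samples, val_samples, test_samples,
                 out_csv=None):
    """Train/evaluate every named configuration on identical data and seed.

    ``grid`` maps a run name to a dict with keys ``net`` (NetConfig) and
    optionally ``train`` (TrainConfig).  Returns one row per run with the
    module flags, loss/optimizer and the seven test metrics; a run that
    raises is kept as a row flagged ``failed``.
    """
    if len(grid) < 2:
        raise ConfigurationError("an ablation grid needs at least 2 configs")
    rows = []
    for name, entry in grid.items():
        net_cfg = entry["net"]
        tcfg = entry.get("train") or TrainConfig()
        row = {
            "name": name,
            "backbone": net_cfg.use_backbone,
            "attention": net_cfg.use_attention,
            "nac": net_cfg.use_nac,
            "loss": tcfg.loss, "optimizer": tcfg.optimizer,
            "failed": False,
        }
        try:
            result = train(train_samples, val_samples, net_cfg, tcfg)
            _, summary = evaluate(result.model, test_samples)
            row.update(summary.as_dict())
            row["best_val_dice"] = result.best_val_dice
        except Exception as exc:  # partial table with failure flags
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    if out_csv:
        names = sorted({k for r in rows for k in r})
        with open(out_csv, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=names)
            w.writeheader()
            w.writerows(rows)
    return rows


# ---------------------------------------------------------------------------
# desk preset: the single-CPU study conditions


def desk_net_config(**overrides) -> NetConfig:
    """Depth-4, widths 8/16/32/64 network for 64x64 phantoms."""
    kw = dict(depth=4, widths=(8, 16, 32, 64), input_size=64)
    kw.update(overrides)
    return NetConfig(**kw)


def desk_train_config(**overrides) -> TrainConfig:
    """30-epoch, batch-8 training preset."""
    kw = dict(epochs=30, batch_size=8)
    kw.update(overrides)
    return TrainConfig(**kw)


def desk_dataset(n_train: int = 200, n_val: int = 50, n_test: int = 50,
                 seed: int = 0, image_size: int = 64):
    """Balanced phantom datasets at the desk scale (disjoint seeds)."""
    spec = PhantomSpec(image_size=image_size)
    train_set = generate_dataset(n_train, spec, seed=seed)
    val_set = generate_dataset(n_val, spec, seed=seed + 1_000_003)
    test_set = generate_dataset(n_test, spec, seed=seed + 2_000_003)
    return train_set, val_set, test_set
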
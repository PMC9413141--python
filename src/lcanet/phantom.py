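"""Ultrasound-like phantom generator with exact ground-truth masks.

Each phantom is a speckled grayscale image containing one low-contrast
nodule with a blurred ("weak") edge.  The scene is a smooth low-frequency
background field darkened by the blurred nodule footprint, multiplied by
gamma-distributed speckle — the standard multiplicative model of fully
developed ultrasound speckle.  The ground-truth mask is the geometric
(unblurred) nodule support, mirroring how expert annotations trace the
lesion boundary rather than the image gradient.

Nodule size classes are disjoint area fractions of the image: small
(0.5-2%), medium (2-8%), large (8-25%).  Placement is central, at the image
border (the nodule contour touches the boundary), or uniformly random.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

SIZE_CLASSES = {
    "small": (0.005, 0.02),
    "medium": (0.02, 0.08),
    "large": (0.08, 0.25),
}
PLACEMENTS = ("center", "edge", "random")


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom draw.

    ``size_class`` / ``placement`` may be None, in which case dataset
    generation rotates through all options round-robin.

    ``edge_blur_sigma`` and ``speckle_shape`` default to None, meaning
    "resolution-scaled": the reference values (2 px blur, gamma shape 4)
    are defined at the 256x256 working size and rescaled for other sizes
    the way physical downsampling rescales them — blur width shrinks with
    the image (sigma * size/256) while speckle averages out (shape *
    (256/size)^2), so a 64x64 phantom looks like a 256x256 phantom resized,
    not like a harder task.  Pass explicit numbers to pin either one.
    """

    REF_SIZE = 256
    REF_BLUR_SIGMA = 2.0
    REF_SPECKLE_SHAPE = 4.0

    image_size: int = 256
    size_class: str | None = None
    placement: str | None = None
    contrast_drop: float = 0.15      # mean intensity gap, nodule vs background
    edge_blur_sigma: float | None = None   # px; width of the weak edge
    speckle_shape: float | None = None     # gamma shape; larger = milder
    background_mean: float = 0.55
    background_texture: float = 0.06  # amplitude of the low-frequency field
    boundary_wobble: float = 0.08    # radial perturbation of the ellipse
    seed: int = 0

    def __post_init__(self):
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.placement is not None and self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if not 0.0 < self.contrast_drop <= 0.5:
            raise ValueError("contrast_drop must be in (0, 0.5]")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")

    @property
    def resolved_blur_sigma(self) -> float:
        if self.edge_blur_sigma is not None:
            return self.edge_blur_sigma
        return self.REF_BLUR_SIGMA * self.image_size / self.REF_SIZE

    @property
    def resolved_speckle_shape(self) -> float:
        if self.speckle_shape is not None:
            return self.speckle_shape
        return self.REF_SPECKLE_SHAPE * (self.REF_SIZE / self.image_size) ** 2


@dataclass
class PhantomSample:
    """One generated phantom: image in [0,1], binary mask, provenance."""

    image: np.ndarray
    mask: np.ndarray
    spec: PhantomSpec = field(repr=False)
    size_class: str = ""
    placement: str = ""

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


def _nodule_mask(n, rng, size_class, placement, wobble):
    """Binary support of one wobbled ellipse at the requested size/place.

    Axes are rescaled iteratively so the final (possibly border-clipped)
    area fraction lands inside the class band.
    """
    lo, hi = SIZE_CLASSES[size_class]
    target = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
    theta = rng.uniform(0, np.pi)
    ratio = rng.uniform(0.5, 1.0)  # minor/major axis ratio
    area_px = target * n * n
    a = np.sqrt(area_px / (np.pi * ratio))
    b = a * ratio

    # axis-aligned half-extents of the rotated ellipse
    ey = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    ex = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    side = rng.integers(4)
    if placement == "center":
        cy, cx = (n / 2 + rng.uniform(-0.05, 0.05, 2) * n)
    elif placement == "edge":
        off = rng.uniform(0.2, 0.5)  # fraction of the extent hanging outside
        cy, cx = rng.uniform(0.3, 0.7, 2) * n
        if side == 0:
            cy = ey * (1 - off)
        elif side == 1:
            cy = n - 1 - ey * (1 - off)
        elif side == 2:
            cx = ex * (1 - off)
        else:
            cx = n - 1 - ex * (1 - off)
    else:
        my = min(ey, n / 2 - 1)
        mx = min(ex, n / 2 - 1)
        cy = rng.uniform(my, n - 1 - my)
        cx = rng.uniform(mx, n - 1 - mx)

    # low-frequency radial wobble, fixed per nodule
    n_harm = 3
    amp = rng.uniform(0, wobble, n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)

    yy, xx = np.mgrid[0:n, 0:n]

    def support(a_, b_):
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(theta) + dx * np.sin(theta)
        rx = -dy * np.sin(theta) + dx * np.cos(theta)
        ang = np.arctan2(ry, rx)
        r = np.sqrt((ry / a_) ** 2 + (rx / b_) ** 2)
        bound = 1.0 + sum(
            amp[j] * np.cos((j + 2) * ang + phase[j]) for j in range(n_harm)
        )
        return r <= bound

    mask = support(a, b)
    for _ in range(12):
        frac = mask.mean()
        if lo <= frac <= hi:
            break
        if frac <= 0:
            a, b = a * 1.5, b * 1.5
        else:
            scale = np.sqrt(target / frac)
            a, b = a * scale, b * scale
        mask = support(a, b)
    frac = mask.mean()
    if not lo <= frac <= hi:
        raise ValueError(
            f"could not realise a {size_class} nodule (area fraction {frac:.4f})"
        )
    if placement == "edge":
        mask = _ensure_border_touch(mask, side)
    return mask


def _ensure_border_touch(mask, side):
    """Shift an edge-placed nodule so its contour touches the image border.

    The wobble/rescale loop can leave a small gap; shifting by exactly the
    gap moves the component's bounding box onto the border without clipping
    any pixel, so the class-band area is preserved.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    n = mask.shape[0]
    axis, gap = (0, rows[0]) if side == 0 else \
                (0, -(n - 1 - rows[-1])) if side == 1 else \
                (1, cols[0]) if side == 2 else (1, -(n - 1 - cols[-1]))
    if gap:
        mask = np.roll(mask, -gap, axis=axis)
    return mask


def generate_phantom(spec: PhantomSpec, rng=None) -> PhantomSample:
    """Draw one phantom image/mask pair from ``spec``.

    Deterministic given (spec, rng seed); the mask is a single connected
    component whose area fraction lies inside the spec's size-class band.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.image_size
    size_class = spec.size_class or rng.choice(list(SIZE_CLASSES))
    placement = spec.placement or rng.choice(PLACEMENTS)

    mask = _nodule_mask(n, rng, size_class, placement, spec.boundary_wobble)
    labels, ncomp = ndimage.label(mask)
    if ncomp != 1:  # keep the largest component (wobble can rarely pinch off)
        sizes = ndimage.sum(mask, labels, range(1, ncomp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))

    base = spec.background_mean + _smooth_field(rng, n, spec.background_texture)
    scene = base - spec.contrast_drop * ndimage.gaussian_filter(
        mask.astype(float), spec.resolved_blur_sigma
    )
    shape = spec.resolved_speckle_shape
    speckle = rng.gamma(shape, 1.0 / shape, size=(n, n))
    image = np.clip(scene * speckle, 0.0, 1.0)
    return PhantomSample(
        image=image.astype(np.float64),
        mask=mask.astype(np.uint8),
        spec=spec,
        size_class=size_class,
        placement=placement,
    )


def _smooth_field(rng, n, amplitude):
    field_ = ndimage.gaussian_filter(rng.normal(0, 1, (n, n)), sigma=n / 8)
    peak = np.max(np.abs(field_)) or 1.0
    return amplitude * field_ / peak


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Per-sample generator seeds derived deterministically from one seed."""
    return np.random.SeedSequence(seed).generate_state(n)


def generate_dataset(n: int, spec: PhantomSpec, seed: int = 0):
    """n i.i.d. phantoms; size classes and placements rotate round-robin
    (unless the spec pins them) so every regime is represented."""
    if n <= 0:
        raise ValueError("n must be positive")
    seeds = derive_seeds(seed, n)
    classes = list(SIZE_CLASSES)
    samples = []
    for i in range(n):
        s = replace(
            spec,
            size_class=spec.size_class or classes[i % len(classes)],
            placement=spec.placement or PLACEMENTS[(i // len(classes)) % len(PLACEMENTS)],
            seed=int(seeds[i]),
        )
        samples.append(generate_phantom(s))
    return samples


def split_811(n_total: int, seed: int = 0):
    """Shuffled 8:1:1 index split: floor(0.8 n) train, remainder halved
    between validation and test with any odd leftover going to validation."""
    if n_total < 10:
        raise ValueError(f"need at least 10 samples to split 8:1:1, got {n_total}")
    perm = np.random.default_rng(seed).permutation(n_total)
    n_train = int(0.8 * n_total)
    rem = n_total - n_train
    n_val = rem - rem // 2  # odd remainder's extra item to validation
    train = perm[:n_train]
    val = perm[n_train:n_train + n_val]
    test = perm[n_train + n_val:]
    return train, val, test


# ---------------------------------------------------------------------------
# disk IO


def save_dataset(samples, out_dir):
    """Write 8-bit grayscale PNG pairs plus a manifest CSV."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "size_class", "placement", "area_fraction", "seed"])
        for i, s in enumerate(samples):
            Image.fromarray((s.image * 255).astype(np.uint8)).save(
                out / f"img_{i:05d}.png"
            )
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(
                out / f"mask_{i:05d}.png"
            )
            w.writerow([i, s.size_class, s.placement,
                        f"{s.area_fraction:.6f}", s.spec.seed])


def load_dataset(in_dir):
    """Read image/mask PNG pairs written by :func:`save_dataset`."""
    from PIL import Image

    d = Path(in_dir)
    samples = []
    spec = PhantomSpec()
    for img_path in sorted(d.glob("img_*.png")):
        idx = img_path.stem.split("_")[1]
        mask_path = d / f"mask_{idx}.png"
        image = np.asarray(Image.open(img_path), dtype=float) / 255.0
        mask = (np.asarray(Image.open(mask_path)) > 127).astype(np.uint8)
        samples.append(PhantomSample(image=image, mask=mask, spec=spec))
    if not samples:
        raise ValueError(f"no phantom PNGs found under {d}")
    return samples
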
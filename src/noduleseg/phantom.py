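"""Synthetic nodule-phantom patches with pixel-exact ground-truth masks.

Real training data for lung-nodule segmentation are 64×64 CT patches
cropped around a detected nodule, with radiologist-drawn binary masks.
This module generates stand-ins that emulate their geometry: one bright,
quasi-circular nodule of variable size on a darker textured background,
optionally touching a pleural-wall band (juxta-pleural) or a vessel-like
ridge (juxta-vascular).  Wall and vessel are rendered in the image only —
the ground truth is always "nodule versus everything else", so the mask
is exactly the set of pixels whose centre lies within ``radius_px`` of
the nodule centre (closed Euclidean disk).

Nodule diameters of 3–30 mm are mapped linearly onto 4–56 px within the
64×64 patch.  All randomness flows from explicit integer seeds, so every
patch and every dataset is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

PATCH = 64

NODULE_TYPES = ("well_circumscribed", "juxta_pleural", "juxta_vascular")

__all__ = [
    "PATCH", "NODULE_TYPES", "NoduleSpec", "PatchSample", "BoundingBox",
    "DatasetSplit", "synth_patch", "synth_dataset", "flip_augment",
    "split_dataset", "crop_and_resize", "mm_to_px", "save_dataset",
    "load_dataset",
]


def mm_to_px(diameter_mm: float) -> float:
    """Linear map of the 3–30 mm nodule diameter range onto 4–56 px."""
    return 4.0 + (diameter_mm - 3.0) * (56.0 - 4.0) / (30.0 - 3.0)


@dataclass(frozen=True)
class NoduleSpec:
    """Geometry and rendering parameters of one synthetic nodule patch.

    contrast is the nodule-over-background intensity gap in (0, 1];
    noise_sd the standard deviation of the additive Gaussian pixel noise.
    """

    nodule_type: str = "well_circumscribed"
    center: tuple = (32.0, 32.0)
    radius_px: float = 8.0
    contrast: float = 0.45
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.nodule_type not in NODULE_TYPES:
            raise ValueError(f"unknown nodule type {self.nodule_type!r}")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        r, c = self.center
        if not (0 <= r < PATCH and 0 <= c < PATCH):
            raise ValueError("center must lie inside the 64x64 grid")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PatchSample:
    """A 64×64 intensity patch in [0,1] with its {0,1} ground-truth mask."""

    image: np.ndarray
    mask: np.ndarray
    id: str
    spec: NoduleSpec | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass(frozen=True)
class BoundingBox:
    """0-based half-open pixel box [row_min, row_max) × [col_min, col_max)."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("box must have positive extent")

    @property
    def shape(self):
        return (self.row_max - self.row_min, self.col_max - self.col_min)


@dataclass
class DatasetSplit:
    train: list
    test: list
    train_fraction: float
    seed: int


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _disk_mask(center, radius):
    rr, cc = np.mgrid[0:PATCH, 0:PATCH]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 <= radius ** 2).astype(np.uint8)


def synth_patch(spec: NoduleSpec) -> PatchSample:
    """Render one phantom patch; bit-identical for identical specs."""
    mask = _disk_mask(spec.center, spec.radius_px)
    if mask.sum() == 0:
        raise ValueError("degenerate nodule: disk contains no pixel centre")

    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:PATCH, 0:PATCH].astype(np.float64)

    # textured parenchyma background: smoothed white noise around a low base
    base = 0.20 + 0.08 * rng.random()
    texture = gaussian_filter(rng.normal(0.0, 1.0, (PATCH, PATCH)), sigma=2.5)
    image = base + 0.05 * texture

    structure = np.zeros((PATCH, PATCH))
    if spec.nodule_type == "juxta_pleural":
        # bright band along the nearest edge, thick enough to touch the disk
        r0, c0 = spec.center
        dists = {"top": r0, "bottom": PATCH - 1 - r0,
                 "left": c0, "right": PATCH - 1 - c0}
        side = min(dists, key=dists.get)
        gap = max(0.0, dists[side] - spec.radius_px)
        thick = gap + 2.0 + 3.0 * rng.random()
        coord = {"top": rr, "bottom": PATCH - 1 - rr,
                 "left": cc, "right": PATCH - 1 - cc}[side]
        structure[coord <= thick] = spec.contrast * (0.85 + 0.1 * rng.random())
    elif spec.nodule_type == "juxta_vascular":
        # vessel-like ridge through the nodule centre at a random angle
        theta = rng.uniform(0, math.pi)
        d = np.abs((rr - spec.center[0]) * math.sin(theta)
                   - (cc - spec.center[1]) * math.cos(theta))
        width = 1.0 + 1.5 * rng.random()
        structure = spec.contrast * 0.9 * np.exp(-0.5 * (d / width) ** 2)

    nodule = spec.contrast * gaussian_filter(mask.astype(np.float64), 0.6)
    image = image + np.maximum(nodule, structure)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, (PATCH, PATCH))
    image = np.clip(image, 0.0, 1.0)

    sid = f"{spec.nodule_type[:2]}-{spec.seed}"
    return PatchSample(image.astype(np.float32), mask, id=sid, spec=spec)


def synth_dataset(n: int, type_mix=(1 / 3, 1 / 3, 1 / 3),
                  seed: int = 0) -> list:
    """Generate n phantom patches with the given nodule-type proportions.

    Per-sample seeds are derived from the master seed via
    ``numpy.random.SeedSequence``, so the dataset is reproducible and any
    sample can be regenerated in isolation from its spec.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = np.asarray(type_mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("type_mix must be three non-negative values "
                         "summing to 1")
    master = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    samples = []
    for i in range(n):
        rng = np.random.default_rng(int(child_seeds[i]))
        ntype = NODULE_TYPES[int(master.choice(3, p=mix))]
        diameter_mm = rng.uniform(3.0, 30.0)
        radius = mm_to_px(diameter_mm) / 2.0
        margin = min(radius + 1.0, (PATCH - 2) / 2.0)
        lo, hi = margin, PATCH - 1 - margin
        center = (rng.uniform(lo, hi), rng.uniform(lo, hi))
        spec = NoduleSpec(
            nodule_type=ntype,
            center=center,
            radius_px=radius,
            contrast=rng.uniform(0.3, 0.6),
            noise_sd=0.03,
            seed=int(child_seeds[i]),
        )
        sample = synth_patch(spec)
        sample.id = f"{i:05d}-{sample.id}"
        samples.append(sample)
    return samples


# --------------------------------------------------------------------------
# augmentation, split, preprocessing
# --------------------------------------------------------------------------

FLIP_SUFFIX = "-flip"


def flip_augment(samples: list) -> list:
    """Return the originals plus a left-right mirrored copy of each."""
    out = list(samples)
    for s in samples:
        out.append(PatchSample(np.fliplr(s.image).copy(),
                               np.fliplr(s.mask).copy(),
                               id=s.id + FLIP_SUFFIX, spec=s.spec))
    return out


def split_dataset(samples: list, train_fraction: float,
                  seed: int = 0) -> DatasetSplit:
    """Shuffle by seed, then partition into round(f·N) train / rest test."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    order = np.random.default_rng(seed).permutation(len(samples))
    n_train = round(train_fraction * len(samples))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return DatasetSplit(train, test, train_fraction, seed)


def crop_and_resize(image: np.ndarray, box: BoundingBox,
                    out_size=(64, 64)) -> np.ndarray:
    """Crop a bounding box and resample it to ``out_size`` bicubically.

    The resampler maps output pixel centres into the source box
    (half-pixel convention) and evaluates a cubic-spline interpolant of
    the *full* image, so taps just outside the box use real neighbouring
    pixels rather than invented padding.  Output values are clipped to the
    input range.  A box already at the target size is returned verbatim.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    h, w = img.shape
    if not (0 <= box.row_min and box.row_max <= h
            and 0 <= box.col_min and box.col_max <= w):
        raise ValueError("box exceeds image bounds")
    bh, bw = box.shape
    if (bh, bw) == tuple(out_size):
        return img[box.row_min:box.row_max, box.col_min:box.col_max].copy()

    oh, ow = out_size
    r = box.row_min + (np.arange(oh) + 0.5) * bh / oh - 0.5
    c = box.col_min + (np.arange(ow) + 0.5) * bw / ow - 0.5
    coords = np.stack(np.meshgrid(r, c, indexing="ij"))
    out = map_coordinates(img, coords, order=3, mode="mirror")
    return np.clip(out, img.min(), img.max())


# --------------------------------------------------------------------------
# on-disk layout: 8-bit grayscale PNGs plus a CSV index
# --------------------------------------------------------------------------

def save_dataset(samples: list, out_dir, split_labels=None):
    """Write patches/masks as 8-bit PNGs and an index CSV."""
    from PIL import Image
    import pandas as pd

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        ipath = out / "images" / f"{s.id}.png"
        mpath = out / "masks" / f"{s.id}.png"
        Image.fromarray(
            np.round(s.image * 255).astype(np.uint8)).save(ipath)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(mpath)
        rows.append({
            "id": s.id,
            "image_path": str(ipath.relative_to(out)),
            "mask_path": str(mpath.relative_to(out)),
            "nodule_type": s.spec.nodule_type if s.spec else "",
            "split": (split_labels or {}).get(s.id, ""),
        })
    pd.DataFrame(rows).to_csv(out / "index.csv", index=False)
    return out / "index.csv"


def load_dataset(index_csv) -> list:
    from PIL import Image
    import pandas as pd

    index_csv = Path(index_csv)
    root = index_csv.parent
    samples = []
    for row in pd.read_csv(index_csv, keep_default_na=False).itertuples():
        image = np.asarray(Image.open(root / row.image_path),
                           dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(root / row.mask_path)) > 127
                ).astype(np.uint8)
        samples.append(PatchSample(image, mask, id=str(row.id)))
    return samples
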
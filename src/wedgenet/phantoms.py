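"""Synthetic cross-section phantoms and the augmentation menu.

The training corpus emulates cross-sectional images of faceted or rounded
nanocrystals: random overlaps of filled disks and convex polygons with
per-shape flat intensities, clipped to the inscribed circle of the square
grid (tomography of a [0,1] slice assumes zero background outside the
reconstruction circle).  Augmentation applies pad-resize, random rotation,
flip, affine and additive noise, in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.transform import AffineTransform, rescale, rotate, warp

__all__ = [
    "Phantom", "AugmentationSpec", "DatasetManifest", "generate_phantom",
    "augment_image", "generate_suite", "build_library", "load_library",
]

#: clip shapes this many pixels inside the inscribed circle so that linear
#: interpolation during rotation/projection cannot push mass outside it
_CIRCLE_MARGIN = 2.0


@dataclass
class Phantom:
    """A 2-D grayscale ground-truth cross-section with values in [0, 1]."""

    pixels: np.ndarray
    support: str = "inscribed-circle"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("phantom must be a square 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("phantom contains non-finite values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("phantom values must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class AugmentationSpec:
    """Which augmentations apply and how strong they are.

    ``random_rotation`` is a max angle in degrees (or a ``(lo, hi)`` range for
    a deterministic forced angle when ``lo == hi``); ``random_affine`` bounds
    the shear/scale deltas; ``random_noise`` is an additive Gaussian sigma in
    intensity units.  ``flip_axes`` forces specific flips instead of the
    seeded random choice (testing hook).
    """

    pad_resize: bool = False
    random_rotation: float | tuple[float, float] = 0.0
    random_flip: bool = False
    random_affine: float = 0.0
    random_noise: float = 0.0
    flip_axes: tuple[bool, bool] | None = None

    def __post_init__(self):
        lo, hi = self.rotation_range
        if not (0 <= hi <= 180) or lo > hi:
            raise ValueError("rotation bound must lie in [0, 180]")
        if self.random_noise < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.random_affine < 0:
            raise ValueError("affine delta bound must be >= 0")

    @property
    def rotation_range(self) -> tuple[float, float]:
        r = self.random_rotation
        if isinstance(r, (tuple, list)):
            return float(r[0]), float(r[1])
        return -float(r), float(r)


def _inscribed_mask(size: int, margin: float = _CIRCLE_MARGIN) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 < (size / 2.0 - margin) ** 2


def generate_phantom(size: int, shape_budget: tuple[int, int] = (3, 8),
                     seed: int = 0) -> Phantom:
    """Seeded random composition of filled disks and convex polygons.

    Shapes get uniform intensities in [0.2, 1.0]; overlaps resolve by taking
    the maximum; everything is clipped to the inscribed circle of the grid.
    A ``(0, 0)`` budget yields an empty (all-zero) phantom.
    """
    if size < 32:
        raise ValueError("size must be >= 32 pixels")
    lo, hi = shape_budget
    if lo > hi or lo < 0 or hi > 64:
        raise ValueError("shape budget must satisfy 0 <= min <= max <= 64")
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size), dtype=np.float64)
    n_shapes = int(rng.integers(lo, hi + 1))
    c = (size - 1) / 2.0
    r_max = size / 2.0 - _CIRCLE_MARGIN
    for _ in range(n_shapes):
        intensity = rng.uniform(0.2, 1.0)
        # centers biased toward the middle so shapes stay mostly in-circle
        ang = rng.uniform(0, 2 * np.pi)
        rad = r_max * np.sqrt(rng.uniform(0, 0.7))
        cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
        r_shape = rng.uniform(0.05, 0.3) * size
        mask = np.zeros_like(img, dtype=bool)
        if rng.random() < 0.5:
            rr, cc = draw_disk((cy, cx), r_shape, shape=img.shape)
            mask[rr, cc] = True
        else:
            k = int(rng.integers(3, 8))
            pts = np.column_stack([
                cy + rng.uniform(-r_shape, r_shape, size=k + 3),
                cx + rng.uniform(-r_shape, r_shape, size=k + 3),
            ])
            try:
                hull = ConvexHull(pts)
                verts = pts[hull.vertices]
            except QhullError:  # degenerate (collinear) draw
                verts = pts
            rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=img.shape)
            mask[rr, cc] = True
        np.maximum(img, np.where(mask, intensity, 0.0), out=img)
    img[~_inscribed_mask(size)] = 0.0
    return Phantom(img)


def _pad_resize(px: np.ndarray) -> np.ndarray:
    """Shrink content by 1/sqrt(2) so any rotation keeps it on the grid."""
    size = px.shape[0]
    small = rescale(px, 1 / np.sqrt(2), order=1, anti_aliasing=False,
                    preserve_range=True)
    out = np.zeros_like(px)
    off = (size - small.shape[0]) // 2
    out[off:off + small.shape[0], off:off + small.shape[1]] = small
    return out


def augment_image(img: Phantom, spec: AugmentationSpec, seed: int = 0) -> Phantom:
    """Apply the augmentation menu in its fixed order; output keeps the grid size."""
    rng = np.random.default_rng(seed)
    px = img.pixels.copy()
    if spec.pad_resize:
        px = _pad_resize(px)
    lo, hi = spec.rotation_range
    if hi > 0 or lo < 0:
        angle = lo if lo == hi else rng.uniform(lo, hi)
        px = rotate(px, angle, order=1, mode="constant", cval=0.0,
                    preserve_range=True)
    if spec.random_flip:
        if spec.flip_axes is not None:
            fh, fv = spec.flip_axes
        else:
            fh, fv = rng.random() < 0.5, rng.random() < 0.5
        if fh:
            px = px[:, ::-1]
        if fv:
            px = px[::-1, :]
    if spec.random_affine > 0:
        d = spec.random_affine
        scale = (1 + rng.uniform(-d, d), 1 + rng.uniform(-d, d))
        shear = rng.uniform(-d, d)
        c = (px.shape[0] - 1) / 2.0
        center = AffineTransform(translation=(-c, -c))
        tf = (center + AffineTransform(scale=scale, shear=shear) + center.inverse)
        px = warp(px, tf.inverse, order=1, mode="constant", cval=0.0,
                  preserve_range=True)
    if spec.random_noise > 0:
        px = px + rng.normal(0.0, spec.random_noise, size=px.shape)
    return Phantom(np.clip(px, 0.0, 1.0))


@dataclass
class DatasetManifest:
    """Bookkeeping for a generated phantom library."""

    entries: list[dict] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    global_seed: int = 0
    size: int = 128

    def __post_init__(self):
        if self.entries and sum(self.counts.values()) != len(self.entries):
            raise ValueError("per-tag counts do not sum to the entry count")

    def to_json(self) -> str:
        return json.dumps({"entries": self.entries, "counts": self.counts,
                           "global_seed": self.global_seed, "size": self.size},
                          indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(entries=d["entries"], counts=d["counts"],
                   global_seed=d["global_seed"], size=d["size"])


DEFAULT_AUGMENT = AugmentationSpec(random_rotation=180.0, random_flip=True,
                                   random_affine=0.05)


def generate_suite(n: int, size: int = 128, seed: int = 0,
                   shape_budget: tuple[int, int] = (3, 8),
                   augment: AugmentationSpec | None = None) -> list[Phantom]:
    """In-memory phantom suite with per-entry seeds derived from one global seed."""
    seeds = np.random.SeedSequence(seed).generate_state(2 * n)
    out = []
    for i in range(n):
        ph = generate_phantom(size, shape_budget, seed=int(seeds[2 * i]))
        if augment is not None:
            ph = augment_image(ph, augment, seed=int(seeds[2 * i + 1]))
        out.append(ph)
    return out


def build_library(counts: dict[str, int], size: int = 128, seed: int = 0,
                  out_path: str | Path = ".", split_ratio: float = 10.0,
                  augment: AugmentationSpec | None = None,
                  shape_budget: tuple[int, int] = (3, 8)) -> DatasetManifest:
    """Generate a phantom library, writing float32 TIFFs plus a JSON manifest.

    ``split_ratio`` is train:validation (default 10:1, mirroring a 50,000 /
    5,000 split at full scale).  Entry seeds derive deterministically from
    the global seed, so the same call regenerates byte-identical images.
    """
    import tifffile

    if not counts:
        raise ValueError("counts must be nonempty")
    if augment is None:
        augment = DEFAULT_AUGMENT
    total = sum(counts.values())
    seeds = np.random.SeedSequence(seed).generate_state(2 * total + 1)
    rng_split = np.random.default_rng(seeds[-1])
    n_val = int(round(total / (split_ratio + 1)))
    splits = np.array(["train"] * (total - n_val) + ["val"] * n_val)
    rng_split.shuffle(splits)

    out_dir = Path(out_path)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = DatasetManifest(global_seed=seed, size=size, counts=dict(counts))
    i = 0
    for tag, n in counts.items():
        for _ in range(n):
            gseed, aseed = int(seeds[2 * i]), int(seeds[2 * i + 1])
            ph = generate_phantom(size, shape_budget, seed=gseed)
            ph = augment_image(ph, augment, seed=aseed)
            rel = f"{tag}_{i:05d}.tiff"
            tifffile.imwrite(out_dir / rel, ph.pixels.astype(np.float32))
            manifest.entries.append({"path": rel, "tag": tag, "seed": gseed,
                                     "aug_seed": aseed, "split": str(splits[i])})
            i += 1
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def load_library(path: str | Path) -> tuple[DatasetManifest, list[Phantom]]:
    """Read a written library back into memory."""
    import tifffile
    path = Path(path)
    manifest = DatasetManifest.from_json((path / "manifest.json").read_text())
    phantoms = [Phantom(np.asarray(tifffile.imread(path / e["path"]), dtype=np.float64))
                for e in manifest.entries]
    return manifest, phantoms
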
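"""Image batches, standardization, resizing and affine augmentation.

An image batch is a rank-4 float array indexed (instance, channel, height,
width).  Standardization follows the training-set distribution: the grand
mean and population standard deviation are fit on the training batch only
and then applied unchanged to validation and test data — the inference path
is exactly ``resize`` then ``standardize`` with the training statistics,
with no augmentation.

Coordinate convention for the affine transforms: 0-based pixel indices,
row = Y, column = X. Rotation and scaling are applied about the image
center; samples that fall outside the canvas are filled with the constant 0
(neutral after standardization). The transform matrices act on sampling
coordinates, so the realized image motion is the inverse map; the 2x2 core
is exposed via :func:`affine_matrix` for exact coordinate-level checks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .synthetic import LabeledImageSet, read_archive


def as_batch(values: np.ndarray) -> np.ndarray:
    """Validate and return a rank-4 finite float batch (M, C, H, W)."""
    x = np.asarray(values)
    if x.ndim != 4:
        raise ValueError(f"image batch must be rank 4 (M,C,H,W), got rank {x.ndim}")
    if any(d < 1 for d in x.shape):
        raise ValueError(f"all batch dimensions must be >= 1, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("image batch contains non-finite values")
    if not np.issubdtype(x.dtype, np.floating):
        return x.astype(np.float32)
    return x


@dataclass(frozen=True)
class StandardizationStats:
    """Grand mean / sd of the training batch (intensity units).

    ``mean`` and ``sd`` are scalars by default (the statistics pool every
    entry of the training tensor); per-channel statistics are available via
    ``fit_stats(..., per_channel=True)``, in which case both fields are
    length-C arrays. ``source`` records provenance: statistics must come
    from the training split.
    """

    mean: np.ndarray
    sd: np.ndarray
    source: str = "training"

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.mean, dtype=np.float64).tobytes())
        h.update(np.asarray(self.sd, dtype=np.float64).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class AffineSpec:
    """One affine augmentation: rotate / scale / mirror_x / axis_swap.

    ``alpha`` is the rotation angle in radians; ``sx``/``sy`` the scale
    factors (must be positive).
    """

    kind: str
    alpha: float = 0.0
    sx: float = 1.0
    sy: float = 1.0

    def __post_init__(self):
        if self.kind not in ("rotate", "scale", "mirror_x", "axis_swap"):
            raise ValueError(f"unknown affine kind {self.kind!r}")
        if self.kind == "scale" and (self.sx <= 0 or self.sy <= 0):
            raise ValueError(f"scale requires sx>0 and sy>0, got ({self.sx}, {self.sy})")


def affine_matrix(spec: AffineSpec) -> np.ndarray:
    """3x3 homogeneous matrix of the transform in (x, y, 1) coordinates."""
    if spec.kind == "rotate":
        c, s = np.cos(spec.alpha), np.sin(spec.alpha)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    if spec.kind == "scale":
        return np.diag([spec.sx, spec.sy, 1.0])
    if spec.kind == "mirror_x":
        return np.diag([-1.0, 1.0, 1.0])
    return np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def fit_stats(train: np.ndarray, per_channel: bool = False) -> StandardizationStats:
    """Grand mean and population sd over every entry of the training batch."""
    x = as_batch(train)
    if per_channel:
        mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
        sd = x.std(axis=(0, 2, 3), dtype=np.float64)
        if np.any(sd <= 0):
            raise ValueError("zero-variance channel: standardization undefined")
    else:
        mean = np.float64(x.mean(dtype=np.float64))
        sd = np.float64(x.std(dtype=np.float64))
        if sd <= 0:
            raise ValueError("zero-variance batch: standardization undefined")
    return StandardizationStats(mean=mean, sd=sd)


def _bcast(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    return v[None, :, None, None] if v.ndim == 1 else v


def standardize(batch: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """(x - mean) / sd elementwise with the training statistics."""
    x = as_batch(batch)
    sd = np.asarray(stats.sd)
    if np.any(sd <= 0):
        raise ValueError("stats.sd must be positive")
    if sd.ndim == 1 and sd.shape[0] != x.shape[1]:
        raise ValueError(
            f"per-channel stats have {sd.shape[0]} channels, batch has {x.shape[1]}"
        )
    return ((x - _bcast(stats.mean)) / _bcast(stats.sd)).astype(x.dtype)


def unstandardize(batch: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Inverse of :func:`standardize`: x * sd + mean."""
    x = as_batch(batch)
    return (x * _bcast(stats.sd) + _bcast(stats.mean)).astype(x.dtype)


def apply_affine(image: np.ndarray, spec: AffineSpec) -> np.ndarray:
    """Apply one affine transform to a single (C, H, W) image.

    Sampling coordinates are mapped by the spec's matrix about the image
    center with bilinear interpolation and constant-0 fill; the output
    canvas has the input's size.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3:
        raise ValueError(f"image must be (C, H, W), got rank {img.ndim}")
    m_xy = affine_matrix(spec)[:2, :2]
    # reorder the (x, y) matrix to act on (row=y, col=x) index vectors
    m_yx = np.array([[m_xy[1, 1], m_xy[1, 0]], [m_xy[0, 1], m_xy[0, 0]]])
    c, h, w = img.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - m_yx @ center
    out = np.empty_like(img)
    for ci in range(c):
        out[ci] = ndimage.affine_transform(
            img[ci], m_yx, offset=offset, order=1, mode="constant", cval=0.0
        )
    return out


def augment_batch(
    batch: np.ndarray,
    policy: Sequence[tuple[AffineSpec, float]],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Append randomly selected affine copies of the batch.

    ``policy`` is a list of (AffineSpec, probability) pairs. The original
    images are retained first; for each policy entry every image is copied
    with the given probability. Returns the grown batch and an index array
    mapping each output row to its source row, so the caller can grow the
    label vector in lockstep. Deterministic given seed.
    """
    x = as_batch(batch)
    m = x.shape[0]
    sources = [np.arange(m)]
    pieces = [x]
    rng = np.random.default_rng(seed)
    for spec, p in policy:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability must be in [0,1], got {p}")
        take = np.flatnonzero(rng.random(m) < p)
        if take.size:
            pieces.append(
                np.stack([apply_affine(x[i], spec) for i in take]).astype(np.float32)
            )
            sources.append(take)
    return np.concatenate(pieces, axis=0), np.concatenate(sources)


DEFAULT_POLICY: tuple[tuple[AffineSpec, float], ...] = (
    (AffineSpec("rotate", alpha=np.deg2rad(15.0)), 0.5),
    (AffineSpec("rotate", alpha=np.deg2rad(-15.0)), 0.5),
    (AffineSpec("scale", sx=0.9, sy=0.9), 0.5),
    (AffineSpec("scale", sx=1.1, sy=1.1), 0.5),
    (AffineSpec("mirror_x"), 0.5),
    (AffineSpec("axis_swap"), 0.5),
)


def resize(batch: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of every image to side x side."""
    x = as_batch(batch)
    if side < 8:
        raise ValueError(f"target side must be >= 8, got {side}")
    m, c, h, w = x.shape
    if (h, w) == (side, side):
        return x.copy()
    out = np.empty((m, c, side, side), dtype=np.float32)
    for i in range(m):
        for ci in range(c):
            out[i, ci] = _sk_resize(
                x[i, ci],
                (side, side),
                order=1,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            )
    return out


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of one (C, H, W) image (no minimum-side check)."""
    img = np.asarray(image, dtype=np.float32)
    c = img.shape[0]
    out = np.empty((c, side, side), dtype=np.float32)
    for ci in range(c):
        out[ci] = _sk_resize(
            img[ci], (side, side), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return out


def read_image_tree(root: str | Path) -> LabeledImageSet:
    """Read a class-per-subdirectory PNG/JPEG tree into a labeled set.

    Class names are the sorted subdirectory names; pixel values are scaled
    to [0,1]. All images must share one channel count; differing sizes are
    allowed (resize afterwards).
    """
    root = Path(root)
    if root.suffix == ".npz":
        return read_archive(root)
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels = [], []
    shapes = set()
    for cls, name in enumerate(classes):
        files = sorted(
            f for f in (root / name).iterdir()
            if f.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        for f in files:
            arr = np.asarray(Image.open(f), dtype=np.float32) / 255.0
            if arr.ndim == 2:
                arr = arr[None]
            else:
                arr = arr.transpose(2, 0, 1)
            shapes.add(arr.shape)
            images.append(arr)
            labels.append(cls)
    if len({s[0] for s in shapes}) > 1:
        raise ValueError(f"mixed channel counts in tree: {sorted(shapes)}")
    if len(shapes) > 1:  # ragged sizes: caller must resize; stack per-image
        side = max(max(s[1], s[2]) for s in shapes)
        images = [resize_image(im, side) for im in images]
    return LabeledImageSet(np.stack(images), np.asarray(labels), classes)
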
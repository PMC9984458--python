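"""Synthetic labeled image sets for exercising the classifier end to end.

Each class is rendered from a class-specific motif — an oriented sinusoidal
grating, a fixed constellation of Gaussian blobs, or a ring of a fixed
radius — with small per-image jitter, so that a compact CNN (or even a
nearest-class-mean classifier) can separate the classes when ``difficulty``
is low.  As ``difficulty`` approaches 1 every class is blended toward the
same neutral gray canvas, and with heavy additive noise the classes become
statistically indistinguishable.  The generator emulates the statistical
regime of small multi-class, optionally imbalanced image datasets (small
sides, few samples per class); it makes no attempt at photorealism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic labeled image set.

    Parameters
    ----------
    n_classes : number of classes.
    counts_per_class : images per class, one entry per class (this is how
        class imbalance is expressed — exact counts, not a ratio).
    image_side : square image side in pixels (>= 8).
    channels : 1 or 3.
    noise_sd : sd of additive Gaussian pixel noise, in [0,1] intensity units.
    difficulty : 0 = fully separated motifs, 1 = all classes identical.
    seed : RNG seed; the generator is bit-reproducible given the spec.
    """

    n_classes: int
    counts_per_class: tuple[int, ...]
    image_side: int = 32
    channels: int = 3
    noise_sd: float = 0.05
    difficulty: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "counts_per_class", tuple(self.counts_per_class))
        if self.n_classes < 1:
            raise ValueError(f"n_classes must be >= 1, got {self.n_classes}")
        if len(self.counts_per_class) != self.n_classes:
            raise ValueError(
                f"counts_per_class must have n_classes={self.n_classes} entries, "
                f"got {len(self.counts_per_class)}"
            )
        if any(c < 1 for c in self.counts_per_class):
            raise ValueError("counts_per_class entries must all be >= 1")
        if self.image_side < 8:
            raise ValueError(f"image_side must be >= 8, got {self.image_side}")
        if self.channels not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {self.channels}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError(f"difficulty must be in [0,1], got {self.difficulty}")


@dataclass
class LabeledImageSet:
    """Images (M, C, H, W) in [0,1] plus integer labels and class names."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError(f"images must be rank 4, got rank {self.images.ndim}")
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"images count {self.images.shape[0]} != labels length "
                f"{self.labels.shape[0]}"
            )
        if not self.class_names:
            n = int(self.labels.max()) + 1 if self.labels.size else 0
            self.class_names = [f"class_{j}" for j in range(n)]
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("labels out of [0, n_classes) range")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def __len__(self) -> int:
        return self.images.shape[0]


def _motif(cls: int, side: int, rng: np.random.Generator) -> np.ndarray:
    """Render one image of class ``cls`` in [-1, 1] with per-image jitter."""
    family, variant = cls % 3, cls // 3
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    if family == 0:  # oriented grating
        theta = (0.5 + variant) * np.pi / 4.0
        freq = 3.0 + variant
        phase = rng.normal(0.0, 0.25)
        t = (xx * np.cos(theta) + yy * np.sin(theta)) / side
        img = np.sin(2.0 * np.pi * freq * t + phase)
    elif family == 1:  # blob constellation on a fixed diagonal
        k = 2 + variant
        img = np.full((side, side), -1.0)
        sigma = side / 10.0
        for b in range(k):
            cy = side * (b + 1) / (k + 1) + rng.normal(0, side / 40.0)
            cx = side * (b + 1) / (k + 1) + rng.normal(0, side / 40.0)
            img += 2.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        img = np.clip(img, -1.0, 1.0)
    else:  # ring of class-fixed radius
        radius = side * (0.22 + 0.09 * variant)
        width = side / 12.0
        cy = (side - 1) / 2.0 + rng.normal(0, side / 40.0)
        cx = (side - 1) / 2.0 + rng.normal(0, side / 40.0)
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        img = 2.0 * np.exp(-((r - radius) ** 2) / (2 * width**2)) - 1.0
    return img


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Render the dataset described by ``spec``; deterministic given seed.

    Pixels are the motif mapped into [0,1], blended toward a neutral 0.5
    canvas by ``difficulty``, then perturbed with N(0, noise_sd) noise and
    clipped back to [0,1].
    """
    rng = np.random.default_rng(spec.seed)
    side, c = spec.image_side, spec.channels
    total = sum(spec.counts_per_class)
    images = np.empty((total, c, side, side), dtype=np.float32)
    labels = np.empty(total, dtype=np.int64)
    i = 0
    for cls, count in enumerate(spec.counts_per_class):
        for _ in range(count):
            img = 0.5 + 0.45 * _motif(cls, side, rng)
            img = (1.0 - spec.difficulty) * img + spec.difficulty * 0.5
            img = np.broadcast_to(img, (c, side, side)).copy()
            if spec.noise_sd > 0:
                img += rng.normal(0.0, spec.noise_sd, size=img.shape)
            images[i] = np.clip(img, 0.0, 1.0)
            labels[i] = cls
            i += 1
    return LabeledImageSet(
        images, labels, [f"class_{j}" for j in range(spec.n_classes)]
    )


def _split_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items to the three fractions,
    guaranteeing every nonzero fraction at least one item."""
    nonzero = [k for k, f in enumerate(fractions) if f > 0]
    counts = [int(np.floor(f * n)) for f in fractions]
    rem = [f * n - c for f, c in zip(fractions, counts)]
    for _ in range(n - sum(counts)):
        k = int(np.argmax(rem))
        counts[k] += 1
        rem[k] = -1.0
    for k in nonzero:
        while counts[k] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[k] += 1
    return counts


def split_dataset(
    ds: LabeledImageSet,
    fractions: tuple[float, float, float],
    seed: int = 0,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Stratified train/validation/test partition; exact, deterministic.

    Every class is shuffled and sliced independently so per-split class
    proportions match ``fractions`` up to rounding. Raises if a class has
    fewer samples than the number of nonzero fractions.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n_nonzero = sum(1 for f in fractions if f > 0)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in range(ds.n_classes):
        idx = np.flatnonzero(ds.labels == cls)
        if 0 < len(idx) < n_nonzero:
            raise ValueError(
                f"class {cls} has {len(idx)} samples but the split has "
                f"{n_nonzero} nonzero parts"
            )
        idx = rng.permutation(idx)
        counts = _split_counts(len(idx), fractions)
        parts[0].extend(idx[: counts[0]])
        parts[1].extend(idx[counts[0] : counts[0] + counts[1]])
        parts[2].extend(idx[counts[0] + counts[1] :])
    out = []
    for p in parts:
        sel = np.sort(np.asarray(p, dtype=np.int64))
        out.append(
            LabeledImageSet(ds.images[sel], ds.labels[sel], list(ds.class_names))
        )
    return tuple(out)


def write_png_tree(ds: LabeledImageSet, root: str | Path) -> None:
    """Write one PNG per image into class-named subdirectories."""
    root = Path(root)
    for cls, name in enumerate(ds.class_names):
        (root / name).mkdir(parents=True, exist_ok=True)
    for i in range(len(ds)):
        arr = np.clip(ds.images[i] * 255.0 + 0.5, 0, 255).astype(np.uint8)
        arr = arr.transpose(1, 2, 0)  # CHW -> HWC
        img = Image.fromarray(arr[..., 0] if arr.shape[2] == 1 else arr)
        img.save(root / ds.class_names[ds.labels[i]] / f"img_{i:06d}.png")


def write_archive(ds: LabeledImageSet, path: str | Path) -> None:
    """Pack images, labels and class names into one .npz archive."""
    np.savez_compressed(
        path,
        images=ds.images,
        labels=ds.labels,
        class_names=np.asarray(ds.class_names),
    )


def read_archive(path: str | Path) -> LabeledImageSet:
    with np.load(path, allow_pickle=False) as z:
        return LabeledImageSet(
            z["images"], z["labels"], [str(s) for s in z["class_names"]]
        )


def spec_to_json(spec: SyntheticSpec) -> str:
    return json.dumps(
        {
            "n_classes": spec.n_classes,
            "counts_per_class": list(spec.counts_per_class),
            "image_side": spec.image_side,
            "channels": spec.channels,
            "noise_sd": spec.noise_sd,
            "difficulty": spec.difficulty,
            "seed": spec.seed,
        }
    )
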
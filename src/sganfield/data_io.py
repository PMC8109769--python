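"""Image loading, [-1, 1] normalization and experiment partitions.

Datasets live on disk as one sub-directory per class (``root/crop/*.png``,
``root/weed/*.png``).  In memory a sample is a small record holding the
pixel array plus its provenance; partitions (train/val/test and the
labeled/unlabeled split at a given label rate) are seed-deterministic and
class-stratified.  Class order is fixed: crop = 0, weed = 1; the fake class
used by the adversarial classifier is index K = 2 and never appears as a
ground-truth label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

CLASS_NAMES = ("crop", "weed")
IMAGE_EXTS = (".png", ".jpg", ".jpeg")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class Sample:
    """One image with optional ground-truth label (None = unlabeled)."""

    image: np.ndarray  # HWC; uint8 raw or float32 normalized
    label: int | None
    path: str = ""


@dataclass
class DatasetSplit:
    train: list[Sample]
    val: list[Sample]
    test: list[Sample]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS


@dataclass
class LabelRateSplit:
    rate: float
    labeled: list[Sample]
    unlabeled: list[Sample]

    def __post_init__(self):
        if any(s.label is None for s in self.labeled):
            raise ValueError("labeled subset contains a sample without a label")


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def load_image_dir(root: str | Path, class_names: Sequence[str] = CLASS_NAMES) -> list[Sample]:
    """Load ``root/<class>/*`` as (image, label) pairs in lexicographic order."""
    root = Path(root)
    samples: list[Sample] = []
    for label, name in enumerate(class_names):
        class_dir = root / name
        if not class_dir.is_dir():
            raise ConfigurationError(f"missing class directory: {class_dir}")
        files = sorted(p for p in class_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS)
        if not files:
            raise ConfigurationError(f"class directory has no images: {class_dir}")
        for p in files:
            try:
                with Image.open(p) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping undecodable image %s: %s", p, exc)
                continue
            samples.append(Sample(image=arr, label=label, path=str(p)))
    return samples


def normalize(raw: np.ndarray, side: int) -> np.ndarray:
    """Resize to side x side (bilinear) and map pixel v to v/127.5 - 1."""
    if side % 16 != 0:
        raise ConfigurationError(f"image side must be divisible by 16, got {side}")
    arr = np.asarray(raw)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ConfigurationError(f"expected an HxWx3 image, got shape {arr.shape}")
    if arr.shape[0] != side or arr.shape[1] != side:
        arr = np.asarray(
            Image.fromarray(arr.astype(np.uint8)).resize((side, side), Image.BILINEAR)
        )
    return (arr.astype(np.float32) / 127.5) - 1.0


def denormalize(img: np.ndarray) -> np.ndarray:
    """Inverse of the affine map in :func:`normalize` (no resizing)."""
    return np.clip((np.asarray(img, dtype=np.float32) + 1.0) * 127.5, 0, 255).round().astype(np.uint8)


def normalize_samples(samples: Sequence[Sample], side: int) -> list[Sample]:
    return [Sample(normalize(s.image, side), s.label, s.path) for s in samples]


def _per_class_indices(samples: Sequence[Sample]) -> dict[int, np.ndarray]:
    labels = np.array([s.label for s in samples])
    return {c: np.flatnonzero(labels == c) for c in np.unique(labels)}


def _largest_remainder_counts(sizes: Sequence[float], total: int) -> list[int]:
    """Integer counts summing to ``total``, proportional to ``sizes``."""
    floors = [int(np.floor(s)) for s in sizes]
    rem = total - sum(floors)
    order = np.argsort([-(s - np.floor(s)) for s in sizes], kind="stable")
    for i in range(rem):
        floors[order[i]] += 1
    return floors


def split_train_val_test(samples: Sequence[Sample],
                         fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                         seed: int = 0) -> DatasetSplit:
    """Seeded, class-stratified 70/15/15-style partition."""
    if not samples:
        raise ConfigurationError("cannot split an empty sample collection")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ConfigurationError(f"fractions must be non-negative and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: tuple[list[Sample], list[Sample], list[Sample]] = ([], [], [])
    for _, idx in sorted(_per_class_indices(samples).items()):
        if len(idx) < 3:
            raise ConfigurationError(
                f"a class has only {len(idx)} samples; at least 3 are needed to stratify"
            )
        idx = rng.permutation(idx)
        n = len(idx)
        n_train, n_val, _ = _largest_remainder_counts([f * n for f in fractions], n)
        bounds = (n_train, n_train + n_val)
        parts[0].extend(samples[i] for i in idx[: bounds[0]])
        parts[1].extend(samples[i] for i in idx[bounds[0] : bounds[1]])
        parts[2].extend(samples[i] for i in idx[bounds[1] :])
    return DatasetSplit(train=parts[0], val=parts[1], test=parts[2], fractions=tuple(fractions))


def apply_label_rate(train_pool: Sequence[Sample], rate: float, seed: int = 0) -> LabelRateSplit:
    """Keep labels on round(rate * N) samples; strip the rest.

    Selection is class-stratified (per-class quotas by largest remainder) and
    deterministic under ``seed``.  Rounding is half-up, which reproduces the
    published label-rate tables where the rates divide the pool exactly.
    """
    if not 0.0 < rate <= 1.0:
        raise ConfigurationError(f"labeled rate must be in (0, 1], got {rate}")
    n = len(train_pool)
    if n == 0:
        raise ConfigurationError("cannot apply a label rate to an empty pool")
    target = round_half_up(rate * n)
    rng = np.random.default_rng(seed)
    per_class = sorted(_per_class_indices(train_pool).items())
    quotas = _largest_remainder_counts([rate * len(idx) for _, idx in per_class], target)
    labeled: list[Sample] = []
    unlabeled: list[Sample] = []
    for (label, idx), quota in zip(per_class, quotas):
        idx = rng.permutation(idx)
        for i in idx[:quota]:
            labeled.append(train_pool[i])
        for i in idx[quota:]:
            s = train_pool[i]
            unlabeled.append(Sample(image=s.image, label=None, path=s.path))
    return LabelRateSplit(rate=rate, labeled=labeled, unlabeled=unlabeled)


def write_manifest(path: str | Path, split: DatasetSplit, label_split: LabelRateSplit | None = None) -> None:
    """CSV manifest with columns path,label,subset,labeled."""
    labeled_paths = {s.path for s in label_split.labeled} if label_split else set()
    rows = []
    for subset, samples in (("train", split.train), ("val", split.val), ("test", split.test)):
        for s in samples:
            is_labeled = 1 if (subset != "train" or not label_split or s.path in labeled_paths) else 0
            rows.append({"path": s.path, "label": s.label, "subset": subset, "labeled": is_labeled})
    pd.DataFrame(rows, columns=["path", "label", "subset", "labeled"]).to_csv(path, index=False)


def images_array(samples: Sequence[Sample]) -> np.ndarray:
    return np.stack([s.image for s in samples])


def labels_array(samples: Sequence[Sample]) -> np.ndarray:
    return np.array([s.label for s in samples], dtype=np.int64)
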
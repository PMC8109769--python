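"""Procedural crop/weed field imagery.

The UAV imagery the classifier targets — early-growth vegetation seen from
2 m over bare soil — is emulated with two morphologically distinct plant
classes composited onto a textured brown background:

* class 0 "crop": rosettes of 4-8 broad elliptical leaves (a young
  dicotyledonous crop such as pea or strawberry);
* class 1 "weed": tufts of 5-12 thin curved blades (a grass weed such as
  goosegrass).

Both classes are green-dominated inside the plant mask, so color alone does
not separate them; shape does.  A two-feature linear probe (green-pixel
fraction, vegetation-mask compactness) serves as the separability oracle:
at the default parameters it must score well above chance, which guarantees
that downstream learning experiments are testing the learner, not noise.
Images are single-class patches because the classifier is image-level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import label as sk_label
from skimage.measure import perimeter as mask_perimeter
from skimage.morphology import remove_small_objects
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data_io import Sample
from .errors import ConfigurationError


@dataclass
class FieldParams:
    """Knobs of the synthetic field generator (lengths in pixels at the stated resolution)."""

    resolution: int = 64
    soil_red: tuple[float, float] = (95.0, 150.0)
    soil_green: tuple[float, float] = (65.0, 110.0)
    soil_blue: tuple[float, float] = (35.0, 75.0)
    n_plants: tuple[int, int] = (1, 4)
    crop_leaf_radius: tuple[float, float] = (6.0, 11.0)
    weed_blade_length: tuple[float, float] = (9.0, 17.0)
    weed_blade_width: tuple[float, float] = (0.8, 1.6)
    illumination: tuple[float, float] = (0.60, 1.30)
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.resolution < 32 or self.resolution % 16 != 0:
            raise ConfigurationError("resolution must be >= 32 and divisible by 16")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for name in ("soil_red", "soil_green", "soil_blue", "n_plants",
                     "crop_leaf_radius", "weed_blade_length", "weed_blade_width",
                     "illumination"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"range {name} must be non-degenerate, got ({lo}, {hi})")

    def scale(self) -> float:
        """Geometry scale factor relative to the reference 64 px resolution."""
        return self.resolution / 64.0


def make_soil_background(params: FieldParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Brown textured background (uint8 HWC) with R > G > B channel means."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    res = params.resolution
    base = np.array([rng.uniform(*params.soil_red),
                     rng.uniform(*params.soil_green),
                     rng.uniform(*params.soil_blue)])
    # enforce a brown hue with margins that survive pixel noise: R > G > B
    base[0] = max(base[0], base[1] + 22.0)
    base[2] = min(base[2], base[1] - 18.0)
    # low-frequency mottling shared across channels, plus per-pixel noise
    texture = gaussian_filter(rng.normal(0.0, 1.0, (res, res)), sigma=max(2.0, res / 16))
    texture = texture / (texture.std() + 1e-9) * 6.0
    img = base[None, None, :] + texture[:, :, None]
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _leaf_green(rng: np.random.Generator) -> np.ndarray:
    g = rng.uniform(110, 210)
    r = g * rng.uniform(0.35, 0.75)
    b = r * rng.uniform(0.5, 0.9)
    return np.array([r, g, b])


def render_plant(kind: str, params: FieldParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one plant sprite; returns (rgb float array, boolean alpha mask).

    Crop sprites are broad-leaf rosettes; weed sprites are thin-blade tufts.
    Every in-mask pixel satisfies G > R and G > B.
    """
    s = params.scale()
    if kind == "crop":
        radius = rng.uniform(*params.crop_leaf_radius) * s
        half = int(np.ceil(radius * 1.8)) + 2
    elif kind == "weed":
        length = rng.uniform(*params.weed_blade_length) * s
        half = int(np.ceil(length * 1.2)) + 2
    else:
        raise ConfigurationError(f"unknown plant kind: {kind!r}")
    side = 2 * half + 1
    rgb = np.zeros((side, side, 3))
    mask = np.zeros((side, side), dtype=bool)
    center = np.array([half, half], dtype=float)

    if kind == "crop":
        n_leaves = rng.integers(4, 9)
        # rosette core so the overlapping leaves form one contiguous blob
        rr, cc = draw_ellipse(center[0], center[1], 0.40 * radius, 0.40 * radius, shape=mask.shape)
        rgb[rr, cc] = _leaf_green(rng)
        mask[rr, cc] = True
        angles = np.linspace(0, 2 * np.pi, n_leaves, endpoint=False) + rng.uniform(0, 2 * np.pi)
        for ang in angles:
            ang = ang + rng.normal(0, 0.15)
            lr = radius * rng.uniform(0.8, 1.0)
            cy = center[0] + 0.50 * lr * np.sin(ang)
            cx = center[1] + 0.50 * lr * np.cos(ang)
            rr, cc = draw_ellipse(cy, cx, 0.55 * lr, 0.36 * lr, shape=mask.shape, rotation=-ang)
            rgb[rr, cc] = _leaf_green(rng)
            mask[rr, cc] = True
    else:
        n_blades = rng.integers(5, 13)
        for _ in range(n_blades):
            ang = rng.uniform(0, 2 * np.pi)
            curve = rng.normal(0, 0.35)
            blade_len = length * rng.uniform(0.7, 1.0)
            width = rng.uniform(*params.weed_blade_width) * s
            color = _leaf_green(rng)
            for t in np.linspace(0.05, 1.0, max(8, int(2 * blade_len))):
                a = ang + curve * t  # blades bend as they extend
                py = center[0] + blade_len * t * np.sin(a)
                px = center[1] + blade_len * t * np.cos(a)
                r_disk = max(0.45, width * (1.0 - 0.5 * t) / 2.0)
                rr, cc = draw_disk((py, px), r_disk, shape=mask.shape)
                rgb[rr, cc] = color
                mask[rr, cc] = True
    return rgb, mask


def generate_sample(class_label: int, params: FieldParams,
                    rng: np.random.Generator | None = None) -> Sample:
    """Soil background composited with plants of a single class."""
    if class_label not in (0, 1):
        raise ConfigurationError(f"class_label must be 0 (crop) or 1 (weed), got {class_label}")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    img = make_soil_background(params, rng).astype(float)
    res = params.resolution
    kind = "crop" if class_label == 0 else "weed"
    n_plants = int(rng.integers(params.n_plants[0], params.n_plants[1] + 1))
    for _ in range(n_plants):
        sprite, mask = render_plant(kind, params, rng)
        sh = sprite.shape[0]
        # mostly-inside placement: at most ~1/6 of the sprite may leave the frame
        top = int(rng.integers(-sh // 6, res - 5 * sh // 6))
        left = int(rng.integers(-sh // 6, res - 5 * sh // 6))
        y0, y1 = max(0, top), min(res, top + sh)
        x0, x1 = max(0, left), min(res, left + sh)
        if y0 >= y1 or x0 >= x1:
            continue
        sub = mask[y0 - top : y1 - top, x0 - left : x1 - left]
        img[y0:y1, x0:x1][sub] = sprite[y0 - top : y1 - top, x0 - left : x1 - left][sub]
    # per-image illumination jitter: uneven daylight across UAV frames
    img = img * rng.uniform(*params.illumination)
    return Sample(image=np.clip(img, 0, 255).astype(np.uint8), label=class_label)


def generate_dataset(n_per_class: int, params: FieldParams) -> list[Sample]:
    """Balanced, seed-deterministic synthetic dataset (2 * n_per_class samples)."""
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    seeds = np.random.SeedSequence(params.seed).spawn(2 * n_per_class)
    samples = []
    for i, ss in enumerate(seeds):
        label = i % 2
        samples.append(generate_sample(label, params, np.random.default_rng(ss)))
    return samples


# ---------------------------------------------------------------------------
# Separability oracle
# ---------------------------------------------------------------------------

def vegetation_mask(image: np.ndarray) -> np.ndarray:
    img = image.astype(np.int32)
    return (img[:, :, 1] > img[:, :, 0]) & (img[:, :, 1] > img[:, :, 2])


def compactness(mask: np.ndarray) -> float:
    """area / perimeter^2 of a boolean mask (0 for an empty mask)."""
    area = float(mask.sum())
    if area == 0:
        return 0.0
    per = float(mask_perimeter(mask))
    if per == 0:
        return 1.0  # single isolated pixels: maximally compact by convention
    return area / per**2


def shape_features(image: np.ndarray) -> np.ndarray:
    """(green-pixel fraction, vegetation-mask compactness) for one raw image.

    Isolated speckle pixels from sensor noise are removed before measuring,
    as any practical vegetation-index pipeline would, and compactness is
    taken on the largest connected component (the dominant plant), which is
    insensitive to plant count and to small clipped fragments at the patch
    border.
    """
    mask = remove_small_objects(vegetation_mask(image), max_size=5)
    labelled = sk_label(mask)
    if labelled.max() == 0:
        return np.array([0.0, 0.0])
    sizes = np.bincount(labelled.ravel())[1:]
    main = compactness(labelled == (int(np.argmax(sizes)) + 1))
    return np.array([mask.mean(), main])


def separability_oracle(samples: list[Sample], seed: int = 0, test_fraction: float = 0.2) -> float:
    """Accuracy (%) of a 2-feature logistic probe with an 80/20 split.

    This is deliberately a shallow, non-convolutional reference: it bounds
    how much signal the two designed features carry, independently of any
    network trained downstream.
    """
    x = np.stack([shape_features(s.image) for s in samples])
    y = np.array([s.label for s in samples])
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(x))
    n_test = max(1, int(round(test_fraction * len(x))))
    test_idx, train_idx = idx[:n_test], idx[n_test:]
    clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
    clf.fit(x[train_idx], y[train_idx])
    return float(clf.score(x[test_idx], y[test_idx]) * 100.0)


def write_dataset(root: str | Path, samples: list[Sample], params: FieldParams,
                  class_names: tuple[str, str] = ("crop", "weed")) -> None:
    """Write samples as PNGs in the one-directory-per-class layout plus params.yaml."""
    root = Path(root)
    counters = [0, 0]
    for name in class_names:
        (root / name).mkdir(parents=True, exist_ok=True)
    for s in samples:
        name = class_names[s.label]
        out = root / name / f"{name}_{counters[s.label]:05d}.png"
        Image.fromarray(s.image).save(out)
        counters[s.label] += 1
    meta = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(params).items()}
    with open(root / "params.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
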
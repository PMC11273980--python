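"""Synthetic four-class image sets for download-free pipeline runs.

The generator emulates the *structure* of the brain-MRI classification task —
four classes of single-channel images whose identity is encoded by simple
geometry — without any pretence of anatomical realism:

  class 0 ("glioma")     bright filled ellipse near the image center
  class 1 ("meningioma") bright ring (annulus) near the center
  class 2 ("notumor")    background texture only, no structure
  class 3 ("pituitary")  compact bright blob in a fixed corner region

Position, radius and orientation jitter plus Gaussian pixel noise are drawn
from a seeded generator, so identical configs produce bitwise-identical sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .data import LabeledImageSet

DEFAULT_CLASS_NAMES = ("glioma", "meningioma", "notumor", "pituitary")


@dataclass
class SyntheticConfig:
    n_per_class: int = 100
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0
    difficulty: str = "easy"
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16x16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")


def _grid(h: int, w: int):
    return np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")


def _draw_class(label: int, h: int, w: int, rng: np.random.Generator,
                difficulty: str) -> np.ndarray:
    """One noiseless image of the given class on a dim textured background."""
    yy, xx = _grid(h, w)
    easy = difficulty == "easy"
    # low-amplitude smooth background texture
    fy, fx = rng.uniform(1, 3, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    img = 0.15 + 0.05 * np.sin(2 * np.pi * fy * yy / h + phase[0]) * \
        np.sin(2 * np.pi * fx * xx / w + phase[1])
    contrast = 0.7 if easy else 0.35
    jitter = 0.08 if easy else 0.2
    if label == 2:  # background only
        return img
    if label == 3:  # corner blob, fixed quadrant
        cy = h * (0.2 + rng.uniform(-jitter / 2, jitter / 2))
        cx = w * (0.2 + rng.uniform(-jitter / 2, jitter / 2))
        r = min(h, w) * rng.uniform(0.06, 0.1)
        img += contrast * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r ** 2)))
        return img
    cy = h * (0.5 + rng.uniform(-jitter, jitter))
    cx = w * (0.5 + rng.uniform(-jitter, jitter))
    if label == 0:  # filled ellipse
        ry = h * rng.uniform(0.12, 0.2)
        rx = w * rng.uniform(0.12, 0.2)
        theta = rng.uniform(0, np.pi)
        ys, xs = yy - cy, xx - cx
        u = ys * np.cos(theta) + xs * np.sin(theta)
        v = -ys * np.sin(theta) + xs * np.cos(theta)
        mask = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        img += contrast * mask
    else:  # label == 1: ring
        r_out = min(h, w) * rng.uniform(0.16, 0.22)
        width = r_out * (0.35 if easy else 0.5)
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        img += contrast * (np.abs(dist - r_out) <= width / 2)
    return img


def generate_synthetic_set(config: SyntheticConfig) -> LabeledImageSet:
    """Four balanced classes of single-channel images in [0, 1]."""
    h, w = config.image_size
    rng = np.random.default_rng(config.seed)
    images, labels = [], []
    for label in range(4):
        for _ in range(config.n_per_class):
            img = _draw_class(label, h, w, rng, config.difficulty)
            if config.noise_sd > 0:
                img = img + rng.normal(0, config.noise_sd, size=img.shape)
            images.append(np.clip(img, 0.0, 1.0)[None, :, :])
            labels.append(label)
    return LabeledImageSet(
        np.stack(images).astype(np.float32),
        np.asarray(labels),
        list(DEFAULT_CLASS_NAMES),
    )


def write_synthetic_folder(config: SyntheticConfig, root) -> Path:
    """Materialize the synthetic set as 8-bit PNGs in the class-folder layout
    that :func:`tumornet.data.load_image_folder` expects."""
    root = Path(root)
    data = generate_synthetic_set(config)
    counters = {name: 0 for name in data.class_names}
    for img, label in zip(data.images, data.labels):
        name = data.class_names[int(label)]
        class_dir = root / name
        class_dir.mkdir(parents=True, exist_ok=True)
        arr = np.round(img[0] * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(class_dir / f"{name}_{counters[name]:04d}.png")
        counters[name] += 1
    return root
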
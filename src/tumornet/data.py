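"""Image-folder loading and the shuffled 80/20 train/test split.

The expected on-disk layout is one subdirectory per class holding JPEG/PNG
files (the layout of the public brain-MRI dataset the classifier targets).
Images are decoded, bilinearly resized, scaled to [0, 1], and single-channel
inputs are replicated to three channels so the first conv block always sees
a 3-channel map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}


@dataclass
class LabeledImageSet:
    """Images as one (N, C, H, W) float32 array plus integer labels."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise ValueError("label index exceeds the number of class names")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "LabeledImageSet":
        indices = np.asarray(indices)
        return LabeledImageSet(self.images[indices], self.labels[indices], self.class_names)

    def to_three_channel(self) -> "LabeledImageSet":
        """Replicate single-channel images to three channels."""
        if self.images.shape[1] == 3:
            return self
        if self.images.shape[1] != 1:
            raise ValueError(f"cannot expand {self.images.shape[1]} channels to 3")
        return LabeledImageSet(np.repeat(self.images, 3, axis=1), self.labels, self.class_names)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == i).sum()) for i, name in enumerate(self.class_names)
        }


@dataclass
class SplitConfig:
    """Shuffled train/test split; the published protocol uses 0.8 / seed 101."""

    train_fraction: float = 0.8
    shuffle_seed: int = 101
    stratify: bool = False

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def load_image_folder(root, target_size: tuple[int, int]) -> LabeledImageSet:
    """Load ``<root>/<class_name>/*.{jpg,jpeg,png}`` into a LabeledImageSet.

    Class names are sorted lexicographically and labels assigned by that
    order.  Images are resized (bilinear) to ``target_size`` (height, width),
    pixel values scaled to [0, 1], grayscale replicated to 3 channels.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"data root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"{root} contains no class subdirectories")
    images, labels, class_names = [], [], []
    h, w = target_size
    for label, class_dir in enumerate(class_dirs):
        class_names.append(class_dir.name)
        files = sorted(
            f for f in class_dir.iterdir() if f.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise ValueError(f"class folder {class_dir} holds no images")
        for path in files:
            try:
                with Image.open(path) as img:
                    img = img.convert("L") if img.mode not in ("RGB", "L") else img
                    img = img.resize((w, h), Image.BILINEAR)
                    arr = np.asarray(img, dtype=np.float32) / 255.0
            except Exception as exc:
                raise ValueError(f"unreadable image file {path}: {exc}") from exc
            if arr.ndim == 2:
                arr = np.repeat(arr[None, :, :], 3, axis=0)
            else:
                arr = arr.transpose(2, 0, 1)
            images.append(arr)
            labels.append(label)
    return LabeledImageSet(np.stack(images), np.asarray(labels), class_names)


def train_test_split(data: LabeledImageSet,
                     config: SplitConfig) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Shuffle with ``shuffle_seed`` and cut at round(n * train_fraction).

    With ``stratify`` the split is performed per class with the same seed,
    preserving class proportions; the default is the plain shuffled split of
    the published protocol.
    """
    n = len(data)
    rng = np.random.default_rng(config.shuffle_seed)
    if config.stratify:
        train_idx, test_idx = [], []
        for c in range(data.num_classes):
            cls = np.flatnonzero(data.labels == c)
            perm = cls[rng.permutation(len(cls))]
            cut = int(round(len(cls) * config.train_fraction))
            train_idx.append(perm[:cut])
            test_idx.append(perm[cut:])
        train_idx = np.concatenate(train_idx)
        test_idx = np.concatenate(test_idx)
    else:
        perm = rng.permutation(n)
        cut = int(round(n * config.train_fraction))
        train_idx, test_idx = perm[:cut], perm[cut:]
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError(
            f"train_fraction {config.train_fraction} leaves an empty side for n={n}"
        )
    return data.subset(train_idx), data.subset(test_idx)
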
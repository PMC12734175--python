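"""Image-folder loading, preprocessing, and on-the-fly augmentation.

Datasets follow the usual class-per-directory layout (one subdirectory
per class, JPEG/PNG files inside). Preprocessing is a plain bilinear
resize to a square followed by division by 255; augmentation applies
rotation, flips, and additive Gaussian noise, and is only ever applied
to training folds.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from ..branches import ImageBatch

logger = logging.getLogger("leafgate.data")

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}

__all__ = [
    "DatasetManifest", "load_image_folder", "load_images", "preprocess",
    "AugmentationSpec", "augment", "rotate_image",
]


@dataclass
class DatasetManifest:
    """Inventory of a class-per-directory image dataset.

    ``classes`` are unique and lexically sorted; ``files`` maps each class
    to its image paths; ``folds`` optionally maps each file to a fold
    index (or train/test role) and never places a file in two splits.
    """

    root: Path
    classes: list[str]
    files: dict[str, list[Path]]
    folds: dict[str, int] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(self.files[c]) for c in self.classes}

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.files.values())

    def write_csv(self, path: Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["file", "class", "fold"])
            for c in self.classes:
                for f in self.files[c]:
                    w.writerow([str(f), c, self.folds.get(str(f), "")])


def load_image_folder(root) -> DatasetManifest:
    """Scan a class-per-directory tree into a manifest.

    Empty class directories are excluded with a warning; files that are
    not decodable images raise an error naming the file; non-image files
    are ignored (their count is logged).
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    classes, files = [], {}
    n_ignored = 0
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        entries = sorted(p for p in sub.iterdir() if p.is_file())
        images = [p for p in entries if p.suffix.lower() in IMAGE_EXTENSIONS]
        n_ignored += len(entries) - len(images)
        if not images:
            logger.warning("class directory %s has no images; excluded", sub.name)
            continue
        for p in images:
            try:
                with Image.open(p) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError) as exc:
                raise ValueError(f"undecodable image file {p}") from exc
        classes.append(sub.name)
        files[sub.name] = images
    if n_ignored:
        logger.info("ignored %d non-image files", n_ignored)
    return DatasetManifest(root=root, classes=classes, files=files)


def preprocess(image, size: int = 224) -> np.ndarray:
    """Resize to ``size x size`` (plain bilinear) and scale to [0, 1].

    Accepts a PIL image, a uint8 array, or a float array already in
    [0, 1]. Non-RGB inputs are converted (with a logged note).
    """
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, np.ndarray):
        if image.size == 0:
            raise ValueError("zero-sized image")
        if image.dtype != np.uint8:
            arr = np.asarray(image, dtype=np.float64)
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("float image input must already lie in [0, 1]")
            image = (arr * 255).round().astype(np.uint8)
        image = Image.fromarray(image)
    if image.width == 0 or image.height == 0:
        raise ValueError("zero-sized image")
    if image.mode != "RGB":
        logger.info("converting %s image to RGB", image.mode)
        image = image.convert("RGB")
    if (image.width, image.height) != (size, size):
        image = image.resize((size, size), Image.BILINEAR)
    return np.asarray(image, dtype=np.float32) / 255.0


def load_images(manifest: DatasetManifest, size: int = 224) -> ImageBatch:
    """Decode and preprocess every file in a manifest into one batch."""
    pixels, labels, ids = [], [], []
    for k, c in enumerate(manifest.classes):
        for p in manifest.files[c]:
            pixels.append(preprocess(p, size=size))
            labels.append(k)
            ids.append(str(p.relative_to(manifest.root)))
    return ImageBatch(np.stack(pixels), np.asarray(labels), ids)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """Rotation / flip / additive-noise augmentation parameters.

    ``rotation`` is the maximum absolute angle in degrees (drawn
    uniformly), flips are Bernoulli with the given probabilities, and
    ``noise_sigma`` is the standard deviation of additive Gaussian noise
    in normalized pixel units (output re-clipped to [0, 1]).
    """

    rotation: float = 30.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    noise_sigma: float = 0.05

    def __post_init__(self):
        if not (0 <= self.hflip_prob <= 1 and 0 <= self.vflip_prob <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.rotation < 0:
            raise ValueError("rotation range must be nonnegative")

    @classmethod
    def off(cls) -> "AugmentationSpec":
        return cls(rotation=0.0, hflip_prob=0.0, vflip_prob=0.0, noise_sigma=0.0)

    def with_(self, **kw) -> "AugmentationSpec":
        return replace(self, **kw)


def rotate_image(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the centre with bilinear interpolation, reflect padding."""
    out = ndimage.rotate(image, angle, axes=(1, 0), reshape=False, order=1,
                         mode="reflect")
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def augment(image: np.ndarray, spec: AugmentationSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to one image."""
    out = np.asarray(image, dtype=np.float32)
    if spec.rotation > 0:
        angle = rng.uniform(-spec.rotation, spec.rotation)
        out = rotate_image(out, angle)
    if spec.hflip_prob > 0 and rng.random() < spec.hflip_prob:
        out = out[:, ::-1, :]
    if spec.vflip_prob > 0 and rng.random() < spec.vflip_prob:
        out = out[::-1, :, :]
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
        out = np.clip(out, 0.0, 1.0)
    return np.ascontiguousarray(out, dtype=np.float32)
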
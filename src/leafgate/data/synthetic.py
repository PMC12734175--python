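"""Seeded synthetic leaf-disease image generator.

Each image is an elliptical leaf with faint veins on a textured soil
background. Disease classes differ in *where* lesion pigment is placed,
not in how much of it there is: every lesion class targets the same leaf
area fraction and uses the same lesion colour, so class identity is
carried by spatial arrangement rather than by global colour statistics.

* ``speckle`` — many small high-frequency dots (a detail-scale cue);
* ``blotch`` — one large, smooth-edged discoloured region (a global,
  low-frequency cue);
* ``vein_aligned`` — lesions laid along the lateral veins with
  left-right symmetry about the midrib (a long-range structural cue);
* ``healthy`` — base leaf texture only;
* ``mixed`` — one of the three lesion cues drawn per image, which forces
  image-adaptive (rather than class-constant) branch gating.

All randomness derives from ``spec.seed`` through named substreams; the
same spec always yields bitwise-identical arrays. Pixels are quantized
to the uint8 grid so a PNG dump round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from ..branches import ImageBatch
from ..utils import substream
from .pipeline import DatasetManifest

CUE_TYPES = ("healthy", "speckle", "blotch", "vein_aligned", "mixed")

__all__ = ["SyntheticDatasetSpec", "synth_generate", "write_dataset",
           "baseline_features", "CUE_TYPES"]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for one synthetic dataset.

    ``n_per_class`` is the minority-class count; the first listed class
    is the majority class and receives ``imbalance_ratio`` times as many
    images (mirroring real leaf-disease surveys where one disease
    dominates collection counts). ``cue_strength`` in (0, 1] scales the
    lesion/leaf contrast; ``lesion_fraction`` is the leaf-area fraction
    covered by lesions in every diseased class.
    """

    n_per_class: int = 200
    classes: tuple[str, ...] = ("blotch", "healthy", "speckle", "vein_aligned")
    image_size: int = 64
    imbalance_ratio: float = 1.0
    cue_strength: float = 0.95
    lesion_fraction: float = 0.16
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio must be >= 1")
        for c in self.classes:
            if c not in CUE_TYPES:
                raise ValueError(f"unknown cue type {c!r}; choose from {CUE_TYPES}")
        if not 0 < self.cue_strength <= 1:
            raise ValueError("cue_strength must lie in (0, 1]")

    def counts(self) -> dict[str, int]:
        out = {c: self.n_per_class for c in self.classes}
        out[self.classes[0]] = int(round(self.imbalance_ratio * self.n_per_class))
        return out

    def with_(self, **kw) -> "SyntheticDatasetSpec":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _leaf_frame(S: int, rng: np.random.Generator):
    """Leaf ellipse axes and a rotated (u, v) coordinate frame."""
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    cx = cy = (S - 1) / 2.0
    theta = rng.uniform(0, np.pi)
    a = S * rng.uniform(0.40, 0.45)     # semi-major (along midrib)
    b = S * rng.uniform(0.28, 0.33)     # semi-minor
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * (xx - cx) + st * (yy - cy)
    v = -st * (xx - cx) + ct * (yy - cy)
    return u, v, a, b


def _smooth_noise(S: int, rng: np.random.Generator, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal((S, S)), sigma)


def _vein_segments(a: float, b: float, n_pairs: int = 4):
    """Lateral vein segments in leaf coordinates, symmetric about the midrib.

    Each segment runs from a point on the midrib outward at a fixed
    angle; the ``side=-1`` twin is its exact mirror image.
    """
    phi = np.deg2rad(55.0)
    segs = []
    for j in range(n_pairs):
        u0 = -0.65 * a + j * (1.2 * a / n_pairs)
        length = 0.85 * b * (1.0 - 0.3 * abs(u0) / a)
        for side in (+1.0, -1.0):
            segs.append((u0, side, phi, length))
    return segs


def _paint_segment(mask: np.ndarray, u: np.ndarray, v: np.ndarray,
                   seg, radius: float, t0: float = 0.0, t1: float = 1.0) -> None:
    u0, side, phi, length = seg
    ts = np.linspace(t0 * length, t1 * length, max(int(2 * length), 2))
    for t in ts:
        pu = u0 + t * np.cos(phi)
        pv = side * t * np.sin(phi)
        mask |= (u - pu) ** 2 + (v - pv) ** 2 <= radius ** 2


def _speckle_overlay(S: int, leaf: np.ndarray, fraction: float,
                     lesion_col: np.ndarray, strength: float,
                     rng: np.random.Generator):
    """Two-tone pustules: dark core with a brighter rim.

    The rim/core contrast gives speckle its high-frequency signature
    while the spot-averaged colour stays close to the shared lesion
    colour, keeping channel means matched across disease classes.
    """
    scale = S / 64.0
    r = 1.4 * scale
    leaf_area = float(leaf.sum())
    n_dots = max(4, int(round(fraction * leaf_area / (np.pi * r * r))))
    idx = np.flatnonzero(leaf)
    picks = rng.choice(idx, size=min(n_dots, idx.size), replace=False)
    core = np.zeros((S, S), dtype=bool)
    rim = np.zeros((S, S), dtype=bool)
    yy, xx = np.unravel_index(picks, (S, S))
    gy, gx = np.mgrid[0:S, 0:S]
    for cy_, cx_ in zip(yy, xx):
        d2 = (gy - cy_) ** 2 + (gx - cx_) ** 2
        core |= d2 <= (0.7 * r) ** 2
        rim |= (d2 > (0.7 * r) ** 2) & (d2 <= r * r)
    alpha = (((core | rim) & (leaf > 0)).astype(np.float64) * strength)[..., None]
    colour = np.where(core[..., None], (lesion_col - 0.15)[None, None, :],
                      (lesion_col + 0.12)[None, None, :])
    return alpha, colour


def _lesion_mask(cue: str, S: int, u, v, a, b, leaf: np.ndarray,
                 fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Soft [0, 1] lesion alpha mask (blotch and vein-aligned cues).

    Both cues are built from the same thick streak primitive (same
    width, same edge blur), so their local texture statistics match;
    what distinguishes them is the arrangement — one concentrated
    cluster versus streaks radiating along the symmetric lateral veins.
    """
    leaf_area = float(leaf.sum())
    scale = S / 64.0
    if cue == "blotch":
        # one large, smoothly-bounded discoloured region: a purely
        # low-frequency cue with no sharp edges
        target = fraction * leaf_area
        aspect = rng.uniform(0.7, 1.4)
        ra = np.sqrt(target * aspect / np.pi)
        rb = np.sqrt(target / (aspect * np.pi))
        ou = rng.uniform(-0.30, 0.30) * a
        ov = rng.uniform(-0.30, 0.30) * b
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        uu = ca * (u - ou) + sa * (v - ov)
        vv = -sa * (u - ou) + ca * (v - ov)
        mask = (uu / ra) ** 2 + (vv / rb) ** 2 <= 1.0
        soft = ndimage.gaussian_filter(mask.astype(np.float64), 2.5 * scale)
        # renormalise so total pigment matches the hard-masked cues
        inside = soft * (leaf > 0)
        if inside.sum() > 0:
            soft = np.clip(soft * (target / inside.sum()), 0.0, 1.0)
    elif cue == "vein_aligned":
        # thin lesions along symmetric lateral veins: fine, long-range
        # structure that survives only at (near-)full resolution
        segs = _vein_segments(a, b)
        pair_ids = rng.choice(len(segs) // 2, size=3, replace=False)
        mask = np.zeros((S, S), dtype=bool)
        for pid in pair_ids:
            for seg in (segs[2 * pid], segs[2 * pid + 1]):
                _paint_segment(mask, u, v, seg, radius=1.2 * scale,
                               t0=0.15, t1=0.9)
        soft = ndimage.gaussian_filter(mask.astype(np.float64), 0.5 * scale)
    else:
        raise ValueError(f"unknown lesion cue {cue!r}")
    return np.clip(soft, 0.0, 1.0) * leaf


def _render_image(cue: str, spec: SyntheticDatasetSpec,
                  rng: np.random.Generator) -> np.ndarray:
    S = spec.image_size
    u, v, a, b = _leaf_frame(S, rng)
    leaf = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.float64)

    # background: brown soil texture
    bg_col = np.array([0.36, 0.28, 0.20]) + rng.uniform(-0.02, 0.02, 3)
    img = np.empty((S, S, 3))
    for c in range(3):
        img[:, :, c] = bg_col[c] + 0.05 * _smooth_noise(S, rng, 3.0) \
            + 0.005 * rng.standard_normal((S, S))

    # leaf: green with low-frequency mottle and fine grain
    leaf_col = np.array([0.20, 0.45, 0.14]) + rng.uniform(-0.02, 0.02, 3)
    mottle = 0.04 * _smooth_noise(S, rng, 2.5)
    grain = 0.002 * rng.standard_normal((S, S))
    leaf_img = np.empty_like(img)
    for c in range(3):
        leaf_img[:, :, c] = leaf_col[c] + mottle + grain

    # faint veins (present in every class): midrib + lateral pairs
    veins = np.zeros((S, S), dtype=bool)
    veins |= (np.abs(v) <= 0.7 * S / 64) & (np.abs(u) <= 0.92 * a)
    for seg in _vein_segments(a, b):
        _paint_segment(veins, u, v, seg, radius=0.6 * S / 64)
    leaf_img[veins] += 0.035

    edge = ndimage.gaussian_filter(leaf, 0.7)[..., None]
    img = img * (1 - edge) + leaf_img * edge

    actual_cue = cue
    if cue == "mixed":
        actual_cue = rng.choice(["speckle", "blotch", "vein_aligned"])
    if actual_cue != "healthy":
        lesion_col = np.array([0.42, 0.30, 0.10]) + rng.uniform(-0.03, 0.03, 3)
        if actual_cue == "speckle":
            alpha, colour = _speckle_overlay(S, leaf, spec.lesion_fraction,
                                             lesion_col, spec.cue_strength, rng)
            img = img * (1 - alpha) + colour * alpha
        elif actual_cue == "blotch":
            # additive colour shift: the underlying leaf texture is kept,
            # so the cue is purely the low-frequency discoloration; the
            # blotch covers twice the streak/speckle fraction, matching
            # the way large-area discoloration presents in the field
            alpha = _lesion_mask(actual_cue, S, u, v, a, b, leaf > 0,
                                 2 * spec.lesion_fraction, rng)
            alpha = (alpha * spec.cue_strength)[..., None]
            img = img + alpha * (lesion_col - leaf_col)[None, None, :]
        else:
            alpha = _lesion_mask(actual_cue, S, u, v, a, b, leaf > 0,
                                 spec.lesion_fraction, rng)
            alpha = (alpha * spec.cue_strength)[..., None]
            img = img * (1 - alpha) + lesion_col * alpha

    quantized = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
    return quantized.astype(np.float32) / 255.0


def synth_generate(spec: SyntheticDatasetSpec) -> tuple[ImageBatch, list[str]]:
    """Render the dataset described by ``spec``.

    Returns an :class:`ImageBatch` (labels index into the returned class
    list, which preserves ``spec.classes`` order) plus the class names.
    """
    pixels, labels, ids = [], [], []
    counts = spec.counts()
    for k, cls in enumerate(spec.classes):
        for i in range(counts[cls]):
            rng = substream(spec.seed, f"synth/{cls}/{i}")
            pixels.append(_render_image(cls, spec, rng))
            labels.append(k)
            ids.append(f"{cls}/{cls}_{i:04d}.png")
    return ImageBatch(np.stack(pixels), np.asarray(labels), ids), list(spec.classes)


def write_dataset(images: ImageBatch, class_names: list[str], root,
                  write_manifest: bool = True) -> DatasetManifest:
    """Dump a batch as a class-per-directory PNG tree (lossless round-trip)."""
    root = Path(root)
    files: dict[str, list[Path]] = {c: [] for c in class_names}
    for pix, label, img_id in zip(images.pixels, images.labels, images.ids):
        cls = class_names[label]
        rel = Path(img_id) if "/" in img_id else Path(cls) / f"{img_id}.png"
        path = root / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.round(np.asarray(pix) * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
        files[cls].append(path)
    manifest = DatasetManifest(root=root, classes=sorted(class_names),
                               files={c: files[c] for c in sorted(class_names)})
    if write_manifest:
        manifest.write_csv(root / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# separability diagnostic
# ---------------------------------------------------------------------------

def baseline_features(pixels: np.ndarray) -> np.ndarray:
    """Pixel-statistics features: channel means + radial spectral energies.

    Used as a model-free separability check on generated datasets: a
    linear classifier on these features should already distinguish the
    cue classes, confirming the signal exists before any deep model is
    trained.
    """
    pixels = np.asarray(pixels)
    n, S = pixels.shape[0], pixels.shape[1]
    chan_means = pixels.mean(axis=(1, 2))                      # (n, 3)
    gray = pixels.mean(axis=-1)
    gray = gray - gray.mean(axis=(1, 2), keepdims=True)
    spec = np.abs(np.fft.fft2(gray)) ** 2
    fy = np.fft.fftfreq(S)[:, None]
    fx = np.fft.fftfreq(S)[None, :]
    r = np.sqrt(fx**2 + fy**2) / 0.5
    bands = [(0.0, 0.1), (0.1, 0.25), (0.25, 0.5), (0.5, 1.01)]
    energies = np.stack(
        [spec[:, (r >= lo) & (r < hi)].sum(axis=1) for lo, hi in bands],
        axis=1,
    )
    return np.concatenate([chan_means, np.log(energies + 1e-12)], axis=1)
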
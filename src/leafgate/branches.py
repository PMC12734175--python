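"""The three feature-extraction branches of the leaf-disease classifier.

A detail-scale CNN preserves high-frequency texture (tiny speckles, fine
lesion edges) at 1/4 of the input resolution; a global-context CNN
aggressively downsamples to 1/32 resolution to capture whole-leaf cues
such as large discolored areas; a vision-transformer branch models
long-range structure (vein-aligned or symmetric lesion layouts) through
patch tokens and self-attention, summarised by a classification token.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GELU,
    LayerNorm,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
    concat,
)

__all__ = [
    "ImageBatch",
    "BranchConfig",
    "FeatureMap",
    "TokenSequence",
    "DetailBranch",
    "GlobalBranch",
    "ViTBranch",
    "detail_branch_forward",
    "global_branch_forward",
    "vit_branch_forward",
    "patchify",
    "self_attention",
    "images_to_tensor",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageBatch:
    """A batch of preprocessed RGB images with integer class labels.

    ``pixels`` has shape ``(batch, height, width, 3)`` with values in
    [0, 1]; ``labels`` are class indices; ``ids`` identify images across
    exports (gate reports, manifests).
    """

    pixels: np.ndarray
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.pixels.ndim != 4 or self.pixels.shape[-1] != 3:
            raise ValueError(
                f"pixels must be (batch, height, width, 3), got {self.pixels.shape}"
            )
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("pixel values must lie in [0, 1] after preprocessing")
        if len(self.labels) != len(self.pixels):
            raise ValueError("labels and pixels disagree in batch size")
        if not self.ids:
            self.ids = [f"img{i:05d}" for i in range(len(self.pixels))]

    def __len__(self) -> int:
        return len(self.pixels)

    def subset(self, idx) -> "ImageBatch":
        idx = np.asarray(idx)
        return ImageBatch(self.pixels[idx], self.labels[idx],
                          [self.ids[i] for i in idx])


@dataclass(frozen=True)
class BranchConfig:
    """Architecture hyperparameters shared by the three branches.

    The full preset mirrors the published architecture (64-channel detail
    branch, 128-channel global branch, ViT-Base transformer); the tiny
    preset is a desk-scale variant used throughout the test suite.
    """

    input_size: int = 224
    detail_channels: int = 64
    global_channels: int = 128
    vit_patch: int = 16
    vit_dim: int = 768
    vit_layers: int = 12
    vit_heads: int = 12
    common_dim: int = 256
    gate_hidden: int = 12
    fusion_dim: int = 256      # attention-fusion projection width
    tiny_preset: bool = False

    def __post_init__(self):
        for name in ("input_size", "detail_channels", "global_channels",
                     "vit_patch", "vit_dim", "vit_layers", "vit_heads",
                     "common_dim", "gate_hidden", "fusion_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_size % self.vit_patch:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"vit_patch {self.vit_patch}"
            )
        if self.vit_dim % self.vit_heads:
            raise ValueError("vit_dim must be divisible by vit_heads")

    @classmethod
    def full(cls, **overrides) -> "BranchConfig":
        return replace(cls(), **overrides) if overrides else cls()

    @classmethod
    def tiny(cls, **overrides) -> "BranchConfig":
        cfg = cls(input_size=64, detail_channels=16, global_channels=32,
                  vit_patch=16, vit_dim=64, vit_layers=2, vit_heads=2,
                  common_dim=32, gate_hidden=12, fusion_dim=64,
                  tiny_preset=True)
        return replace(cfg, **overrides) if overrides else cfg

    @property
    def n_patches(self) -> int:
        return (self.input_size // self.vit_patch) ** 2


@dataclass
class FeatureMap:
    """Convolutional activations ``(batch, channels, h', w')``."""

    activations: Tensor
    downsample_factor: int

    @property
    def channels(self) -> int:
        return self.activations.shape[1]


@dataclass
class TokenSequence:
    """ViT tokens ``(batch, N+1, vit_dim)``; the CLS token is index 0."""

    tokens: Tensor
    positional: np.ndarray

    @property
    def n_patch_tokens(self) -> int:
        return self.tokens.shape[1] - 1


def images_to_tensor(images: ImageBatch) -> Tensor:
    """Convert an image batch to a channels-first float tensor."""
    return Tensor(np.ascontiguousarray(images.pixels.transpose(0, 3, 1, 2)))


def _check_divisible(h: int, w: int, factor: int) -> None:
    if h % factor:
        raise ValueError(f"height {h} not divisible by downsample factor {factor}")
    if w % factor:
        raise ValueError(f"width {w} not divisible by downsample factor {factor}")


# ---------------------------------------------------------------------------
# detail-scale CNN (1/4 resolution)
# ---------------------------------------------------------------------------

class _ResidualBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, rng, padding=1, bias=False)
        self.bn1 = BatchNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, rng, padding=1, bias=False)
        self.bn2 = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (x + y).relu()


class DetailBranch(Module):
    """Shallow high-resolution CNN; output ``detail_channels`` at 1/4 size.

    The branch is responsible for high-frequency evidence only, so its
    input is high-pass filtered (image minus a Gaussian blur): fine
    speckles, lesion edges, and thin streaks pass through while smooth
    large-area discoloration — the global branch's territory — is
    suppressed. This enforces the scale separation between branches by
    construction rather than hoping training discovers it.

    Two stride-1 3x3 convolutions then scan at full resolution, a single
    2x2 max-pool and one strided 3x3 convolution bring the map to 1/4
    resolution, and two residual blocks refine it. Batch normalisation
    and ReLU follow every convolution.
    """

    downsample_factor = 4

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.detail_channels
        # blur scale grows with input size so the passband is relative
        self.highpass_sigma = cfg.input_size / 64.0
        self.stem = Sequential(
            Conv2d(3, d, 3, rng, padding=1, bias=False), BatchNorm2d(d), ReLU(),
            Conv2d(d, d, 3, rng, padding=1, bias=False), BatchNorm2d(d), ReLU(),
            MaxPool2d(2),
            Conv2d(d, d, 3, rng, stride=2, padding=1, bias=False),
            BatchNorm2d(d), ReLU(),
        )
        self.res1 = _ResidualBlock(d, rng)
        self.res2 = _ResidualBlock(d, rng)

    def _highpass(self, x: Tensor) -> Tensor:
        from scipy.ndimage import gaussian_filter

        low = gaussian_filter(x.data, sigma=(0, 0, self.highpass_sigma,
                                             self.highpass_sigma))
        return Tensor((x.data - low).astype(np.float32))

    def forward(self, x: Tensor) -> FeatureMap:
        _check_divisible(x.shape[2], x.shape[3], self.downsample_factor)
        y = self.res2(self.res1(self.stem(self._highpass(x))))
        return FeatureMap(y, self.downsample_factor)


# ---------------------------------------------------------------------------
# global-context CNN (1/32 resolution)
# ---------------------------------------------------------------------------

class GlobalBranch(Module):
    """Aggressively downsampling CNN; output ``global_channels`` at 1/32.

    Works on a 2x-downsampled copy of the image (average pooling), so
    sub-pixel texture is invisible to it by construction and only
    low-frequency, whole-leaf cues remain. A 7x7 stride-2 convolution
    opens the stem, 3x3 convolutions alternate with 2x2 pools, and the
    final stage uses dilation 2 to widen the receptive field without
    extra pooling.
    """

    downsample_factor = 32

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator):
        super().__init__()
        g = cfg.global_channels
        if g % 4:
            raise ValueError("global_channels must be divisible by 4")
        self.stem = Sequential(
            AvgPool2d(2),                     # downsampled input copy
            Conv2d(3, g // 4, 7, rng, stride=2, padding=3, bias=False),
            BatchNorm2d(g // 4), ReLU(),
            MaxPool2d(2),
            Conv2d(g // 4, g // 2, 3, rng, padding=1, bias=False),
            BatchNorm2d(g // 2), ReLU(),
            MaxPool2d(2),
            Conv2d(g // 2, g, 3, rng, padding=2, dilation=2, bias=False),
            BatchNorm2d(g), ReLU(),
            MaxPool2d(2),
        )

    def forward(self, x: Tensor) -> FeatureMap:
        _check_divisible(x.shape[2], x.shape[3], self.downsample_factor)
        return FeatureMap(self.stem(x), self.downsample_factor)


# ---------------------------------------------------------------------------
# transformer branch
# ---------------------------------------------------------------------------

def self_attention(Q, K, V):
    """Scaled dot-product attention: ``softmax(Q K^T / sqrt(d_k)) V``.

    Accepts numpy arrays or :class:`Tensor` objects with matching inner
    dimensions; supports stacked leading (batch/head) axes.
    """
    q = Q if isinstance(Q, Tensor) else Tensor(np.asarray(Q, dtype=np.float64))
    k = K if isinstance(K, Tensor) else Tensor(np.asarray(K, dtype=np.float64))
    v = V if isinstance(V, Tensor) else Tensor(np.asarray(V, dtype=np.float64))
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(
            f"query width {q.shape[-1]} != key width {k.shape[-1]}"
        )
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(
            f"key count {k.shape[-2]} != value count {v.shape[-2]}"
        )
    d_k = q.shape[-1]
    axes = tuple(range(k.ndim))
    kT = k.transpose(*axes[:-2], axes[-1], axes[-2])
    scores = q.matmul(kT) * (1.0 / np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    out = weights.matmul(v)
    if not isinstance(Q, Tensor):
        return out.data
    return out


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(B, T, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (B, h, T, hd)
        attended = self_attention(q, k, v)        # (B, h, T, hd)
        merged = attended.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(merged)


class _EncoderBlock(Module):
    """Pre-norm transformer encoder layer with a 4x MLP."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = Sequential(Linear(dim, 4 * dim, rng), GELU(),
                              Linear(4 * dim, dim, rng))

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.mlp(self.ln2(x))


class ViTBranch(Module):
    """Patch-token transformer whose CLS embedding summarises structure."""

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator,
                 input_size: int | None = None):
        super().__init__()
        self.cfg = cfg
        self.input_size = input_size or cfg.input_size
        if self.input_size % cfg.vit_patch:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"vit_patch {cfg.vit_patch}"
            )
        n = (self.input_size // cfg.vit_patch) ** 2
        d = cfg.vit_dim
        self.patch_proj = Linear(cfg.vit_patch ** 2 * 3, d, rng)
        self.cls_token = Tensor(
            (rng.standard_normal((1, 1, d)) * 0.02).astype(np.float32),
            requires_grad=True)
        self.pos_embed = Tensor(
            (rng.standard_normal((1, n + 1, d)) * 0.02).astype(np.float32),
            requires_grad=True)
        self.blocks = Sequential(*[_EncoderBlock(d, cfg.vit_heads, rng)
                                   for _ in range(cfg.vit_layers)])
        self.ln = LayerNorm(d)

    # -- tokenisation ---------------------------------------------------
    def tokenize(self, x: Tensor) -> TokenSequence:
        """Split into patches, project, prepend CLS, add positions."""
        B, C, H, W = x.shape
        p = self.cfg.vit_patch
        if H % p or W % p:
            raise ValueError(f"image {H}x{W} not divisible by patch size {p}")
        nh, nw = H // p, W // p
        patches = (x.reshape(B, C, nh, p, nw, p)
                    .transpose(0, 2, 4, 1, 3, 5)
                    .reshape(B, nh * nw, C * p * p))
        tok = self.patch_proj(patches)                       # (B, N, D)
        cls = self.cls_token + Tensor(np.zeros((B, 1, tok.shape[-1]),
                                               dtype=np.float32))
        tokens = concat([cls, tok], axis=1) + self.pos_embed
        return TokenSequence(tokens, self.pos_embed.data[0])

    def forward(self, x: Tensor) -> Tensor:
        seq = self.tokenize(x)
        encoded = self.ln(self.blocks(seq.tokens))
        return encoded[:, 0, :]                              # CLS embedding


# ---------------------------------------------------------------------------
# thin functional wrappers (deterministic given a seed)
# ---------------------------------------------------------------------------

def detail_branch_forward(images: ImageBatch, cfg: BranchConfig,
                          seed: int = 0) -> FeatureMap:
    branch = DetailBranch(cfg, np.random.default_rng(seed))
    branch.eval()
    return branch(images_to_tensor(images))


def global_branch_forward(images: ImageBatch, cfg: BranchConfig,
                          seed: int = 0) -> FeatureMap:
    branch = GlobalBranch(cfg, np.random.default_rng(seed))
    branch.eval()
    return branch(images_to_tensor(images))


def patchify(images: ImageBatch, cfg: BranchConfig, seed: int = 0) -> TokenSequence:
    size = images.pixels.shape[1]
    vit = ViTBranch(cfg, np.random.default_rng(seed), input_size=size)
    vit.eval()
    return vit.tokenize(images_to_tensor(images))


def vit_branch_forward(images: ImageBatch, cfg: BranchConfig,
                       seed: int = 0) -> Tensor:
    size = images.pixels.shape[1]
    vit = ViTBranch(cfg, np.random.default_rng(seed), input_size=size)
    vit.eval()
    return vit(images_to_tensor(images))
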
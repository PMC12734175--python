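"""Gated Scale-Attention Fusion (GSAF) and alternative fusion strategies.

GSAF projects the three branch outputs to a common width ``C``, pools
them to global descriptors ``z_i``, feeds the concatenated descriptor
through a tiny two-layer MLP to obtain logits ``s``, and forms a
temperature softmax gate ``g = softmax(s / tau)``. The fused embedding
is the convex combination ``Phi = g_d phi_d + g_g phi_g + g_t phi_t``.

Alternative strategies used in ablations — score-based attention fusion
over a 256-wide common projection, static concatenation/averaging,
single-branch heads, and an optional cross-attention exchange between
the pooled branch tokens — live here as well so that ablation runs share
one model class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .branches import (
    BranchConfig,
    DetailBranch,
    FeatureMap,
    GlobalBranch,
    ViTBranch,
    self_attention,
)
from .nn import Conv2d, Linear, Module, Sequential, GELU, Tensor, concat, stack

__all__ = [
    "CommonEmbedding",
    "GateWeights",
    "FusedEmbedding",
    "GateNetwork",
    "AttentionFusion",
    "CrossBranchAttention",
    "HMCTAFModel",
    "FUSION_STRATEGIES",
    "global_average_pool",
    "project_to_common",
    "compute_gate",
    "fuse_gsaf",
    "gate_entropy",
    "attention_fusion",
    "static_fusion",
    "count_gate_parameters",
]

#: fusion strategies understood by :class:`HMCTAFModel` and the ablation driver
FUSION_STRATEGIES = (
    "gsaf", "gsaf_no_sparsity", "attention", "static_concat", "static_average",
    "cross_attention", "detail_only", "global_only", "vit_only", "cnns_only",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CommonEmbedding:
    """Branch embeddings projected and pooled to a shared width ``C``."""

    phi_d: Tensor
    phi_g: Tensor
    phi_t: Tensor

    @property
    def width(self) -> int:
        return self.phi_d.shape[-1]


@dataclass
class GateWeights:
    """Gate computation intermediates for one batch.

    ``u = [z_d; z_g; z_t]`` (detail, global, transformer order),
    ``s`` the logits, ``g`` the softmax gate on the probability simplex.
    """

    z_d: Tensor
    z_g: Tensor
    z_t: Tensor
    u: Tensor
    s: Tensor
    g: Tensor

    @property
    def gate_array(self) -> np.ndarray:
        return np.asarray(self.g.data)


@dataclass
class FusedEmbedding:
    phi: Tensor
    strategy: str


# ---------------------------------------------------------------------------
# functional pieces
# ---------------------------------------------------------------------------

def global_average_pool(phi) -> Tensor:
    """Per-channel spatial mean; identity on already-pooled vectors."""
    t = phi.activations if isinstance(phi, FeatureMap) else phi
    if not isinstance(t, Tensor):
        t = Tensor(np.asarray(t))
    if t.ndim == 2:
        return t
    if t.ndim == 4:
        if t.shape[2] == 0 or t.shape[3] == 0:
            raise ValueError("cannot pool a feature map with empty spatial extent")
        return t.mean(axis=(2, 3))
    raise ValueError(f"expected (B, C) or (B, C, H, W), got shape {t.shape}")


def gate_entropy(g) -> Tensor:
    """Shannon entropy H(g) = -sum_i g_i log g_i (natural log, 0 log 0 = 0).

    Accepts a single gate vector, a batch ``(B, 3)``, or a Tensor;
    returns per-row entropies (scalar for a single vector).
    """
    if isinstance(g, Tensor):
        logg = g.log(eps=1e-12)
        return -(g * logg).sum(axis=-1)
    arr = np.asarray(g, dtype=float)
    if np.any(arr < -1e-9):
        raise ValueError("gate weights must be nonnegative")
    arr = np.clip(arr, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, arr * np.log(np.where(arr > 0, arr, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def count_gate_parameters(C: int, h: int) -> int:
    """Trainable parameters of the gate MLP: 3*C*h + h + 3*h + 3.

    Both weight matrices (h x 3C and 3 x h) and both bias vectors are
    counted; the published O(3Ch + 3h) figure ignores the biases.
    """
    if C <= 0 or h <= 0:
        raise ValueError("C and h must be positive")
    return 3 * C * h + h + 3 * h + 3


class GateNetwork(Module):
    """Tiny two-layer GELU MLP mapping descriptors to a 3-way softmax gate."""

    def __init__(self, common_dim: int, hidden: int, rng: np.random.Generator,
                 tau: float = 1.0):
        super().__init__()
        if tau <= 0:
            raise ValueError("temperature tau must be positive")
        self.common_dim, self.hidden, self.tau = common_dim, hidden, tau
        self.fc1 = Linear(3 * common_dim, hidden, rng)
        self.fc2 = Linear(hidden, 3, rng)
        # zero-init the output layer: the gate starts exactly uniform and
        # sharpens only as evidence accumulates
        self.fc2.weight.data *= 0.0

    def forward(self, z_d: Tensor, z_g: Tensor, z_t: Tensor,
                tau: float | None = None) -> GateWeights:
        for name, z in (("z_d", z_d), ("z_g", z_g), ("z_t", z_t)):
            if not np.all(np.isfinite(z.data)):
                raise ValueError(f"non-finite descriptor {name}")
        tau = self.tau if tau is None else tau
        if tau <= 0:
            raise ValueError("temperature tau must be positive")
        u = concat([z_d, z_g, z_t], axis=-1)
        s = self.fc2(self.fc1(u).gelu())
        g = (s * (1.0 / tau)).softmax(axis=-1)
        return GateWeights(z_d=z_d, z_g=z_g, z_t=z_t, u=u, s=s, g=g)


def compute_gate(z_d, z_g, z_t, gate: GateNetwork,
                 tau: float | None = None) -> GateWeights:
    """Functional wrapper around :meth:`GateNetwork.forward`."""
    as_t = lambda z: z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
    return gate(as_t(z_d), as_t(z_g), as_t(z_t), tau=tau)


def fuse_gsaf(gate: GateWeights, emb: CommonEmbedding) -> FusedEmbedding:
    """Convex combination Phi = g_d phi_d + g_g phi_g + g_t phi_t."""
    C = emb.width
    for name, phi in (("phi_d", emb.phi_d), ("phi_g", emb.phi_g),
                      ("phi_t", emb.phi_t)):
        if phi.shape[-1] != C:
            raise ValueError(f"{name} width {phi.shape[-1]} != C={C}")
    g = gate.g
    phi = (g[:, 0:1] * emb.phi_d + g[:, 1:2] * emb.phi_g
           + g[:, 2:3] * emb.phi_t)
    return FusedEmbedding(phi=phi, strategy="gsaf")


def project_to_common(detail_map: FeatureMap, global_map: FeatureMap,
                      cls_embedding: Tensor, C: int,
                      seed: int = 0) -> CommonEmbedding:
    """Project branch outputs to width ``C`` (1x1 conv / linear) and pool.

    Thin functional form used in tests and examples; the model class owns
    its own trained projection layers.
    """
    if C <= 0:
        raise ValueError("common width C must be positive")
    rng = np.random.default_rng(seed)
    pd = Conv2d(detail_map.channels, C, 1, rng)
    pg = Conv2d(global_map.channels, C, 1, rng)
    pt = Linear(cls_embedding.shape[-1], C, rng)
    return CommonEmbedding(
        phi_d=global_average_pool(pd(detail_map.activations)),
        phi_g=global_average_pool(pg(global_map.activations)),
        phi_t=pt(cls_embedding),
    )


class AttentionFusion(Module):
    """Score-based attention fusion over a common projection width.

    Each branch vector is linearly projected to ``fusion_dim`` (256 in
    the full model), a small shared MLP scores each projected vector, the
    scores are softmax-normalised into importance weights ``alpha``, and
    the output is ``sum_i alpha_i f_i``.
    """

    def __init__(self, widths: tuple[int, int, int], fusion_dim: int,
                 rng: np.random.Generator, score_hidden: int = 32):
        super().__init__()
        self.fusion_dim = fusion_dim
        self.proj_d = Linear(widths[0], fusion_dim, rng)
        self.proj_g = Linear(widths[1], fusion_dim, rng)
        self.proj_t = Linear(widths[2], fusion_dim, rng)
        self.scorer = Sequential(Linear(fusion_dim, score_hidden, rng), GELU(),
                                 Linear(score_hidden, 1, rng))

    def forward(self, v_d: Tensor, v_g: Tensor, v_t: Tensor):
        f = stack([self.proj_d(v_d), self.proj_g(v_g), self.proj_t(v_t)],
                  axis=1)                                   # (B, 3, F)
        scores = self.scorer(f).reshape(f.shape[0], 3)      # (B, 3)
        alpha = scores.softmax(axis=-1)
        fused = (alpha.reshape(f.shape[0], 3, 1) * f).sum(axis=1)
        return fused, alpha


def attention_fusion(v_d, v_g, v_t, module: AttentionFusion) -> FusedEmbedding:
    as_t = lambda v: v if isinstance(v, Tensor) else Tensor(np.atleast_2d(v))
    fused, _ = module(as_t(v_d), as_t(v_g), as_t(v_t))
    return FusedEmbedding(phi=fused, strategy="attention")


def static_fusion(vectors, mode: str) -> FusedEmbedding:
    """Static (parameter-free) fusion: concatenation or elementwise mean."""
    ts = [v if isinstance(v, Tensor) else Tensor(np.atleast_2d(v))
          for v in vectors]
    if mode == "concat":
        return FusedEmbedding(phi=concat(ts, axis=-1), strategy="static_concat")
    if mode == "average":
        widths = {t.shape[-1] for t in ts}
        if len(widths) > 1:
            raise ValueError(f"average requires equal widths, got {sorted(widths)}")
        out = ts[0]
        for t in ts[1:]:
            out = out + t
        return FusedEmbedding(phi=out * (1.0 / len(ts)),
                              strategy="static_average")
    raise ValueError(f"unknown static fusion mode {mode!r}")


class CrossBranchAttention(Module):
    """Single-head cross-attention between the three pooled branch tokens.

    Optional refinement (off by default): the three C-wide vectors form a
    3-token sequence; each token attends over all three, letting branches
    modulate each other before fusion.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)

    def forward(self, tokens: Tensor) -> Tensor:            # (B, 3, C)
        out = self_attention(self.wq(tokens), self.wk(tokens), self.wv(tokens))
        return tokens + out


# ---------------------------------------------------------------------------
# the full classifier
# ---------------------------------------------------------------------------

class HMCTAFModel(Module):
    """Three-branch leaf-disease classifier with a selectable fusion head.

    Only the submodules a strategy needs are constructed, so trainable
    parameter counts reported per strategy reflect that strategy alone
    (e.g. single-branch variants carry no gate or projections).
    """

    def __init__(self, cfg: BranchConfig, n_classes: int,
                 strategy: str = "gsaf", seed: int = 0, tau: float = 1.0):
        super().__init__()
        if strategy not in FUSION_STRATEGIES:
            raise ValueError(
                f"unknown strategy {strategy!r}; choose from {FUSION_STRATEGIES}"
            )
        self.cfg, self.n_classes, self.strategy = cfg, n_classes, strategy
        rng = np.random.default_rng(seed)
        C, D, G, V = (cfg.common_dim, cfg.detail_channels,
                      cfg.global_channels, cfg.vit_dim)

        need = self._needed_branches(strategy)
        if "d" in need:
            self.detail = DetailBranch(cfg, rng)
        if "g" in need:
            self.global_ = GlobalBranch(cfg, rng)
        if "t" in need:
            self.vit = ViTBranch(cfg, rng)

        if strategy in ("gsaf", "gsaf_no_sparsity", "static_average",
                        "cross_attention"):
            self.proj_d = Conv2d(D, C, 1, rng)
            self.proj_g = Conv2d(G, C, 1, rng)
            self.proj_t = Linear(V, C, rng)
        if strategy in ("gsaf", "gsaf_no_sparsity"):
            self.gate = GateNetwork(C, cfg.gate_hidden, rng, tau=tau)
        if strategy == "attention":
            self.attn_fusion = AttentionFusion((D, G, V), cfg.fusion_dim, rng)
        if strategy == "cross_attention":
            self.cross = CrossBranchAttention(C, rng)

        head_width = {
            "gsaf": C, "gsaf_no_sparsity": C, "static_average": C,
            "cross_attention": C, "attention": cfg.fusion_dim,
            "static_concat": D + G + V, "detail_only": D, "global_only": G,
            "vit_only": V, "cnns_only": D + G,
        }[strategy]
        self.head = Linear(head_width, n_classes, rng)

    @staticmethod
    def _needed_branches(strategy: str) -> str:
        return {"detail_only": "d", "global_only": "g", "vit_only": "t",
                "cnns_only": "dg"}.get(strategy, "dgt")

    # ------------------------------------------------------------------
    def forward(self, x: Tensor):
        """Return ``(logits, gate_weights_or_None)`` for an image tensor."""
        s = self.strategy
        if s == "detail_only":
            return self.head(global_average_pool(self.detail(x))), None
        if s == "global_only":
            return self.head(global_average_pool(self.global_(x))), None
        if s == "vit_only":
            return self.head(self.vit(x)), None
        if s == "cnns_only":
            v = concat([global_average_pool(self.detail(x)),
                        global_average_pool(self.global_(x))], axis=-1)
            return self.head(v), None

        dmap, gmap, cls = self.detail(x), self.global_(x), self.vit(x)
        if s == "static_concat":
            fused = static_fusion([global_average_pool(dmap),
                                   global_average_pool(gmap), cls], "concat")
            return self.head(fused.phi), None
        if s == "attention":
            fused, alpha = self.attn_fusion(global_average_pool(dmap),
                                            global_average_pool(gmap), cls)
            return self.head(fused), None

        emb = CommonEmbedding(
            phi_d=global_average_pool(self.proj_d(dmap.activations)),
            phi_g=global_average_pool(self.proj_g(gmap.activations)),
            phi_t=self.proj_t(cls),
        )
        if s == "static_average":
            fused = static_fusion([emb.phi_d, emb.phi_g, emb.phi_t], "average")
            return self.head(fused.phi), None
        if s == "cross_attention":
            tokens = stack([emb.phi_d, emb.phi_g, emb.phi_t], axis=1)
            return self.head(self.cross(tokens).mean(axis=1)), None
        # gsaf / gsaf_no_sparsity
        gate = self.gate(emb.phi_d, emb.phi_g, emb.phi_t)
        fused = fuse_gsaf(gate, emb)
        return self.head(fused.phi), gate
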
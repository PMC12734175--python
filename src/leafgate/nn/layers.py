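"""Neural-network layers built on the autograd engine.

Layers follow the usual conventions: ``(batch, channels, height, width)``
for convolutional feature maps and ``(batch, tokens, width)`` for token
sequences. Parameters are float32; initialisation draws from an
explicitly passed :class:`numpy.random.Generator` so that model builds
are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "MaxPool2d",
    "AvgPool2d",
    "BatchNorm2d",
    "LayerNorm",
    "ReLU",
    "GELU",
]


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- checkpointing --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, buf in self._buffers().items():
            state[n] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = self._buffers()
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {value.shape}"
                    )
                params[name].data = value.astype(params[name].data.dtype).copy()
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for mn, m in self._modules.items():
            out.update(m._buffers(prefix + mn + "."))
        if isinstance(self, BatchNorm2d):
            out[prefix + "running_mean"] = self.running_mean
            out[prefix + "running_var"] = self.running_var
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(_kaiming(rng, (out_features, in_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x.matmul(self.weight.transpose(1, 0))
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """2-D convolution (cross-correlation) with stride, padding, dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        k = kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.kernel_size = k
        self.weight = Tensor(
            _kaiming(rng, (out_channels, in_channels, k, k), in_channels * k * k),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        s, p, d = self.stride, self.padding, self.dilation
        k = self.kernel_size
        xd = x.data
        B, C, H, W = xd.shape
        span = d * (k - 1) + 1
        oh = (H + 2 * p - span) // s + 1
        ow = (W + 2 * p - span) // s + 1
        if oh <= 0 or ow <= 0:
            raise ValueError(f"input {H}x{W} too small for kernel span {span}")
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
        # im2col: one contiguous copy, then a single batched GEMM
        sb, sc, sh, sw = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, shape=(B, C, k, k, oh, ow),
            strides=(sb, sc, sh * d, sw * d, sh * s, sw * s))
        cols = np.ascontiguousarray(view).reshape(B, C * k * k, oh * ow)
        wf = w.data.reshape(-1, C * k * k)
        out_data = np.matmul(wf, cols).reshape(B, -1, oh, ow)
        if b is not None:
            out_data += b.data[None, :, None, None]
        req = x.requires_grad or w.requires_grad
        parents = (x, w) if b is None else (x, w, b)
        out = Tensor(out_data, requires_grad=req, parents=parents)

        def _backward(g: np.ndarray) -> None:
            gf = g.reshape(B, -1, oh * ow)
            if b is not None:
                b.accumulate(g.sum(axis=(0, 2, 3)))
            gw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            w.accumulate(gw.reshape(w.data.shape))
            if not x.requires_grad:
                return
            dcols = np.matmul(wf.T, gf).reshape(B, C, k, k, oh, ow)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i * d: i * d + (oh - 1) * s + 1: s,
                        j * d: j * d + (ow - 1) * s + 1: s] += dcols[:, :, i, j]
            x.accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        out._backward = _backward if req else None
        return out


class MaxPool2d(Module):
    """Non-overlapping max pooling (kernel = stride)."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.k = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        k = self.k
        B, C, H, W = x.shape
        if H % k:
            raise ValueError(f"height {H} not divisible by pool size {k}")
        if W % k:
            raise ValueError(f"width {W} not divisible by pool size {k}")
        xr = x.data.reshape(B, C, H // k, k, W // k, k)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // k, W // k, k * k)
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        out = Tensor(out_data, requires_grad=x.requires_grad, parents=(x,))

        def _backward(g: np.ndarray) -> None:
            gr = np.zeros((B, C, H // k, W // k, k * k), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(B, C, H // k, W // k, k, k).transpose(0, 1, 2, 4, 3, 5)
            x.accumulate(gr.reshape(B, C, H, W))

        out._backward = _backward if x.requires_grad else None
        return out


class AvgPool2d(Module):
    """Non-overlapping average pooling (kernel = stride)."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.k = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        k = self.k
        B, C, H, W = x.shape
        if H % k:
            raise ValueError(f"height {H} not divisible by pool size {k}")
        if W % k:
            raise ValueError(f"width {W} not divisible by pool size {k}")
        out_data = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))
        out = Tensor(out_data, requires_grad=x.requires_grad, parents=(x,))

        def _backward(g: np.ndarray) -> None:
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x.accumulate(gx)

        out._backward = _backward if x.requires_grad else None
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        if self.training:
            mean = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (xd - mean[None, :, None, None]) / std[None, :, None, None]
        out_data = self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]
        gamma, beta = self.gamma, self.beta
        req = x.requires_grad or gamma.requires_grad
        out = Tensor(out_data, requires_grad=req, parents=(x, gamma, beta))
        training = self.training

        def _backward(g: np.ndarray) -> None:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta.accumulate(g.sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            gs = gamma.data[None, :, None, None] / std[None, :, None, None]
            if not training:
                x.accumulate(g * gs)
                return
            n = g.shape[0] * g.shape[2] * g.shape[3]
            gmean = g.mean(axis=(0, 2, 3), keepdims=True)
            gxhat_mean = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x.accumulate(gs * (g - gmean - xhat * gxhat_mean))
            del n

        out._backward = _backward if req else None
        return out


class LayerNorm(Module):
    """Normalisation over the last axis with learned affine parameters."""

    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(width, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(width, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        mean = xd.mean(axis=-1, keepdims=True)
        var = xd.var(axis=-1, keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (xd - mean) / std
        out_data = self.gamma.data * xhat + self.beta.data
        gamma, beta = self.gamma, self.beta
        req = x.requires_grad or gamma.requires_grad
        out = Tensor(out_data, requires_grad=req, parents=(x, gamma, beta))

        def _backward(g: np.ndarray) -> None:
            gamma.accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            beta.accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
            if not x.requires_grad:
                return
            gx = g * gamma.data
            gmean = gx.mean(axis=-1, keepdims=True)
            gxhat_mean = (gx * xhat).mean(axis=-1, keepdims=True)
            x.accumulate((gx - gmean - xhat * gxhat_mean) / std)

        out._backward = _backward if req else None
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()
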
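"""Neural-network layers (3D convolutions, normalization, attention plumbing).

Convolutions are implemented as an accumulation over kernel offsets — each
offset is a single einsum over a shifted view — which keeps peak memory small
for dilated kernels on 3D volumes and supports grouped and dilated variants
with one code path.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import DTYPE, Tensor, _attach

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential", "Linear", "Bilinear",
    "Conv3d", "ConvTranspose3d", "BatchNorm3d", "LayerNorm", "Dropout",
    "LeakyReLU", "avg_pool3d", "max_pool3d",
]


class Parameter(Tensor):
    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if key.startswith("running_") and isinstance(val, np.ndarray):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(params) | set(bufs)) - set(state)
        if missing:
            raise ValueError(f"missing tensors in state dict: {sorted(missing)}")
        mismatched = [
            name for name in params
            if tuple(state[name].shape) != tuple(params[name].shape)
        ]
        if mismatched:
            raise ValueError(f"shape mismatch for tensors: {sorted(mismatched)}")
        for name, p in params.items():
            p.data = state[name].astype(DTYPE, copy=True)
        for name, b in bufs.items():
            b[...] = state[name]


class ModuleList(Module):
    def __init__(self, modules):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class Bilinear(Module):
    """out_k = a^T W_k b + bias_k with W of shape (out, in1, in2)."""

    def __init__(self, in1: int, in2: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (out_features, in1, in2), in1 * in2))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        W = self.weight
        out = Tensor(np.einsum("ni,kij,nj->nk", a.data, W.data, b.data))

        def bw(g):
            ga = np.einsum("nk,kij,nj->ni", g, W.data, b.data)
            gb = np.einsum("nk,kij,ni->nj", g, W.data, a.data)
            gw = np.einsum("nk,ni,nj->kij", g, a.data, b.data)
            return ga, gb, gw

        _attach(out, (a, b, W), bw)
        return out + self.bias


class Conv3d(Module):
    """3D convolution, stride 1, same padding, optional dilation and groups."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size ** 3
        self.weight = Parameter(_kaiming(
            rng, (out_channels, in_channels // groups) + (kernel_size,) * 3, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    @staticmethod
    def _im2col(data: np.ndarray, k: int, dil: int, groups: int) -> np.ndarray:
        """(N, C, D, H, W) -> (N, groups, (C/groups)*k^3, D*H*W) patch matrix.

        The row layout is channel-major then kernel-offset, matching a plain
        reshape of the weight tensor, so every GEMM below runs on views.
        """
        pad = dil * (k - 1) // 2
        N, C, D, H, W = data.shape
        xp = np.pad(data, [(0, 0), (0, 0)] + [(pad, pad)] * 3)
        s = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp,
            shape=(N, C, k, k, k, D, H, W),
            strides=(s[0], s[1], s[2] * dil, s[3] * dil, s[4] * dil,
                     s[2], s[3], s[4]),
            writeable=False)
        return view.reshape(N, groups, (C // groups) * k ** 3, D * H * W)

    def _offsets(self, shape: tuple[int, int, int]):
        """Kernel offsets with a nonempty valid region, as (t, out_lo, out_hi).

        For offset s = dil * (t - center), output voxels p with p + s inside
        the volume receive w[t] * x[p + s]; everything else is zero padding.
        """
        k, dil = self.kernel_size, self.dilation
        ctr = (k - 1) // 2
        per_axis = []
        for ax in range(3):
            n = shape[ax]
            entries = []
            for t in range(k):
                s = dil * (t - ctr)
                lo, hi = max(0, -s), min(n, n - s)
                if lo < hi:
                    entries.append((t, s, lo, hi))
            per_axis.append(entries)
        return per_axis

    def forward(self, x: Tensor) -> Tensor:
        k, dil, g = self.kernel_size, self.dilation, self.groups
        N, C, D, H, Wd = x.shape
        co = self.out_channels
        cg, og = C // g, co // g
        w = self.weight
        extent = dil * (k - 1) + 1
        # When the padded halo dominates the volume (or the patch matrix
        # would be huge), accumulate over kernel offsets on valid overlaps
        # only; otherwise one big im2col GEMM wins.
        use_offsets = k > 1 and 2 * extent > min(D, H, Wd)
        if use_offsets:
            return self._forward_offsets(x)
        X = D * H * Wd
        k3 = k ** 3
        patches = self._im2col(x.data, k, dil, g)  # (N, g, cg*k3, X)
        wg = w.data.reshape(g, og, cg * k3)
        out = np.matmul(wg, patches)  # -> (N, g, og, X), contiguous
        res = Tensor(out.reshape(N, co, D, H, Wd))

        def bw(gout):
            gr = gout.reshape(N, g, og, X)
            # weight gradient: batched GEMM against the recomputed patch
            # matrix (recomputation keeps forward memory flat)
            patches2 = self._im2col(x.data, k, dil, g)
            gw = np.matmul(gr, patches2.swapaxes(2, 3)).sum(axis=0)
            gw = gw.reshape(w.shape)
            # input gradient: same-padded dilated correlation of the output
            # gradient with the spatially flipped, channel-transposed kernel
            wf = w.data.reshape(g, og, cg, k, k, k)[..., ::-1, ::-1, ::-1]
            wf = np.ascontiguousarray(
                wf.reshape(g, og, cg, k3).transpose(0, 2, 1, 3)
            ).reshape(g, cg, og * k3)
            gpatches = self._im2col(np.ascontiguousarray(gout), k, dil, g)
            gx = np.matmul(wf, gpatches)  # (N, g, cg, X)
            return gx.reshape(N, C, D, H, Wd), gw

        _attach(res, (x, w), bw)
        if self.bias is not None:
            res = res + self.bias.reshape(1, co, 1, 1, 1)
        return res

    def _forward_offsets(self, x: Tensor) -> Tensor:
        g = self.groups
        N, C, D, H, Wd = x.shape
        co = self.out_channels
        cg, og = C // g, co // g
        w = self.weight
        per_axis = self._offsets((D, H, Wd))
        wg = w.data.reshape(g, og, cg, self.kernel_size ** 3)
        xg = x.data.reshape(N, g, cg, D, H, Wd)
        k = self.kernel_size
        out = np.zeros((N, g, og, D, H, Wd), dtype=DTYPE)
        for (ti, sd, d0, d1) in per_axis[0]:
            for (tj, sh, h0, h1) in per_axis[1]:
                for (tl, sw, w0, w1) in per_axis[2]:
                    t = (ti * k + tj) * k + tl
                    xs = xg[:, :, :, d0 + sd:d1 + sd, h0 + sh:h1 + sh,
                            w0 + sw:w1 + sw]
                    shp = xs.shape
                    r = np.matmul(wg[:, :, :, t], xs.reshape(N, g, cg, -1))
                    out[:, :, :, d0:d1, h0:h1, w0:w1] += r.reshape(
                        (N, g, og) + shp[3:])
        res = Tensor(out.reshape(N, co, D, H, Wd))

        def bw(gout):
            gr = gout.reshape(N, g, og, D, H, Wd)
            gw = np.zeros_like(wg)
            gx = np.zeros((N, g, cg, D, H, Wd), dtype=DTYPE)
            for (ti, sd, d0, d1) in per_axis[0]:
                for (tj, sh, h0, h1) in per_axis[1]:
                    for (tl, sw, w0, w1) in per_axis[2]:
                        t = (ti * k + tj) * k + tl
                        gs = gr[:, :, :, d0:d1, h0:h1, w0:w1]
                        shp = gs.shape
                        gflat = np.ascontiguousarray(gs).reshape(N, g, og, -1)
                        xs = xg[:, :, :, d0 + sd:d1 + sd, h0 + sh:h1 + sh,
                                w0 + sw:w1 + sw]
                        xflat = np.ascontiguousarray(xs).reshape(N, g, cg, -1)
                        gw[:, :, :, t] += np.einsum(
                            "ngov,ngcv->goc", gflat, xflat)
                        gxs = np.matmul(wg[:, :, :, t].swapaxes(1, 2), gflat)
                        gx[:, :, :, d0 + sd:d1 + sd, h0 + sh:h1 + sh,
                           w0 + sw:w1 + sw] += gxs.reshape(
                            (N, g, cg) + shp[3:])
            return gx.reshape(N, C, D, H, Wd), gw.reshape(w.shape)

        _attach(res, (x, w), bw)
        if self.bias is not None:
            res = res + self.bias.reshape(1, co, 1, 1, 1)
        return res


class ConvTranspose3d(Module):
    """Transposed conv with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 8
        self.weight = Parameter(_kaiming(
            rng, (in_channels, out_channels, 2, 2, 2), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        N, C, D, H, Wd = x.shape
        co = self.out_channels
        w = self.weight
        out = np.einsum("ncdhw,coijl->nodihjwl", x.data, w.data, optimize=True)
        out = out.reshape(N, co, 2 * D, 2 * H, 2 * Wd)
        res = Tensor(out)

        def bw(g):
            gr = g.reshape(N, co, D, 2, H, 2, Wd, 2)
            gx = np.einsum("nodihjwl,coijl->ncdhw", gr, w.data, optimize=True)
            gw = np.einsum("nodihjwl,ncdhw->coijl", gr, x.data, optimize=True)
            return gx, gw

        _attach(res, (x, w), bw)
        return res + self.bias.reshape(1, co, 1, 1, 1)


class BatchNorm3d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c) + (1,) * (x.ndim - 2)
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(c) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(c) - self.running_var)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight + self.bias


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


def _pool_view(x: Tensor):
    N, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"pooling requires even spatial dims, got {(D, H, W)}")
    return x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2), (N, C, D, H, W)


def avg_pool3d(x: Tensor) -> Tensor:
    """Window-2/stride-2 average pooling."""
    r, (N, C, D, H, W) = _pool_view(x)
    out = Tensor(r.mean(axis=(3, 5, 7)))

    def bw(g):
        ge = g[:, :, :, None, :, None, :, None] / 8.0
        return (np.broadcast_to(ge, r.shape).reshape(N, C, D, H, W).astype(DTYPE),)

    _attach(out, (x,), bw)
    return out


def max_pool3d(x: Tensor) -> Tensor:
    """Window-2/stride-2 max pooling; gradient split evenly among ties."""
    r, (N, C, D, H, W) = _pool_view(x)
    m = r.max(axis=(3, 5, 7))
    out = Tensor(m)

    def bw(g):
        mask = (r == m[:, :, :, None, :, None, :, None]).astype(DTYPE)
        mask /= mask.sum(axis=(3, 5, 7), keepdims=True)
        ge = g[:, :, :, None, :, None, :, None] * mask
        return (ge.reshape(N, C, D, H, W),)

    _attach(out, (x,), bw)
    return out
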
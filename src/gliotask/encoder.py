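"""Customized 3D transformer encoder with multi-view adapter fine-tuning.

A plain ViT-style 3D backbone (patch embedding + transformer blocks) stands in
for a pretrained medical segmentation encoder. Three customizations adapt it
to 5-channel multimodal input and two classification tasks:

1. **Patch-embed expansion** — a single-channel patch-embedding kernel is
   replicated across 5 input channels and scaled by 1/5, so an input whose 5
   channels are identical reproduces the original single-channel response.
2. **Multi-view adapter** — image tokens are globally pooled and reduced to
   an ``embed_dim/8`` bottleneck, the 101 tabular (radiomic + clinical)
   features are reduced to the same width, and a bilinear layer produces
   per-channel sigmoid gates applied to a width-preserving linear transform
   of the tokens.
3. **Deep fusion branch** — the gated token grid passes through three
   parallel dilated grouped-convolution branches (kernels 3/5/7, dilation 3),
   is summed, normalized and projected pointwise to the QKV width
   (``3 * embed_dim``), and added to each block's query/key/value tensor.

At the reference scale (128^3 input, patch 16, embed 384) the token grid is
(8, 8, 8) x 384 and the adapter bottleneck is 48 wide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 5
    input_size: int = 128
    patch_size: int = 16
    embed_dim: int = 384
    n_blocks: int = 4
    n_heads: int = 6
    adapter_reduction: int = 8
    tabular_dim: int = 101
    mlp_ratio: int = 4
    freeze_backbone: bool = True
    qkv_dim: int | None = None  # None => 3 * embed_dim

    def __post_init__(self):
        if self.input_size % self.patch_size:
            raise ValueError(
                f"input_size {self.input_size} not divisible by patch_size "
                f"{self.patch_size}")
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}")
        if self.embed_dim % self.adapter_reduction:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by adapter_reduction "
                f"{self.adapter_reduction}")
        if self.embed_dim % (self.embed_dim // self.adapter_reduction):
            raise ValueError("embed_dim must be divisible by its group count")

    @property
    def grid(self) -> int:
        return self.input_size // self.patch_size

    @property
    def n_tokens(self) -> int:
        return self.grid ** 3

    @property
    def adapter_hidden(self) -> int:
        return self.embed_dim // self.adapter_reduction

    @property
    def resolved_qkv_dim(self) -> int:
        return self.qkv_dim if self.qkv_dim is not None else 3 * self.embed_dim


def expand_patch_embed(base_weights: np.ndarray, n_channels: int = 5) -> np.ndarray:
    """Replicate a 1-input-channel patch-embed kernel across ``n_channels``.

    The copy is scaled by ``1/n_channels`` so that an input whose channels are
    all equal to v reproduces the original single-channel response on v.
    """
    if base_weights.ndim != 5 or base_weights.shape[1] != 1:
        raise ValueError(
            f"expected a single-input-channel kernel (out, 1, k, k, k), "
            f"got shape {base_weights.shape}")
    return np.repeat(base_weights, n_channels, axis=1) / float(n_channels)


class PatchEmbed(nn.Module):
    """Non-overlapping strided convolution producing a token grid."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        c, p, e = cfg.in_channels, cfg.patch_size, cfg.embed_dim
        fan_in = c * p ** 3
        bound = np.sqrt(1.0 / fan_in)
        self.patch_size = p
        self.weight = nn.Parameter(
            rng.uniform(-bound, bound, size=(e, c, p, p, p)).astype(nn.DTYPE))
        self.bias = nn.Parameter(np.zeros(e, dtype=nn.DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, D, H, W) -> (N, T, E) tokens in row-major grid order."""
        N, C, D, H, W = x.shape
        p = self.patch_size
        if D % p or H % p or W % p:
            raise ValueError(f"spatial dims {(D, H, W)} not divisible by patch {p}")
        g = D // p
        w = self.weight
        xr = x.data.reshape(N, C, g, p, g, p, g, p)
        out = np.einsum("nmaibjck,emijk->nabce", xr, w.data, optimize=True)
        res = Tensor(out.reshape(N, g ** 3, -1))

        def bw(gout):
            gr = gout.reshape(N, g, g, g, -1)
            gx = np.einsum("nabce,emijk->nmaibjck", gr, w.data, optimize=True)
            gw = np.einsum("nabce,nmaibjck->emijk", gr, xr, optimize=True)
            return gx.reshape(N, C, D, H, W), gw

        nn.tensor._attach(res, (x, w), bw)
        return res + self.bias


class MVAdapter(nn.Module):
    """Bilinear multi-view gating of image tokens by pooled image + tabular features."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        e, h = cfg.embed_dim, cfg.adapter_hidden
        self.tabular_dim = cfg.tabular_dim
        self.fc_img = nn.Linear(e, h, rng)
        self.fc_tab = nn.Linear(cfg.tabular_dim, h, rng)
        self.bilinear = nn.Bilinear(h, h, e, rng)
        self.fc_tokens = nn.Linear(e, e, rng)

    def gate(self, tokens: Tensor, tabular: Tensor) -> Tensor:
        if tabular.shape[-1] != self.tabular_dim:
            raise ValueError(
                f"tabular width {tabular.shape[-1]} != configured "
                f"{self.tabular_dim}")
        pooled = tokens.mean(axis=1)  # GAP over the spatial grid
        a = self.fc_img(pooled)
        b = self.fc_tab(tabular)
        return self.bilinear(a, b).sigmoid()

    def forward(self, tokens: Tensor, tabular: Tensor) -> Tensor:
        g = self.gate(tokens, tabular)
        n, e = g.shape
        return g.reshape(n, 1, e) * self.fc_tokens(tokens)


class DGCB(nn.Module):
    """Multi-scale dilated grouped convolutions producing QKV-width features."""

    KERNELS = (7, 5, 3)

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        e = cfg.embed_dim
        groups = e // 8
        self.grid = cfg.grid
        self.dilated = nn.ModuleList([
            nn.Conv3d(e, e, k, rng, dilation=3, groups=groups)
            for k in self.KERNELS])
        self.grouped = nn.ModuleList([
            nn.Conv3d(e, e, k, rng, groups=groups) for k in self.KERNELS])
        self.bn = nn.BatchNorm3d(e)
        self.pointwise = nn.Conv3d(e, cfg.resolved_qkv_dim, 1, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        """(N, T, E) gated tokens -> (N, T, qkv_dim) fused features."""
        n, t, e = tokens.shape
        g = self.grid
        x = tokens.transpose(0, 2, 1).reshape(n, e, g, g, g)
        acc = None
        for dil, grp in zip(self.dilated, self.grouped):
            branch = grp(dil(x).leaky_relu())
            acc = branch if acc is None else acc + branch
        fused = self.pointwise(self.bn(acc).leaky_relu())
        return fused.reshape(n, -1, t).transpose(0, 2, 1)


def inject_qkv(x_fusion: Tensor, x_qkv: Tensor) -> Tensor:
    """Additive injection of fused features into a block's QKV tensor."""
    if x_fusion.shape != x_qkv.shape:
        raise ValueError(
            f"fusion/QKV shape mismatch: {x_fusion.shape} vs {x_qkv.shape}")
    return x_qkv + x_fusion


class TransformerBlock(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        e = cfg.embed_dim
        self.n_heads = cfg.n_heads
        self.head_dim = e // cfg.n_heads
        self.ln1 = nn.LayerNorm(e)
        self.qkv = nn.Linear(e, 3 * e, rng)
        self.proj = nn.Linear(e, e, rng)
        self.ln2 = nn.LayerNorm(e)
        self.mlp_in = nn.Linear(e, cfg.mlp_ratio * e, rng)
        self.mlp_out = nn.Linear(cfg.mlp_ratio * e, e, rng)
        self.adapter = MVAdapter(cfg, rng)
        self.dgcb = DGCB(cfg, rng)

    def backbone_params(self) -> list[nn.Parameter]:
        mods = [self.ln1, self.qkv, self.proj, self.ln2, self.mlp_in, self.mlp_out]
        return [p for m in mods for p in m.parameters()]

    def adapter_params(self) -> list[nn.Parameter]:
        return self.adapter.parameters() + self.dgcb.parameters()

    def forward(self, x: Tensor, tabular: Tensor | None,
                use_adapter: bool = True) -> Tensor:
        n, t, e = x.shape
        qkv = self.qkv(self.ln1(x))
        if use_adapter and tabular is not None:
            x_fmw = self.adapter(x, tabular)
            x_fusion = self.dgcb(x_fmw)
            qkv = inject_qkv(x_fusion, qkv)
        h, d = self.n_heads, self.head_dim
        qkv = qkv.reshape(n, t, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, e)
        x = x + self.proj(out)
        return x + self.mlp_out(self.mlp_in(self.ln2(x)).gelu())


class Encoder(nn.Module):
    """Patch embedding + positional embedding + adapter-injected blocks + GAP."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.patch_embed = PatchEmbed(cfg, rng)
        self.pos_embed = nn.Parameter(
            (0.02 * rng.standard_normal((1, cfg.n_tokens, cfg.embed_dim)))
            .astype(nn.DTYPE))
        self.blocks = nn.ModuleList(
            [TransformerBlock(cfg, rng) for _ in range(cfg.n_blocks)])
        self.ln_final = nn.LayerNorm(cfg.embed_dim)
        if cfg.freeze_backbone:
            self.freeze_backbone()

    # -- freezing -----------------------------------------------------------
    def freeze_backbone(self) -> None:
        """Train only the patch embedding, adapters and (externally) heads."""
        for blk in self.blocks:
            for p in blk.backbone_params():
                p.requires_grad = False
        self.pos_embed.requires_grad = False
        for p in self.ln_final.parameters():
            p.requires_grad = False

    def unfreeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = True

    def zero_adapters(self) -> None:
        for blk in self.blocks:
            for p in blk.adapter_params():
                p.data[...] = 0.0

    # -- forward ------------------------------------------------------------
    def tokens(self, x: Tensor, tabular: Tensor | None,
               use_adapters: bool = True,
               capture: list[Tensor] | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if tabular is not None and not isinstance(tabular, Tensor):
            tabular = Tensor(tabular)
        t = self.patch_embed(x) + self.pos_embed
        if capture is not None:
            t.requires_grad = t.retain_grad = True
            capture.append(t)
        for blk in self.blocks:
            t = blk(t, tabular, use_adapter=use_adapters)
            if capture is not None:
                t.requires_grad = t.retain_grad = True
                capture.append(t)
        return self.ln_final(t)

    def forward(self, x: Tensor, tabular: Tensor | None = None,
                use_adapters: bool = True,
                capture: list[Tensor] | None = None) -> Tensor:
        """(N, C, D, H, W) volume + (N, 101) tabular -> (N, embed_dim) features."""
        return self.tokens(x, tabular, use_adapters, capture).mean(axis=1)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: nn.Module, path, config: dict | None = None) -> None:
    """Flat named-tensor archive (.npz) with a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    if config is not None:
        Path(str(path) + ".json").write_text(json.dumps(config, indent=2))


def load_checkpoint(model: nn.Module, path) -> None:
    with np.load(Path(path), allow_pickle=False) as archive:
        state = {k: archive[k] for k in archive.files}
    model.load_state_dict(state)


def load_pretrained(path, cfg: EncoderConfig,
                    rng: np.random.Generator | None = None) -> Encoder:
    """Build an encoder from a backbone checkpoint, expanding a single-channel
    patch embedding fivefold when needed. A missing path is an error; random
    initialization is the documented default when no checkpoint is used."""
    model = Encoder(cfg, rng=rng)
    with np.load(Path(path), allow_pickle=False) as archive:
        state = {k: archive[k] for k in archive.files}
    pe_key = "patch_embed.weight"
    if pe_key in state and state[pe_key].shape[1] == 1 and cfg.in_channels > 1:
        state[pe_key] = expand_patch_embed(state[pe_key], cfg.in_channels)
    own = model.state_dict()
    mismatched = [
        k for k in state
        if k in own and tuple(state[k].shape) != tuple(own[k].shape)
    ]
    if mismatched:
        raise ValueError(
            f"checkpoint does not match configured architecture; offending "
            f"tensors: {sorted(mismatched)}")
    merged = dict(own)
    merged.update({k: v for k, v in state.items() if k in own})
    model.load_state_dict(merged)
    return model
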
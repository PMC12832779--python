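"""T2-FLAIR mismatch feature extraction.

The block first takes an "overview" of each modality: average- and max-pooled
copies are concatenated at half resolution and passed through a chain of
multi-scale dilated blocks (kernel 7 -> 5 -> 3, dilation 3) whose weights are
shared between the T2 and FLAIR branches. A transposed convolution restores
full resolution and a sigmoid yields a per-voxel weight map in (0, 1). The
mismatch map is the difference of the weighted modalities:

    x_tf = w(t2) * t2 - w(flair) * flair

Because the weight function is shared, identical inputs cancel exactly and
swapping the inputs negates the output. ``bypass=True`` short-circuits the
weighting (all-ones maps), reproducing plain T2 - FLAIR subtraction — the
"no mismatch block" ablation as a code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class DBConfig:
    """Dilated-block hyperparameters."""

    kernel_size: int
    dilation: int = 3
    width: int = 8
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {self.dilation}")


def pool_concat(volume: Tensor) -> Tensor:
    """Concatenate average- and max-pooled copies at half resolution.

    Input is (N, 1, D, H, W) with even spatial dims; output (N, 2, D/2, H/2,
    W/2) with channel 0 average-pooled and channel 1 max-pooled.
    """
    if not isinstance(volume, Tensor):
        volume = Tensor(volume)
    if volume.ndim != 5 or volume.shape[1] != 1:
        raise ValueError(f"expected (N, 1, D, H, W) input, got {volume.shape}")
    if any(s % 2 for s in volume.shape[2:]):
        raise ValueError(
            f"pooling requires even spatial dims, got {volume.shape[2:]}; pad first")
    return nn.concatenate(
        [nn.avg_pool3d(volume), nn.max_pool3d(volume)], axis=1)


class DilatedBlock(nn.Module):
    """dilated conv -> LeakyReLU -> BatchNorm -> conv -> LeakyReLU -> dropout
    -> conv -> FFN (two pointwise convs with a LeakyReLU between)."""

    def __init__(self, in_channels: int, cfg: DBConfig, rng: np.random.Generator):
        super().__init__()
        k, w = cfg.kernel_size, cfg.width
        self.cfg = cfg
        self.conv_dilated = nn.Conv3d(in_channels, w, k, rng, dilation=cfg.dilation)
        self.bn = nn.BatchNorm3d(w)
        self.conv1 = nn.Conv3d(w, w, k, rng)
        self.dropout = nn.Dropout(cfg.dropout_rate, rng)
        self.conv2 = nn.Conv3d(w, w, k, rng)
        # FFN with x2 hidden expansion (expansion factor is a free choice)
        self.ffn_in = nn.Conv3d(w, 2 * w, 1, rng)
        self.ffn_out = nn.Conv3d(2 * w, w, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(self.conv_dilated(x).leaky_relu())
        x = self.dropout(self.conv1(x).leaky_relu())
        x = self.conv2(x)
        return self.ffn_out(self.ffn_in(x).leaky_relu())


class MismatchExtractor(nn.Module):
    """Shared-weight mismatch block: one weight network serves both branches."""

    def __init__(self, width: int = 8, dropout_rate: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.width = width
        self.db7 = DilatedBlock(2, DBConfig(7, width=width, dropout_rate=dropout_rate), rng)
        self.db5 = DilatedBlock(width, DBConfig(5, width=width, dropout_rate=dropout_rate), rng)
        self.db3 = DilatedBlock(width, DBConfig(3, width=width, dropout_rate=dropout_rate), rng)
        self.upsample = nn.ConvTranspose3d(width, 1, rng)

    def compute_weight_map(self, pooled: Tensor, bypass: bool = False,
                           full_shape: tuple[int, ...] | None = None) -> Tensor:
        """Map a pooled 2-channel half-resolution pair to a (0,1) weight map."""
        if bypass:
            if full_shape is None:
                n, _, d, h, w = pooled.shape
                full_shape = (n, 1, 2 * d, 2 * h, 2 * w)
            return Tensor(np.ones(full_shape, dtype=nn.DTYPE))
        x = self.db3(self.db5(self.db7(pooled)))
        return self.upsample(x).sigmoid()

    def forward(self, t2: Tensor, flair: Tensor, bypass: bool = False) -> Tensor:
        if not isinstance(t2, Tensor):
            t2 = Tensor(t2)
        if not isinstance(flair, Tensor):
            flair = Tensor(flair)
        if t2.shape != flair.shape:
            raise ValueError(
                f"T2/FLAIR shape mismatch: {t2.shape} vs {flair.shape}")
        if bypass:
            return t2 - flair
        n = t2.shape[0]
        # one pass through the shared weight network for both branches
        pooled = nn.concatenate([pool_concat(t2), pool_concat(flair)], axis=0)
        weights = self.compute_weight_map(pooled)
        return weights[:n] * t2 - weights[n:] * flair
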
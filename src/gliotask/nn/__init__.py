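def _tune_allocator() -> None:
    """Keep glibc from mmap-ing/returning large numpy temporaries.

    The training loop allocates and frees many multi-MB scratch arrays; with
    default thresholds each one is a fresh mmap whose pages must be faulted
    and zeroed, which dominates runtime on slow-memory hosts. Raising the
    mmap/trim thresholds lets the heap reuse those blocks.
    """
    import ctypes
    import ctypes.util

    try:
        libc = ctypes.CDLL(ctypes.util.find_library("c") or "libc.so.6")
        M_TRIM_THRESHOLD, M_MMAP_THRESHOLD = -1, -3
        libc.mallopt(M_MMAP_THRESHOLD, 1 << 30)
        libc.mallopt(M_TRIM_THRESHOLD, 1 << 30)
    except Exception:  # non-glibc platforms: harmless no-op
        pass


_tune_allocator()

from .tensor import Tensor, concatenate, stack, pad3d, no_grad, DTYPE
from .layers import (
    Parameter, Module, ModuleList, Sequential, Linear, Bilinear, Conv3d,
    ConvTranspose3d, BatchNorm3d, LayerNorm, Dropout, LeakyReLU,
    avg_pool3d, max_pool3d,
)
from .optim import Adam, RAdam, Ranger, cosine_lr

__all__ = [
    "Tensor", "concatenate", "stack", "pad3d", "no_grad", "DTYPE",
    "Parameter", "Module", "ModuleList", "Sequential", "Linear", "Bilinear",
    "Conv3d", "ConvTranspose3d", "BatchNorm3d", "LayerNorm", "Dropout",
    "LeakyReLU", "avg_pool3d", "max_pool3d",
    "Adam", "RAdam", "Ranger", "cosine_lr",
]
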
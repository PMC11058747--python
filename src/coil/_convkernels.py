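"""JIT-compiled gather/scatter kernels for the 3x3 convolution layers.

im2col collects the 3x3 neighborhood of every pixel of a zero-padded
channels-last tensor into a (B*H*W, 9*C) matrix so the convolution becomes
one GEMM; col2im is its exact adjoint (scatter-add).  Written as explicit
loops and compiled with numba because these gathers dominate the CPU cost
of denoiser training if done with strided numpy copies.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(fastmath=True, cache=True)
def _im2col_kernel(xp, out, h, w, c):  # pragma: no cover - compiled
    b_ = xp.shape[0]
    for b in range(b_):
        for i in range(h):
            for j in range(w):
                idx = 0
                for dy in range(3):
                    for dx in range(3):
                        for ch in range(c):
                            out[b, i, j, idx] = xp[b, i + dy, j + dx, ch]
                            idx += 1


@nb.njit(fastmath=True, cache=True)
def _col2im_kernel(g, gx_pad, h, w, c):  # pragma: no cover - compiled
    b_ = g.shape[0]
    for b in range(b_):
        for i in range(h):
            for j in range(w):
                idx = 0
                for dy in range(3):
                    for dx in range(3):
                        for ch in range(c):
                            gx_pad[b, i + dy, j + dx, ch] += g[b, i, j, idx]
                            idx += 1


class BufferPool:
    """Reusable work arrays keyed by (tag, shape, dtype).

    Fresh multi-megabyte allocations per conv call dominate runtime through
    page faults; reusing the buffers across iterations removes that cost.
    Buffers are owned by one layer, so aliasing is controlled by the caller.
    """

    def __init__(self):
        self._store: dict = {}

    def get(self, tag: str, shape: tuple, dtype, zero: bool = False) -> np.ndarray:
        key = (tag, shape, np.dtype(dtype))
        buf = self._store.get(key)
        if buf is None:
            buf = np.zeros(shape, dtype=dtype)
            self._store[key] = buf
        elif zero:
            buf[...] = 0
        return buf


def im2col(x: np.ndarray, pool: BufferPool, tag: str = "cols") -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, 9*C) patch matrix with zero padding.

    ``tag`` names the output buffer so callers that must keep two patch
    matrices alive at once (activations and tangents) do not alias.
    """
    b, h, w, c = x.shape
    # border stays zero across reuses: the kernel only reads, and writes
    # touch the interior only
    xp = pool.get("xp", (b, h + 2, w + 2, c), x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    out = pool.get(tag, (b, h, w, 9 * c), x.dtype)
    _im2col_kernel(xp, out, h, w, c)
    return out.reshape(b * h * w, 9 * c)


def col2im(gcols: np.ndarray, shape: tuple[int, int, int], c: int,
           pool: BufferPool) -> np.ndarray:
    """Adjoint of :func:`im2col`: (B*H*W, 9*C) -> (B, H, W, C)."""
    b, h, w = shape
    g = np.ascontiguousarray(gcols).reshape(b, h, w, 9 * c)
    gx_pad = pool.get("gx_pad", (b, h + 2, w + 2, c), gcols.dtype, zero=True)
    _col2im_kernel(g, gx_pad, h, w, c)
    return gx_pad[:, 1:-1, 1:-1, :].copy()
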
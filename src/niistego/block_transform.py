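"""4x4 microblock tiling and the orthonormal 2-D DCT used by the codec.

The embedding unit is a 4x4 pixel microblock.  Its frequency-domain
counterpart is a 4x4 coefficient block obtained with the separable
orthonormal DCT-II, ``C = T @ MB @ T.T``: position (0, 0) holds the
approximation (DC) coefficient — four times the block mean — and the
remaining fifteen are detail coefficients.  For microblocks with values in
[0, 1] the DC lies in [0, 4] and every detail coefficient has magnitude
strictly below 2; the quantization codec relies on both bounds.

Slices whose side lengths are not multiples of four keep their residual
right/bottom strips outside the block grid; those margins pass through the
codec untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["BlockGrid", "dct_matrix", "forward_block", "inverse_block", "tile", "untile"]


@lru_cache(maxsize=1)
def _dct_matrix_cached() -> np.ndarray:
    k = np.arange(4)[:, None]
    n = np.arange(4)[None, :]
    t = np.sqrt(2.0 / 4.0) * np.cos((2 * n + 1) * k * np.pi / 8.0)
    t[0, :] = 1.0 / np.sqrt(4.0)
    t.setflags(write=False)
    return t


def dct_matrix() -> np.ndarray:
    """Return the orthonormal 4-point DCT-II matrix ``T``.

    Row 0 is the constant ``1/sqrt(4)``; row ``k > 0``, column ``n`` is
    ``sqrt(2/4) * cos((2n+1) k pi / 8)``.  ``T @ T.T`` is the identity, so
    the inverse transform is the transpose.
    """
    return _dct_matrix_cached()


def forward_block(mb: np.ndarray) -> np.ndarray:
    """2-D DCT of one 4x4 microblock, or a batch with shape ``(..., 4, 4)``."""
    t = dct_matrix()
    return t @ np.asarray(mb, dtype=np.float64) @ t.T


def inverse_block(cb: np.ndarray) -> np.ndarray:
    """Inverse 2-D DCT of a 4x4 coefficient block (batched like forward_block)."""
    t = dct_matrix()
    return t.T @ np.asarray(cb, dtype=np.float64) @ t


@dataclass
class BlockGrid:
    """Non-overlapping 4x4 tiling of an m x n plane.

    ``blocks`` has shape ``(m // 4, n // 4, 4, 4)``.  ``right_margin`` is the
    strip ``plane[:4*(m//4), 4*(n//4):]`` and ``bottom_margin`` the strip
    ``plane[4*(m//4):, :]``; together with the blocks they reproduce the
    plane exactly.
    """

    blocks: np.ndarray
    right_margin: np.ndarray
    bottom_margin: np.ndarray
    shape: tuple[int, int]


def tile(plane: np.ndarray) -> BlockGrid:
    """Partition a plane into the 4x4 block grid plus residual margins.

    Raises ``ValueError`` for planes smaller than 4x4 — there would be no
    block to carry the payload.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got shape {plane.shape}")
    m, n = plane.shape
    if m < 4 or n < 4:
        raise ValueError(f"plane {m}x{n} is smaller than one 4x4 block")
    bm, bn = m // 4, n // 4
    core = plane[: 4 * bm, : 4 * bn]
    blocks = core.reshape(bm, 4, bn, 4).transpose(0, 2, 1, 3).copy()
    return BlockGrid(
        blocks=blocks,
        right_margin=plane[: 4 * bm, 4 * bn :].copy(),
        bottom_margin=plane[4 * bm :, :].copy(),
        shape=(m, n),
    )


def untile(grid: BlockGrid) -> np.ndarray:
    """Reassemble the plane from a block grid; exact inverse of :func:`tile`."""
    m, n = grid.shape
    bm, bn = grid.blocks.shape[:2]
    out = np.empty((m, n), dtype=grid.blocks.dtype)
    out[: 4 * bm, : 4 * bn] = grid.blocks.transpose(0, 2, 1, 3).reshape(4 * bm, 4 * bn)
    out[: 4 * bm, 4 * bn :] = grid.right_margin
    out[4 * bm :, :] = grid.bottom_margin
    return out
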
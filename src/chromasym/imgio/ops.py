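"""Pixel-level helpers: maximum projection and largest inscribed square."""

from __future__ import annotations

import numpy as np

from ..errors import EmptyRegionError
from .model import ImageStack

__all__ = ["max_projection", "largest_inscribed_square"]


def max_projection(stack: ImageStack, channel: str) -> np.ndarray:
    """Per-pixel maximum over z of one channel."""
    return stack.channel(channel).max(axis=0)


def largest_inscribed_square(mask: np.ndarray) -> tuple[int, int, int]:
    """Largest axis-aligned square fully inside the true region of ``mask``.

    Returns ``(top, left, side)``. Ties on side are broken by the smallest
    ``(top, left)`` lexicographically.

    Uses the classic dynamic program where ``side[i, j]`` is the edge of the
    largest square whose bottom-right corner is ``(i, j)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got {mask.ndim}D")
    if not mask.any():
        raise EmptyRegionError("cannot inscribe a square in an empty mask")
    ny, nx = mask.shape
    side = np.zeros((ny, nx), dtype=np.int64)
    for i in range(ny):
        row = mask[i]
        for j in range(nx):
            if not row[j]:
                continue
            if i == 0 or j == 0:
                side[i, j] = 1
            else:
                side[i, j] = 1 + min(side[i - 1, j], side[i, j - 1], side[i - 1, j - 1])
    best = int(side.max())
    ii, jj = np.nonzero(side == best)
    tops = ii - best + 1
    lefts = jj - best + 1
    order = np.lexsort((lefts, tops))
    k = order[0]
    return int(tops[k]), int(lefts[k]), best
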
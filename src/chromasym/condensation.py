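"""Sister-chromatid condensation scoring.

Pipeline per cell: maximum-project each channel, crop the largest square
inscribed in the nucleus mask, rescale each channel independently to the
full 16-bit range (min -> 0, max -> 65535), threshold at a fraction
(default 35%) of the scaled maximum, and report

* the condensation parameter: percent of pixels strictly below threshold;
* the occupied area: pixels at or above threshold (the complement);
* the compaction factor: new-channel occupied area / old-channel occupied
  area (> 1 means the old-histone chromatin is more condensed).

Per-cell rescaling makes all of this invariant to affine gain/offset
changes of the raw acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, EmptyRegionError, UndefinedRatioError
from .imgio.model import ImageStack
from .imgio.ops import largest_inscribed_square, max_projection

__all__ = [
    "ScaledImage",
    "CondensationResult",
    "rescale_16bit",
    "condensation_threshold",
    "condensation_parameter",
    "compaction_factor",
    "analyze_condensation",
]

U16_MAX = 65535
DEFAULT_THRESHOLD_FRACTION = 0.35


@dataclass
class ScaledImage:
    """A 2D image rescaled onto [0, 65535], keeping the original extrema."""

    data: np.ndarray
    original_min: float
    original_max: float
    degenerate: bool = False  # constant input; data is all zeros


@dataclass
class CondensationResult:
    """Per-cell condensation statistics for an (old, new) channel pair."""

    threshold: int
    condensation_parameter_old: float  # percent of pixels below threshold
    condensation_parameter_new: float
    occupied_old: int  # pixels at/above threshold
    occupied_new: int
    total_pixels: int

    @property
    def compaction_factor(self) -> float:
        if self.occupied_old == 0:
            raise UndefinedRatioError("old channel has no occupied pixels")
        return self.occupied_new / self.occupied_old

    @property
    def log2_compaction_factor(self) -> float:
        return float(np.log2(self.compaction_factor))


def rescale_16bit(image: np.ndarray) -> ScaledImage:
    """Per-cell linear rescale: minimum -> 0, maximum -> 65535.

    Integerization rounds half away from zero. A constant input cannot be
    stretched; it maps to all zeros and is flagged degenerate rather than
    raising.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ContractError("cannot rescale an empty image")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return ScaledImage(
            data=np.zeros(image.shape, dtype=np.uint16),
            original_min=lo,
            original_max=hi,
            degenerate=True,
        )
    scaled = (image - lo) / (hi - lo) * U16_MAX
    data = np.floor(scaled + 0.5).astype(np.uint16)  # values are >= 0
    return ScaledImage(data=data, original_min=lo, original_max=hi)


def condensation_threshold(
    fraction: float = DEFAULT_THRESHOLD_FRACTION, image_max: int = U16_MAX
) -> int:
    """Intensity threshold: floor(fraction * image_max) in scaled counts."""
    if not 0.0 < fraction < 1.0:
        raise ContractError(f"threshold fraction must be in (0, 1), got {fraction}")
    return int(np.floor(fraction * image_max))


def condensation_parameter(scaled: ScaledImage, mask: np.ndarray, threshold: int) -> float:
    """Percent of masked pixels strictly below ``threshold``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("condensation_parameter over an empty mask")
    values = scaled.data[mask]
    return 100.0 * float((values < threshold).sum()) / values.size


def compaction_factor(
    old_scaled: ScaledImage,
    new_scaled: ScaledImage,
    mask: np.ndarray,
    threshold: int,
) -> CondensationResult:
    """Condensation statistics for a pair of independently rescaled channels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("compaction_factor over an empty mask")
    if old_scaled.data.shape != new_scaled.data.shape:
        raise ContractError("old and new channels must share one shape")
    total = int(mask.sum())
    occ_old = int((old_scaled.data[mask] >= threshold).sum())
    occ_new = int((new_scaled.data[mask] >= threshold).sum())
    result = CondensationResult(
        threshold=int(threshold),
        condensation_parameter_old=100.0 * (total - occ_old) / total,
        condensation_parameter_new=100.0 * (total - occ_new) / total,
        occupied_old=occ_old,
        occupied_new=occ_new,
        total_pixels=total,
    )
    return result


def analyze_condensation(
    stack: ImageStack,
    nucleus_mask: np.ndarray,
    channels: tuple[str, str] = ("old", "new"),
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> CondensationResult:
    """Full per-cell pipeline: project, crop, rescale, threshold, score."""
    old_name, new_name = channels
    proj_old = max_projection(stack, old_name)
    proj_new = max_projection(stack, new_name)
    top, left, side = largest_inscribed_square(nucleus_mask)
    window = np.s_[top : top + side, left : left + side]
    old_scaled = rescale_16bit(proj_old[window])
    new_scaled = rescale_16bit(proj_new[window])
    threshold = condensation_threshold(threshold_fraction, U16_MAX)
    full = np.ones((side, side), dtype=bool)
    return compaction_factor(old_scaled, new_scaled, full, threshold)
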
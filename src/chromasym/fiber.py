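"""Chromatin-fiber sister-strand quantification.

Fibers are measured in fixed-length (default 2 um) segments along a
user-traced axis. Within a segment the two strand regions are inputs; the
lagging strand is the one with the higher background-subtracted mean PCNA
intensity, and the reported statistic is

    log2( (leading mean - background mean) / (lagging mean - background mean) )

Segments with tied PCNA means or a non-positive subtracted intensity are
excluded and counted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from shapely import LineString
from shapely.ops import substring

from .errors import (
    AmbiguousStrandError,
    ContractError,
    DegenerateStatisticError,
    InvalidSegmentError,
)

__all__ = [
    "FiberSegment",
    "FiberSummary",
    "segment_fiber",
    "assign_strands",
    "fiber_log2_ratio",
    "analyze_fiber_segment",
    "summarize_fibers",
]

DEFAULT_SEGMENT_LENGTH_UM = 2.0


@dataclass
class FiberSegment:
    """One measured fiber segment."""

    index: int
    length_um: float
    leading_mean: float
    lagging_mean: float
    background_mean: float
    pcna_leading_mean: float
    pcna_lagging_mean: float
    lagging_id: str  # which input mask was called lagging

    @property
    def log2_ratio(self) -> float:
        lead = self.leading_mean - self.background_mean
        lag = self.lagging_mean - self.background_mean
        if lead <= 0 or lag <= 0:
            raise InvalidSegmentError(
                f"segment {self.index}: non-positive subtracted intensity "
                f"(lead {lead}, lag {lag})"
            )
        return float(np.log2(lead / lag))


@dataclass
class FiberSummary:
    """Mean +/- SE of segment log2 ratios with a one-sample t vs 0."""

    n: int
    mean: float
    se: float | None  # None when n == 1
    t_statistic: float | None = None
    p_value: float | None = None
    excluded: dict[str, int] = field(default_factory=dict)


def segment_fiber(
    axis_points: np.ndarray,
    pixel_size_um: float,
    segment_length_um: float = DEFAULT_SEGMENT_LENGTH_UM,
) -> list[LineString]:
    """Partition a fiber axis polyline into fixed-length arc segments.

    ``axis_points`` is an ``(n, 2)`` array of ``(y, x)`` pixel coordinates.
    Returns consecutive, non-overlapping :class:`~shapely.LineString` pieces
    of exactly ``segment_length_um`` (micrometre coordinates); a trailing
    remainder shorter than one segment is dropped.
    """
    pts = np.asarray(axis_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ContractError("axis_points must be an (n >= 2, 2) array of (y, x)")
    if pixel_size_um <= 0 or segment_length_um <= 0:
        raise ContractError("pixel size and segment length must be positive")
    # shapely works in (x, y); scale pixels to micrometres
    line = LineString(np.column_stack([pts[:, 1], pts[:, 0]]) * pixel_size_um)
    n_segments = int(np.floor(line.length / segment_length_um + 1e-12))
    if n_segments == 0:
        raise ContractError(
            f"fiber is {line.length:.3f} um, shorter than one {segment_length_um} um segment"
        )
    return [
        substring(line, i * segment_length_um, (i + 1) * segment_length_um)
        for i in range(n_segments)
    ]


def _bg_subtracted_mean(image: np.ndarray, mask: np.ndarray, background_mean: float) -> float:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ContractError("strand mask is empty")
    return float(image[mask].mean()) - background_mean


def assign_strands(
    strand_mask_a: np.ndarray,
    strand_mask_b: np.ndarray,
    pcna_image: np.ndarray,
    background_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(leading_mask, lagging_mask)`` by PCNA enrichment.

    The lagging strand is the one with the higher background-subtracted mean
    PCNA; an exact tie raises :class:`AmbiguousStrandError` so the segment
    can be excluded rather than guessed.
    """
    a = np.asarray(strand_mask_a, dtype=bool)
    b = np.asarray(strand_mask_b, dtype=bool)
    if (a & b).any():
        raise ContractError("strand masks must be disjoint")
    bg_mean = float(np.asarray(pcna_image)[np.asarray(background_mask, dtype=bool)].mean())
    pcna_a = _bg_subtracted_mean(pcna_image, a, bg_mean)
    pcna_b = _bg_subtracted_mean(pcna_image, b, bg_mean)
    if pcna_a == pcna_b:
        raise AmbiguousStrandError(f"equal PCNA means ({pcna_a}); cannot assign strands")
    return (a, b) if pcna_b > pcna_a else (b, a)


def fiber_log2_ratio(
    histone_image: np.ndarray,
    leading_mask: np.ndarray,
    lagging_mask: np.ndarray,
    background_mask: np.ndarray,
) -> float:
    """log2 of the background-subtracted leading/lagging mean intensity ratio."""
    bg_mean = float(np.asarray(histone_image)[np.asarray(background_mask, dtype=bool)].mean())
    lead = _bg_subtracted_mean(histone_image, leading_mask, 0.0) - bg_mean
    lag = _bg_subtracted_mean(histone_image, lagging_mask, 0.0) - bg_mean
    if lead <= 0 or lag <= 0:
        raise InvalidSegmentError(
            f"non-positive subtracted intensity (lead {lead}, lag {lag})"
        )
    return float(np.log2(lead / lag))


def analyze_fiber_segment(
    index: int,
    histone_image: np.ndarray,
    pcna_image: np.ndarray,
    strand_mask_a: np.ndarray,
    strand_mask_b: np.ndarray,
    background_mask: np.ndarray,
    length_um: float = DEFAULT_SEGMENT_LENGTH_UM,
    strand_ids: tuple[str, str] = ("a", "b"),
) -> FiberSegment:
    """Assign strands by PCNA and measure one segment."""
    leading, lagging = assign_strands(strand_mask_a, strand_mask_b, pcna_image, background_mask)
    lagging_id = (
        strand_ids[1]
        if np.array_equal(lagging, np.asarray(strand_mask_b, dtype=bool))
        else strand_ids[0]
    )
    hist_bg = float(np.asarray(histone_image)[np.asarray(background_mask, dtype=bool)].mean())
    pcna_bg = float(np.asarray(pcna_image)[np.asarray(background_mask, dtype=bool)].mean())
    return FiberSegment(
        index=index,
        length_um=length_um,
        leading_mean=float(np.asarray(histone_image)[leading].mean()),
        lagging_mean=float(np.asarray(histone_image)[lagging].mean()),
        background_mean=hist_bg,
        pcna_leading_mean=float(np.asarray(pcna_image)[leading].mean()) - pcna_bg,
        pcna_lagging_mean=float(np.asarray(pcna_image)[lagging].mean()) - pcna_bg,
        lagging_id=lagging_id,
    )


def summarize_fibers(log2_values, excluded: dict[str, int] | None = None) -> FiberSummary:
    """Mean +/- SE over valid segment log2 ratios, with one-sample t vs 0."""
    values = np.asarray(list(log2_values), dtype=float)
    if values.size == 0:
        raise DegenerateStatisticError("no valid fiber segments to summarize")
    mean = float(values.mean())
    if values.size == 1:
        return FiberSummary(n=1, mean=mean, se=None, excluded=excluded or {})
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    t_stat = p_val = None
    if values.std(ddof=1) > 0:
        res = scipy.stats.ttest_1samp(values, popmean=0.0)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return FiberSummary(
        n=int(values.size), mean=mean, se=se, t_statistic=t_stat, p_value=p_val,
        excluded=excluded or {},
    )
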
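"""Chromatin association, pixel colocalization, and replication timing.

* ``chromatin_bound_fraction``: on one slice, the amount of a factor on the
  chromatin region (area x mean intensity) divided by the amount elsewhere
  in the cell (cell area x cell mean minus the bound amount).
* ``spearman_coloc``: Spearman rank correlation of two channels over a
  user-drawn bounding region (+1 perfect, 0 none, -1 perfect
  anti-correlation; ties get average ranks).
* nuclear-size proxies and the log2 GSC/GB intensity ratio used to order
  post-mitotic pairs in time; a negative log2 ratio means the
  differentiating daughter leads replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ContractError, DegenerateStatisticError, EmptyRegionError, UndefinedRatioError
from .imgio.model import ImageStack, RegionOfInterest
from .imgio.roi import rasterize_roi
from .quant3d import TotalSignal

__all__ = [
    "ChromatinAssociation",
    "ColocResult",
    "ReplicationTiming",
    "chromatin_bound_fraction",
    "chromatin_bound_fraction_stack",
    "select_chromatin_slice",
    "spearman_coloc",
    "nuclear_size_single_slice",
    "nuclear_size_volume",
    "replication_ratio",
    "timing_curve",
]


@dataclass
class ChromatinAssociation:
    """Area x mean-intensity accounting of one factor around chromatin."""

    chromatin_area: int
    chromatin_mean: float
    cell_area: int
    cell_mean: float
    background: float = 0.0  # per-pixel level subtracted from both means

    @property
    def amount_bound(self) -> float:
        return self.chromatin_area * (self.chromatin_mean - self.background)

    @property
    def amount_excluded(self) -> float:
        return self.cell_area * (self.cell_mean - self.background) - self.amount_bound

    @property
    def bound_ratio(self) -> float:
        excluded = self.amount_excluded
        if excluded <= 0:
            raise UndefinedRatioError(
                f"excluded amount is {excluded}; all signal lies on chromatin"
            )
        return self.amount_bound / excluded


@dataclass
class ColocResult:
    """Spearman colocalization of one channel pair over a bounding region."""

    channel_a: str
    channel_b: str
    rho: float
    n_pixels: int


@dataclass
class ReplicationTiming:
    """One post-mitotic sibling pair's replication-timing entry."""

    pair_id: str
    nuclear_size: float  # px^2 (single-slice) or px^2 x um (volume proxy)
    size_method: str  # "slice" | "volume"
    channel: str  # PCNA or EdU
    log2_ratio: float  # log2(stem / diff); negative => diff side leads


def chromatin_bound_fraction(
    image_slice: np.ndarray,
    chromatin_mask: np.ndarray,
    cell_mask: np.ndarray,
    background: float = 0.0,
) -> ChromatinAssociation:
    """Bound/excluded amount accounting on a single slice.

    ``background`` (per-pixel counts) is subtracted from both means before
    the area x mean products; the default 0 reports the raw variant.
    """
    image_slice = np.asarray(image_slice)
    chrom = np.asarray(chromatin_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if image_slice.shape != chrom.shape or image_slice.shape != cell.shape:
        raise ContractError("image and masks must share one 2D shape")
    if not chrom.any():
        raise EmptyRegionError("chromatin mask is empty")
    if not cell[chrom].all():
        raise ContractError("chromatin mask must lie inside the cell mask")
    if int(cell.sum()) <= int(chrom.sum()):
        raise ContractError("cell mask must be strictly larger than the chromatin mask")
    return ChromatinAssociation(
        chromatin_area=int(chrom.sum()),
        chromatin_mean=float(image_slice[chrom].mean()),
        cell_area=int(cell.sum()),
        cell_mean=float(image_slice[cell].mean()),
        background=float(background),
    )


def select_chromatin_slice(chromatin_masks: np.ndarray) -> int:
    """Index of the slice with the largest chromatin cross-section.

    ``chromatin_masks`` is a ``(z, y, x)`` boolean array; ties resolve to the
    lowest z.
    """
    masks = np.asarray(chromatin_masks, dtype=bool)
    if masks.ndim != 3:
        raise ContractError("chromatin_masks must be (z, y, x)")
    areas = masks.sum(axis=(1, 2))
    if areas.max() == 0:
        raise EmptyRegionError("chromatin mask is empty on every slice")
    return int(np.argmax(areas))


def chromatin_bound_fraction_stack(
    stack: ImageStack,
    channel: str,
    chromatin_masks: np.ndarray,
    cell_masks: np.ndarray,
    background: float = 0.0,
) -> tuple[ChromatinAssociation, int]:
    """Pick the largest-chromatin slice of a stack, then quantify it."""
    z = select_chromatin_slice(chromatin_masks)
    assoc = chromatin_bound_fraction(
        stack.channel(channel)[z],
        np.asarray(chromatin_masks, dtype=bool)[z],
        np.asarray(cell_masks, dtype=bool)[z],
        background=background,
    )
    return assoc, z


def spearman_coloc(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    box_mask: np.ndarray,
    names: tuple[str, str] = ("a", "b"),
) -> ColocResult:
    """Spearman rank correlation of two channels over the masked pixels."""
    a = np.asarray(channel_a)
    b = np.asarray(channel_b)
    mask = np.asarray(box_mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ContractError("channels and box mask must share one shape")
    xs, ys = a[mask].astype(float), b[mask].astype(float)
    if xs.size < 3:
        raise ContractError(f"need at least 3 pixels in the box, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateStatisticError("constant channel: Spearman rho undefined")
    rho = scipy.stats.spearmanr(xs, ys).statistic
    return ColocResult(channel_a=names[0], channel_b=names[1], rho=float(rho),
                       n_pixels=int(xs.size))


def nuclear_size_single_slice(
    shape_yx: tuple[int, int], rois: Sequence[RegionOfInterest]
) -> float:
    """Maximum rasterized area (px^2) of per-slice nucleus outlines."""
    if not rois:
        raise ContractError("need at least one nucleus ROI")
    return float(max(int(rasterize_roi(roi, shape_yx).sum()) for roi in rois))


def nuclear_size_volume(
    shape_yx: tuple[int, int], rois: Sequence[RegionOfInterest], z_step_um: float
) -> float:
    """Volume proxy: sum of per-slice areas times the z step."""
    if not rois:
        raise ContractError("need at least one nucleus ROI")
    if z_step_um <= 0:
        raise ContractError("z step must be positive")
    return float(sum(int(rasterize_roi(roi, shape_yx).sum()) for roi in rois)) * z_step_um


def replication_ratio(ts_stem: TotalSignal, ts_diff: TotalSignal) -> float:
    """log2 of the stem-side over differentiating-side total signal.

    Reported in log2 so that a differentiating daughter entering S phase
    first yields a negative value.
    """
    if ts_stem.fs <= 0 or ts_diff.fs <= 0:
        raise UndefinedRatioError(
            f"non-positive totals (Fs {ts_stem.label}={ts_stem.fs}, {ts_diff.label}={ts_diff.fs})"
        )
    return float(np.log2(ts_stem.fs / ts_diff.fs))


def timing_curve(entries: Sequence[ReplicationTiming]) -> pd.DataFrame:
    """Entries sorted ascending by nuclear size (stable on ties), no smoothing."""
    if not entries:
        raise ContractError("need at least one timing entry")
    df = pd.DataFrame(
        [
            {
                "pair_id": e.pair_id,
                "nuclear_size": e.nuclear_size,
                "size_method": e.size_method,
                "channel": e.channel,
                "log2_ratio": e.log2_ratio,
            }
            for e in entries
        ]
    )
    return df.sort_values("nuclear_size", kind="stable", ignore_index=True)
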
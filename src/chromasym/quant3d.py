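"""Sum-of-slices total fluorescence, sister ratios, and the asymmetry call.

The total signal of one region is the sum over slices of the raw region sum
minus an equal-area background sum taken on each slice:

    Fs = sum_z (Rs_z - Bs_z)

Per-slice differences are kept signed (no clamping); a negative grand total
triggers a warning, not an error.

The asymmetry classifier compares a sibling intensity ratio against the
symmetric-control distribution: threshold = control mean + control SE, where
SE uses the sample (n-1) standard deviation; a ratio strictly above the
threshold is called "asymmetric".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContractError, DegenerateStatisticError, EmptyRegionError, UndefinedRatioError
from .imgio.model import ImageStack, RegionOfInterest
from .imgio.roi import rasterize_roi

__all__ = [
    "TotalSignal",
    "SisterRatio",
    "AsymmetryCall",
    "raw_sum",
    "total_signal",
    "sister_ratio",
    "nucleosome_density_ratio",
    "classify_asymmetry",
]

log = logging.getLogger(__name__)

#: relative pixel-area mismatch tolerated between signal and background ROIs
AREA_TOLERANCE = 0.01


@dataclass
class TotalSignal:
    """Background-subtracted total signal of one region in one channel."""

    label: str
    channel: str
    slice_indices: list[int]
    raw_sums: list[int]  # Rs_z
    background_sums: list[int]  # Bs_z

    def __post_init__(self) -> None:
        if len(self.raw_sums) != len(self.background_sums) or len(self.raw_sums) != len(
            self.slice_indices
        ):
            raise ContractError("Rs, Bs and slice lists must have equal length")

    @property
    def fs(self) -> float:
        """Total background-subtracted signal, sum_z (Rs_z - Bs_z)."""
        return float(sum(r - b for r, b in zip(self.raw_sums, self.background_sums)))


@dataclass
class SisterRatio:
    """Directed intensity ratio between two sibling regions."""

    numerator_label: str
    denominator_label: str
    ratio: float
    channel: str = ""
    stage: str = ""

    @property
    def log2_ratio(self) -> float:
        return float(np.log2(self.ratio))


@dataclass
class AsymmetryCall:
    """Classification of a ratio against a control-derived threshold."""

    ratio: float
    control_mean: float
    control_se: float
    call: str  # "asymmetric" | "symmetric"

    @property
    def threshold(self) -> float:
        return self.control_mean + self.control_se


def raw_sum(image: np.ndarray, mask: np.ndarray) -> int:
    """Sum of pixel gray values under ``mask`` (the raw integrated density).

    ``image`` may be 2D or 3D; a 2D mask applied to a 3D image sums the
    masked pixels on every plane.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("raw_sum over an empty mask")
    if image.ndim == 3 and mask.ndim == 2:
        if image.shape[1:] != mask.shape:
            raise ContractError(f"mask shape {mask.shape} does not match planes {image.shape[1:]}")
        return int(image[:, mask].sum())
    if image.shape != mask.shape:
        raise ContractError(f"mask shape {mask.shape} does not match image {image.shape}")
    return int(image[mask].sum())


def total_signal(
    stack: ImageStack,
    channel: str,
    signal_roi: RegionOfInterest,
    background_roi: RegionOfInterest,
    area_tolerance: float = AREA_TOLERANCE,
) -> TotalSignal:
    """Sum-of-slices background-subtracted total for one region.

    The background ROI must rasterize to the same pixel area as the signal
    ROI (within ``area_tolerance``, default 1%) and cover the same slices.
    """
    arr = stack.channel(channel)
    nz = stack.n_slices
    slices = signal_roi.slice_indices(nz)
    if background_roi.slice_indices(nz) != slices:
        raise ContractError("signal and background ROIs must cover the same slices")
    shape_yx = stack.shape[1:]
    sig_mask = rasterize_roi(signal_roi, shape_yx)
    bg_mask = rasterize_roi(background_roi, shape_yx)
    a_sig, a_bg = int(sig_mask.sum()), int(bg_mask.sum())
    if abs(a_sig - a_bg) > area_tolerance * a_sig:
        raise ContractError(
            f"background area {a_bg} px differs from signal area {a_sig} px "
            f"by more than {area_tolerance:.0%}"
        )
    raw_sums = [int(arr[z][sig_mask].sum()) for z in slices]
    bg_sums = [int(arr[z][bg_mask].sum()) for z in slices]
    ts = TotalSignal(
        label=signal_roi.label,
        channel=channel,
        slice_indices=slices,
        raw_sums=raw_sums,
        background_sums=bg_sums,
    )
    if ts.fs < 0:
        log.warning("negative total signal (%s, %s): Fs = %s", signal_roi.label, channel, ts.fs)
    return ts


def sister_ratio(ts_stem: TotalSignal, ts_diff: TotalSignal, stage: str = "") -> SisterRatio:
    """Stem-side over differentiating-side total-signal ratio."""
    if ts_stem.fs <= 0 or ts_diff.fs <= 0:
        raise UndefinedRatioError(
            f"non-positive totals (Fs {ts_stem.label}={ts_stem.fs}, {ts_diff.label}={ts_diff.fs})"
        )
    return SisterRatio(
        numerator_label=ts_stem.label,
        denominator_label=ts_diff.label,
        ratio=ts_stem.fs / ts_diff.fs,
        channel=ts_stem.channel,
        stage=stage,
    )


def nucleosome_density_ratio(sr: SisterRatio) -> float:
    """Sibling nucleosome-density ratio.

    Density is half the total core-histone amount per unit DNA; in a sibling
    ratio the half factor and the (equal) DNA lengths cancel, so the value
    reduces to the total-histone ratio itself.
    """
    return sr.ratio


def control_summary(control_ratios: Sequence[float]) -> tuple[float, float]:
    """(mean, SE) of a control-ratio sample; SE = sd(n-1) / sqrt(n)."""
    values = np.asarray(list(control_ratios), dtype=float)
    if values.size < 2:
        raise DegenerateStatisticError("need at least 2 control ratios to estimate SE")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def classify_asymmetry(
    ratio: float,
    control_ratios: Sequence[float] | None = None,
    summary: tuple[float, float] | None = None,
) -> AsymmetryCall:
    """Call a sibling ratio asymmetric or symmetric.

    Provide either a list of symmetric-control ratios (SG1/SG2) or an
    explicit ``(mean, SE)`` summary. The call is "asymmetric" iff the ratio
    is strictly above mean + SE; a ratio exactly at the threshold is
    "symmetric".
    """
    if summary is None:
        if control_ratios is None:
            raise ContractError("provide control_ratios or an explicit (mean, SE) summary")
        mean, se = control_summary(control_ratios)
    else:
        mean, se = float(summary[0]), float(summary[1])
    call = "asymmetric" if ratio > mean + se else "symmetric"
    return AsymmetryCall(ratio=float(ratio), control_mean=mean, control_se=se, call=call)
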
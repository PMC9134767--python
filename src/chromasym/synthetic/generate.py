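"""Synthetic microscopy image generators with exact ground truth.

Noise model: per-pixel ``Poisson(expected)`` photon noise plus Gaussian read
noise of standard deviation ``sigma``, rounded to integers and clipped to
the 16-bit range. With both disabled the written image *is* the (integer)
expectation, so noiseless downstream statistics match their closed forms
exactly.

Randomness: a single integer seed fans out into named substreams (one per
channel and noise source) keyed by a CRC of the stream name, so adding a
channel or noise source never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import zlib
from fractions import Fraction

import numpy as np

from ..errors import SpecError
from ..imgio.model import CellAnnotation, ImageStack, RegionOfInterest
from ..imgio.roi import rasterize_roi
from .specs import AssociationSpec, CondensationSpec, FiberSpec, GroundTruth, PairSpec

__all__ = [
    "generate_pair",
    "generate_condensation_cell",
    "generate_fiber",
    "generate_association_cell",
]

_U16_MAX = 65535


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named stream of a seeded simulation."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def _sample(mean: np.ndarray, seed: int, stream: str, poisson: bool, sigma: float) -> np.ndarray:
    """Draw an integer image from the noise model around ``mean``."""
    if poisson:
        img = substream(seed, f"{stream}:poisson").poisson(mean).astype(np.float64)
    else:
        img = np.floor(np.asarray(mean, dtype=np.float64) + 0.5)
    if sigma > 0:
        img = img + np.round(substream(seed, f"{stream}:read").normal(0.0, sigma, mean.shape))
    return np.clip(img, 0, _U16_MAX).astype(np.uint16)


# ---------------------------------------------------------------------------
# telophase sibling pairs


def _ellipsoid_template(base: int, radii: tuple[float, float, float]) -> np.ndarray:
    """Integer-valued Gaussian ellipsoid profile in a tight bounding box."""
    half = [int(np.ceil(4.0 * r)) for r in radii]
    axes = [np.arange(-h, h + 1, dtype=float) for h in half]
    dz, dy, dx = np.meshgrid(*axes, indexing="ij")
    u2 = (dz / radii[0]) ** 2 + (dy / radii[1]) ** 2 + (dx / radii[2]) ** 2
    q = np.floor(base * np.exp(-0.5 * u2) + 0.5).astype(np.int64)
    # trim to the nonzero support (symmetric around the center by construction)
    bounds = []
    for axis, h in enumerate(half):
        proj = q.any(axis=tuple(a for a in range(3) if a != axis))
        ext = int(np.nonzero(proj)[0].max()) - h
        bounds.append(slice(h - ext, h + ext + 1))
    return q[tuple(bounds)]


def _place(canvas: np.ndarray, template: np.ndarray, center: tuple[int, int, int]) -> None:
    half = [s // 2 for s in template.shape]
    lo = [c - h for c, h in zip(center, half)]
    hi = [l + s for l, s in zip(lo, template.shape)]
    if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, canvas.shape)):
        raise SpecError(f"mass at {center} with support {template.shape} exceeds stack bounds")
    canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += template


def _auto_background_center(signal_yx: np.ndarray, roi_radius: float) -> tuple[float, float]:
    """First grid position whose circle avoids image borders and all signal."""
    ny, nx = signal_yx.shape
    yy, xx = np.nonzero(signal_yx > 0)
    step = max(2, int(roi_radius / 2))
    # candidate centers sit at pixel centers (integer + 0.5) so the circle
    # rasterizes to exactly the same pixel count as the mass circles
    for y in np.arange(int(roi_radius) + 1.5, ny - roi_radius, step):
        for x in np.arange(int(roi_radius) + 1.5, nx - roi_radius, step):
            if yy.size == 0:
                return float(y), float(x)
            d2 = (yy + 0.5 - y) ** 2 + (xx + 0.5 - x) ** 2
            if d2.min() > (roi_radius + 1.0) ** 2:
                return float(y), float(x)
    raise SpecError("no signal-free spot large enough for the background circle")


def generate_pair(spec: PairSpec, seed: int):
    """Generate one telophase sibling-pair stack.

    Returns ``(stack, rois, annotations, ground_truth)``. The stem-side and
    differentiating-side masses have background-subtracted expected totals
    in exact ratio ``spec.true_ratio``; ROIs are three identical circles
    (one per mass, one on a signal-free background patch).
    """
    frac = Fraction(spec.true_ratio).limit_denominator(spec.max_denominator)
    s_mult, d_mult = frac.numerator, frac.denominator

    template = _ellipsoid_template(spec.base_intensity, spec.radii)
    unit_total = int(template.sum())
    if unit_total == 0:
        raise SpecError("base_intensity too small: template rounds to zero")

    signal = np.zeros(spec.shape, dtype=np.int64)
    _place(signal, template * s_mult, spec.center_stem)
    _place(signal, template * d_mult, spec.center_diff)

    # one shared circle radius: covers the template's in-plane support
    tz, ty, tx = np.nonzero(template)
    hy, hx = template.shape[1] // 2, template.shape[2] // 2
    support_r = float(np.sqrt(((ty - hy) ** 2 + (tx - hx) ** 2).max())) if ty.size else 1.0
    roi_radius = support_r + 1.5

    signal_yx = signal.sum(axis=0)
    centers_yx = [
        (spec.center_stem[1] + 0.5, spec.center_stem[2] + 0.5),
        (spec.center_diff[1] + 0.5, spec.center_diff[2] + 0.5),
    ]
    bg_center = spec.background_center or _auto_background_center(signal_yx, roi_radius)

    rois = [
        RegionOfInterest("GSC", "circle", center=centers_yx[0], radius=roi_radius, pair_id="pair0"),
        RegionOfInterest("GB", "circle", center=centers_yx[1], radius=roi_radius, pair_id="pair0"),
        RegionOfInterest("background", "circle", center=tuple(bg_center), radius=roi_radius),
    ]
    shape_yx = spec.shape[1:]
    masks = [rasterize_roi(r, shape_yx) for r in rois]
    # each circle must capture exactly its own mass and no foreign signal;
    # the background circle must be signal-free
    for mask, own_center in zip(masks[:2], [spec.center_stem, spec.center_diff]):
        captured = int(signal_yx[mask].sum())
        own = np.zeros(spec.shape, dtype=np.int64)
        _place(own, template, own_center)
        own_total = int(own.sum(axis=0)[mask].sum())
        if captured not in (own_total * s_mult, own_total * d_mult) or own_total != unit_total:
            raise SpecError("mass circles overlap each other's signal; move the masses apart")
    if signal_yx[masks[2]].any():
        raise SpecError("background circle overlaps mass signal")

    mean = signal + spec.background
    channel = _sample(mean, seed, spec.channel, spec.poisson, spec.read_noise_sigma)
    stack = ImageStack({spec.channel: channel}, bit_depth=16,
                       metadata={"generator": "pair", "seed": int(seed)})

    annotations = [
        CellAnnotation("GSC", "telophase", "pair0", "stem"),
        CellAnnotation("GB", "telophase", "pair0", "diff"),
    ]
    gt = GroundTruth(
        kind="pair",
        seed=int(seed),
        params=dataclasses.asdict(spec),
        expected={
            "total_stem": unit_total * s_mult,
            "total_diff": unit_total * d_mult,
            "ratio": s_mult / d_mult,
            "log2_ratio": float(np.log2(s_mult / d_mult)),
            "roi_radius": roi_radius,
            "background_center": list(bg_center),
        },
    )
    return stack, rois, annotations, gt


# ---------------------------------------------------------------------------
# condensation cells


def generate_condensation_cell(spec: CondensationSpec, seed: int):
    """Generate a dual-channel nucleus with controllable signal clustering.

    Returns ``(stack, nucleus_mask, ground_truth)``. A positive base field
    ``B`` (a broad dome times a smooth texture, plus compact Gaussian foci)
    is shared between channels; channel ``c`` carries the fixed total
    ``T * B**(1 + gain * f_c)`` (normalized), so a higher cluster fraction
    concentrates the same amount of signal into the foci.

    Because every channel is a monotone pixel-wise transform of the same
    field, the set of pixels at/above any max-relative threshold is an upper
    level set of ``B`` whose cut rises strictly with ``f`` — the expected
    condensation parameter is strictly increasing in the cluster fraction by
    construction, and equal fractions give bit-identical channels.
    """
    from scipy.ndimage import gaussian_filter

    nz, ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cyx = (yy + 0.5 - spec.nucleus_center[0]) ** 2 + (xx + 0.5 - spec.nucleus_center[1]) ** 2
    nucleus = cyx <= spec.nucleus_radius**2
    npix = int(nucleus.sum())
    if npix == 0:
        raise SpecError("nucleus mask is empty")

    dome = np.exp(-0.5 * cyx / (0.6 * spec.nucleus_radius) ** 2)
    rng_tex = substream(seed, "texture")
    texture = gaussian_filter(rng_tex.standard_normal((ny, nx)), spec.texture_blur)
    t = texture - texture[nucleus].mean()
    amp = np.abs(t[nucleus]).max()
    if amp > 0:
        t = t / amp * spec.texture_contrast
    base = dome * (1.0 + t)

    rng_foci = substream(seed, "foci")
    centers = []
    while len(centers) < spec.n_foci:
        y = rng_foci.uniform(0, ny)
        x = rng_foci.uniform(0, nx)
        if (y - spec.nucleus_center[0]) ** 2 + (x - spec.nucleus_center[1]) ** 2 <= (
            0.8 * spec.nucleus_radius
        ) ** 2:
            centers.append((y, x))
    peak = float(base[nucleus].max())
    for y0, x0 in centers:
        blob = np.exp(
            -0.5 * (((yy + 0.5 - y0) ** 2 + (xx + 0.5 - x0) ** 2) / spec.focus_radius**2)
        )
        base = base + 1.5 * peak * blob
    base = np.where(nucleus, base, 0.0)

    zmid = nz // 2
    channels: dict[str, np.ndarray] = {}
    fractions = {
        spec.old_channel: spec.cluster_fraction_old,
        spec.new_channel: spec.cluster_fraction_new,
    }
    for name, f in fractions.items():
        profile = np.where(nucleus, base ** (1.0 + spec.cluster_gain * f), 0.0)
        plane = spec.total_per_channel * profile / profile.sum() + spec.background
        mean = np.full((nz, ny, nx), float(spec.background))
        mean[zmid] = plane
        channels[name] = _sample(mean, seed, name, spec.poisson, spec.read_noise_sigma)

    stack = ImageStack(channels, bit_depth=16,
                       metadata={"generator": "condensation", "seed": int(seed)})
    gt = GroundTruth(
        kind="condensation",
        seed=int(seed),
        params=dataclasses.asdict(spec),
        expected={
            "cluster_fraction": {spec.old_channel: spec.cluster_fraction_old,
                                 spec.new_channel: spec.cluster_fraction_new},
            "foci_centers": [list(c) for c in centers],
        },
    )
    return stack, nucleus, gt


# ---------------------------------------------------------------------------
# chromatin fibers


def generate_fiber(spec: FiberSpec, seed: int):
    """Generate a 2D two-strand fiber image with PCNA on the lagging strand.

    Returns ``(stack, masks, ground_truth)`` where ``stack`` has one z-slice,
    and ``masks`` holds boolean ``"top"``, ``"bottom"`` strand masks and a
    ``"background"`` off-fiber mask.
    """
    width = int(round(spec.fiber_length_um / spec.pixel_size_um))
    if width < 1:
        raise SpecError("fiber shorter than one pixel")
    ny = spec.height_px
    y_top = ny // 2 - spec.strand_separation_px // 2 - spec.strand_width_px // 2
    y_bot = y_top + spec.strand_separation_px
    if y_top < 2 or y_bot + spec.strand_width_px > ny - 2:
        raise SpecError("strands do not fit in the image height")

    top = np.zeros((ny, width), dtype=bool)
    bottom = np.zeros((ny, width), dtype=bool)
    top[y_top : y_top + spec.strand_width_px, :] = True
    bottom[y_bot : y_bot + spec.strand_width_px, :] = True
    background = np.zeros((ny, width), dtype=bool)
    background[: max(1, y_top - 2), :] = True

    lag_mask, lead_mask = (top, bottom) if spec.lagging == "top" else (bottom, top)

    histone = np.full((ny, width), float(spec.background))
    histone[lead_mask] += spec.lead_intensity
    histone[lag_mask] += spec.lag_intensity
    pcna = np.full((ny, width), float(spec.background))
    pcna[lag_mask] += spec.pcna_intensity

    channels = {
        spec.histone_channel: _sample(histone[None], seed, spec.histone_channel,
                                      spec.poisson, spec.read_noise_sigma),
        spec.pcna_channel: _sample(pcna[None], seed, spec.pcna_channel,
                                   spec.poisson, spec.read_noise_sigma),
    }
    stack = ImageStack(channels, voxel_size=(1.0, spec.pixel_size_um, spec.pixel_size_um),
                       bit_depth=16, metadata={"generator": "fiber", "seed": int(seed)})
    masks = {"top": top, "bottom": bottom, "background": background}
    gt = GroundTruth(
        kind="fiber",
        seed=int(seed),
        params=dataclasses.asdict(spec),
        expected={
            "lagging": spec.lagging,
            "ratio": spec.lead_intensity / spec.lag_intensity,
            "log2_ratio": float(np.log2(spec.lead_intensity / spec.lag_intensity)),
        },
    )
    return stack, masks, gt


# ---------------------------------------------------------------------------
# chromatin-association cells


def generate_association_cell(spec: AssociationSpec, seed: int):
    """Generate one cell whose chromatin region holds ``bound_fraction`` of signal.

    Returns ``(image, chromatin_mask, cell_mask, ground_truth)``. The two
    uniform intensity levels are exact rationals in the areas, so the
    noiseless amount ratio bound/excluded equals ``f/(1-f)`` exactly.
    """
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy + 0.5 - spec.cell_center[0]) ** 2 + (xx + 0.5 - spec.cell_center[1]) ** 2
    cell = d2 <= spec.cell_radius**2
    chromatin = d2 <= spec.chromatin_radius**2
    a_chrom = int(chromatin.sum())
    a_out = int(cell.sum()) - a_chrom
    if a_chrom == 0 or a_out <= 0:
        raise SpecError("degenerate geometry: chromatin or cytoplasm area is zero")

    frac = Fraction(spec.bound_fraction).limit_denominator(spec.max_denominator)
    num, den = frac.numerator, frac.denominator
    u_in_raw = num * a_out
    u_out_raw = (den - num) * a_chrom
    g = np.gcd(u_in_raw, u_out_raw)
    u_in = spec.intensity_scale * (u_in_raw // g)
    u_out = spec.intensity_scale * (u_out_raw // g)
    if max(u_in, u_out) > _U16_MAX:
        raise SpecError(
            f"intensity levels ({u_in:.0f}, {u_out:.0f}) exceed 16-bit range; "
            "lower intensity_scale"
        )

    mean = np.zeros((ny, nx))
    mean[cell] = u_out
    mean[chromatin] = u_in
    image = _sample(mean[None], seed, spec.channel, spec.poisson, spec.read_noise_sigma)[0]

    f = num / den
    gt = GroundTruth(
        kind="association",
        seed=int(seed),
        params=dataclasses.asdict(spec),
        expected={
            "bound_fraction": f,
            "bound_ratio": f / (1.0 - f),
            "amount_bound": a_chrom * u_in,
            "amount_excluded": a_out * u_out,
            "intensity_in": u_in,
            "intensity_out": u_out,
        },
    )
    return image, chromatin, cell, gt
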
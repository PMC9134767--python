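"""Parameter specs and ground truth for the synthetic image generators.

Every generator returns a :class:`GroundTruth` carrying the full generative
parameter set, the seed, and the closed-form expected value of each
downstream statistic, so recovery tests never re-derive expectations by
hand.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

from ..errors import SpecError

__all__ = ["PairSpec", "CondensationSpec", "FiberSpec", "AssociationSpec", "GroundTruth"]


@dataclass
class PairSpec:
    """Telophase sibling-pair stack: two ellipsoidal chromatid masses.

    ``true_ratio`` is the stem-side total divided by the differentiating-side
    total of background-subtracted signal, exact in expectation. The ratio is
    realized as a rational ``S/D`` (``Fraction.limit_denominator``), with the
    two masses sharing one congruent integer intensity template scaled by
    ``S`` and ``D`` respectively, so the noiseless measured ratio is exact.
    """

    true_ratio: float = 1.5
    base_intensity: int = 200
    shape: tuple[int, int, int] = (7, 64, 160)
    center_stem: tuple[int, int, int] = (3, 32, 40)
    center_diff: tuple[int, int, int] = (3, 32, 120)
    radii: tuple[float, float, float] = (1.0, 4.0, 4.0)
    background: int = 10
    read_noise_sigma: float = 0.0
    poisson: bool = False
    background_center: tuple[float, float] | None = None  # (y, x); auto-placed if None
    channel: str = "H3"
    max_denominator: int = 1000

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise SpecError(f"true_ratio must be > 0, got {self.true_ratio}")
        if self.background < 0 or self.read_noise_sigma < 0:
            raise SpecError("background and read noise must be non-negative")
        if self.base_intensity <= 0:
            raise SpecError("base_intensity must be positive")


@dataclass
class CondensationSpec:
    """Dual-channel nucleus whose signal clusters into foci.

    ``cluster_fraction`` maps 0 -> fully diffuse, 1 -> fully concentrated in
    compact foci. Foci positions and the diffuse texture field are shared
    between channels so that equal fractions give bit-identical channels.
    """

    cluster_fraction_old: float = 0.5
    cluster_fraction_new: float = 0.5
    shape: tuple[int, int, int] = (3, 56, 56)
    nucleus_center: tuple[float, float] = (28.0, 28.0)
    nucleus_radius: float = 20.0
    n_foci: int = 4
    focus_radius: float = 2.0
    cluster_gain: float = 3.0  # exponent range of the concentration transform
    texture_blur: float = 3.0
    texture_contrast: float = 0.4  # peak-to-mean amplitude of the diffuse field
    total_per_channel: float = 2.0e5
    background: int = 5
    read_noise_sigma: float = 0.0
    poisson: bool = False
    old_channel: str = "old"
    new_channel: str = "new"

    def __post_init__(self) -> None:
        for f in (self.cluster_fraction_old, self.cluster_fraction_new):
            if not 0.0 <= f <= 1.0:
                raise SpecError(f"cluster_fraction must be in [0, 1], got {f}")
        if not 0.0 <= self.texture_contrast < 1.0:
            raise SpecError("texture_contrast must be in [0, 1)")
        if self.n_foci < 1:
            raise SpecError("need at least one focus")


@dataclass
class FiberSpec:
    """Chromatin fiber: two parallel flat strands plus a PCNA channel.

    Strand intensities are amounts *above* background; the generator writes
    ``background + intensity`` inside each strand so the downstream
    background-subtracted ratio is ``lead_intensity / lag_intensity``
    exactly when noise is off and the intensities are integers.
    """

    lead_intensity: float = 200.0
    lag_intensity: float = 100.0
    pcna_intensity: float = 150.0
    background: int = 20
    pixel_size_um: float = 0.04
    fiber_length_um: float = 4.0
    strand_separation_px: int = 8
    strand_width_px: int = 3
    height_px: int = 32
    lagging: str = "bottom"  # which strand carries PCNA: "top" | "bottom"
    read_noise_sigma: float = 0.0
    poisson: bool = False
    histone_channel: str = "H3"
    pcna_channel: str = "PCNA"

    def __post_init__(self) -> None:
        if self.lead_intensity <= 0 or self.lag_intensity <= 0:
            raise SpecError("strand intensities (above background) must be positive")
        if self.lagging not in ("top", "bottom"):
            raise SpecError(f"lagging must be 'top' or 'bottom', got {self.lagging!r}")
        if self.background < 0:
            raise SpecError("background must be non-negative")


@dataclass
class AssociationSpec:
    """One cell with a chromatin region holding ``bound_fraction`` of signal.

    The two uniform intensity levels are derived from ``bound_fraction`` as
    exact rationals, so the noiseless bound/excluded amount ratio equals
    ``f / (1 - f)`` to machine precision.
    """

    bound_fraction: float = 0.75
    shape: tuple[int, int] = (64, 64)
    cell_center: tuple[float, float] = (32.0, 32.0)
    cell_radius: float = 26.0
    chromatin_radius: float = 9.0
    intensity_scale: float = 1.0
    read_noise_sigma: float = 0.0
    poisson: bool = False
    channel: str = "Cdc6"
    max_denominator: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.bound_fraction < 1.0:
            raise SpecError(f"bound_fraction must be in (0, 1), got {self.bound_fraction}")
        if self.chromatin_radius >= self.cell_radius:
            raise SpecError("chromatin region must be strictly inside the cell")


@dataclass
class GroundTruth:
    """Generative parameters + expected downstream statistics for one image."""

    kind: str
    seed: int
    params: dict[str, Any]
    expected: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_coerce)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(kind=raw["kind"], seed=raw["seed"], params=raw["params"],
                   expected=raw.get("expected", {}))


def _coerce(obj):
    import numpy as np

    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def spec_from_mapping(kind: str, mapping: dict[str, Any]):
    """Build a spec dataclass from a plain mapping (e.g. parsed YAML)."""
    cls = {
        "pair": PairSpec,
        "condensation": CondensationSpec,
        "fiber": FiberSpec,
        "association": AssociationSpec,
    }[kind]
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise SpecError(f"unknown {kind} spec fields: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    return cls(**kwargs)
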
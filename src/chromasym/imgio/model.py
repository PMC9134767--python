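"""Core data model: image stacks, regions of interest, annotations, tables.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based;
* the pixel at integer index ``(y, x)`` occupies the unit square
  ``[y, y+1) x [x, x+1)`` and has its center at ``(y + 0.5, x + 0.5)``;
* a pixel belongs to a region iff its *center* lies inside (boundary
  points count as inside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ..errors import ContractError, MissingChannelError

__all__ = [
    "ImageStack",
    "RegionOfInterest",
    "CellAnnotation",
    "MeasurementTable",
    "MEASUREMENT_COLUMNS",
]


@dataclass
class ImageStack:
    """A multi-channel z-stack of non-negative integer intensities.

    Parameters
    ----------
    channels
        Mapping of channel name to a 3D ``(z, y, x)`` integer array. All
        channels must share one shape.
    voxel_size
        Physical voxel extent ``(z, y, x)`` in micrometres; strictly positive.
    bit_depth
        8 or 16; intensities must lie within ``[0, 2**bit_depth - 1]``.
    metadata
        Free-form key/value pairs carried through readers and writers.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 16
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ContractError("an ImageStack needs at least one channel")
        if self.bit_depth not in (8, 16):
            raise ContractError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ContractError(f"channel arrays must be 3D (z, y, x), got shape {first}")
        for name, shape in shapes.items():
            if shape != first:
                raise ContractError(
                    f"channel {name!r} has shape {shape}, expected {first}"
                )
        ceiling = 2**self.bit_depth - 1
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if not np.issubdtype(arr.dtype, np.integer):
                raise ContractError(f"channel {name!r} is not integer-typed")
            if arr.size and (arr.min() < 0 or arr.max() > ceiling):
                raise ContractError(
                    f"channel {name!r} intensities outside [0, {ceiling}]"
                )
            self.channels[name] = arr
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ContractError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Common ``(z, y, x)`` shape of all channels."""
        return next(iter(self.channels.values())).shape

    @property
    def n_slices(self) -> int:
        return self.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None


@dataclass
class RegionOfInterest:
    """A labeled 2D region: a circle or polygon, applied to one or more slices.

    ``kind`` is ``"circle"`` (``center=(cy, cx)``, ``radius`` in pixels) or
    ``"polygon"`` (``vertices`` as an ``(n, 2)`` array of ``(y, x)`` points).
    ``slices`` is the string ``"all"`` or an explicit list of z indices.
    ``pair_id`` groups sibling regions (e.g. the two chromatid masses of one
    dividing cell).
    """

    label: str
    kind: str
    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: np.ndarray | None = None
    slices: str | list[int] = "all"
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "circle":
            if self.center is None or self.radius is None:
                raise ContractError("circle ROI needs center and radius")
            if self.radius <= 0:
                raise ContractError(f"circle radius must be > 0, got {self.radius}")
            self.center = (float(self.center[0]), float(self.center[1]))
            self.radius = float(self.radius)
        elif self.kind == "polygon":
            if self.vertices is None:
                raise ContractError("polygon ROI needs vertices")
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
                raise ContractError("polygon vertices must be an (n, 2) array of (y, x)")
            if len(self.vertices) < 3:
                raise ContractError("polygon needs at least 3 vertices")
        else:
            raise ContractError(f"unknown ROI kind {self.kind!r}")
        if self.slices != "all":
            self.slices = [int(z) for z in self.slices]
            if not self.slices:
                raise ContractError("slices list must be non-empty (or 'all')")

    def slice_indices(self, n_slices: int) -> list[int]:
        """Resolve ``slices`` against a stack of ``n_slices`` planes."""
        if self.slices == "all":
            return list(range(n_slices))
        bad = [z for z in self.slices if z < 0 or z >= n_slices]
        if bad:
            raise ContractError(f"ROI {self.label!r} references slices {bad} outside [0, {n_slices})")
        return list(self.slices)


# cell_type vocabulary: GSC/GB are the asymmetric stem/differentiating pair,
# SG the symmetric-control pair; labels are inputs, never computed here.
_CELL_TYPES = {"GSC", "GB", "SG"}


@dataclass
class CellAnnotation:
    """Identity of one cell in a sibling pair (inputs, drawn by the user)."""

    cell_type: str
    cycle_stage: str
    pair_id: str
    polarity: str  # "stem" | "diff" for GSC-GB pairs; "SG1" | "SG2" otherwise

    def __post_init__(self) -> None:
        if self.cell_type not in _CELL_TYPES:
            raise ContractError(
                f"cell_type must be one of {sorted(_CELL_TYPES)}, got {self.cell_type!r}"
            )


MEASUREMENT_COLUMNS = ["pair_id", "cell_type", "stage", "measure", "channel", "value", "units"]


class MeasurementTable:
    """Long-format measurement rows with provenance.

    One value per ``(pair_id, measure, channel)``; values must be finite.
    Backed by a pandas DataFrame so downstream joins and summaries stay
    idiomatic.
    """

    def __init__(self, rows: Iterable[Mapping[str, Any]] | pd.DataFrame = (),
                 provenance: Mapping[str, Any] | None = None) -> None:
        if isinstance(rows, pd.DataFrame):
            df = rows.copy()
        else:
            df = pd.DataFrame(list(rows))
        for col in MEASUREMENT_COLUMNS:
            if col not in df.columns:
                df[col] = pd.Series(dtype=object)
        self.df = df[MEASUREMENT_COLUMNS + [c for c in df.columns if c not in MEASUREMENT_COLUMNS]]
        self.provenance = dict(provenance or {})
        self._validate()

    def _validate(self) -> None:
        if len(self.df):
            values = pd.to_numeric(self.df["value"], errors="coerce")
            if not np.isfinite(values.to_numpy(dtype=float)).all():
                raise ContractError("measurement values must be finite numbers")
            dup = self.df.duplicated(subset=["pair_id", "measure", "channel", "cell_type"])
            if dup.any():
                raise ContractError(
                    "duplicate (pair_id, cell_type, measure, channel) rows: "
                    f"{self.df[dup].to_dict('records')}"
                )

    def add_row(self, **row: Any) -> None:
        if len(self.df):
            self.df = pd.concat([self.df, pd.DataFrame([row])], ignore_index=True)
        else:
            self.df = pd.DataFrame([row])
            for col in MEASUREMENT_COLUMNS:
                if col not in self.df.columns:
                    self.df[col] = pd.Series(dtype=object)
        self._validate()

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        payload = {"provenance": self.provenance, "rows": self.df.to_dict("records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    @classmethod
    def from_csv(cls, path, provenance: Mapping[str, Any] | None = None) -> "MeasurementTable":
        return cls(pd.read_csv(path), provenance=provenance or {"source": str(path)})


def annotations_from_csv(path) -> list[CellAnnotation]:
    df = pd.read_csv(path)
    return [
        CellAnnotation(
            cell_type=str(r["cell_type"]),
            cycle_stage=str(r.get("cycle_stage", "")),
            pair_id=str(r["pair_id"]),
            polarity=str(r["polarity"]),
        )
        for r in df.to_dict("records")
    ]


def validate_pairing(annotations: Sequence[CellAnnotation]) -> None:
    """Check every pair_id links exactly two siblings with sensible polarity."""
    by_pair: dict[str, list[CellAnnotation]] = {}
    for ann in annotations:
        by_pair.setdefault(ann.pair_id, []).append(ann)
    for pid, members in by_pair.items():
        if len(members) != 2:
            raise ContractError(f"pair {pid!r} has {len(members)} members, expected 2")
        types = sorted(m.cell_type for m in members)
        if types == ["GB", "GSC"]:
            pol = sorted(m.polarity for m in members)
            if pol != ["diff", "stem"]:
                raise ContractError(
                    f"GSC-GB pair {pid!r} needs polarities {{'stem','diff'}}, got {pol}"
                )
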
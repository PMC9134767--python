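"""ROI rasterization and ROI table readers/writers (CSV and JSON)."""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from ..errors import ContractError, EmptyRegionError
from .model import RegionOfInterest

__all__ = [
    "rasterize_roi",
    "read_rois_csv",
    "write_rois_csv",
    "read_rois_json",
    "write_rois_json",
]


def rasterize_roi(roi: RegionOfInterest, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a circle or polygon ROI onto a ``(y, x)`` grid.

    A pixel is set iff its center ``(y + 0.5, x + 0.5)`` lies inside the
    region; boundary points count as inside.

    Raises
    ------
    EmptyRegionError
        If no pixel center falls inside the region.
    """
    ny, nx = int(shape[0]), int(shape[1])
    if ny <= 0 or nx <= 0:
        raise ContractError(f"mask shape must be positive, got {shape}")
    cy = np.arange(ny) + 0.5
    cx = np.arange(nx) + 0.5
    if roi.kind == "circle":
        y0, x0 = roi.center
        dy2 = (cy - y0)[:, None] ** 2
        dx2 = (cx - x0)[None, :] ** 2
        mask = dy2 + dx2 <= roi.radius**2
    else:
        # shapely works in (x, y); covers() includes the boundary
        poly = shapely.Polygon([(x, y) for y, x in roi.vertices])
        yy, xx = np.meshgrid(cy, cx, indexing="ij")
        pts = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]))
        mask = shapely.covers(poly, pts).reshape(ny, nx)
    if not mask.any():
        raise EmptyRegionError(f"ROI {roi.label!r} contains no pixel centers in shape {shape}")
    return mask


def _encode_slices(slices) -> str:
    return "all" if slices == "all" else ";".join(str(z) for z in slices)


def _decode_slices(text: str):
    text = str(text).strip()
    if text in ("all", "", "nan"):
        return "all"
    return [int(tok) for tok in text.replace(",", ";").split(";") if tok.strip()]


def _encode_vertices(vertices: np.ndarray) -> str:
    return ";".join(f"{y:g}:{x:g}" for y, x in vertices)


def _decode_vertices(text: str) -> np.ndarray:
    pts = []
    for tok in str(text).split(";"):
        tok = tok.strip()
        if tok:
            y, x = tok.split(":")
            pts.append((float(y), float(x)))
    return np.asarray(pts)


def _roi_to_record(roi: RegionOfInterest) -> dict:
    rec = {
        "label": roi.label,
        "shape": roi.kind,
        "cy": "" if roi.center is None else roi.center[0],
        "cx": "" if roi.center is None else roi.center[1],
        "radius": "" if roi.radius is None else roi.radius,
        "vertices": "" if roi.vertices is None else _encode_vertices(roi.vertices),
        "slices": _encode_slices(roi.slices),
        "pair_id": roi.pair_id or "",
    }
    return rec


def _roi_from_record(rec: dict) -> RegionOfInterest:
    kind = str(rec["shape"]).strip()
    def _blank(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in ("", "nan")

    center = None
    radius = None
    vertices = None
    if kind == "circle":
        center = (float(rec["cy"]), float(rec["cx"]))
        radius = float(rec["radius"])
    else:
        v = rec.get("vertices")
        if _blank(v):
            raise ContractError(f"polygon ROI {rec.get('label')!r} lacks vertices")
        vertices = _decode_vertices(v) if isinstance(v, str) else np.asarray(v, dtype=float)
    pair_id = rec.get("pair_id")
    return RegionOfInterest(
        label=str(rec["label"]),
        kind=kind,
        center=center,
        radius=radius,
        vertices=vertices,
        slices=_decode_slices(rec.get("slices", "all")),
        pair_id=None if _blank(pair_id) else str(pair_id),
    )


def write_rois_csv(rois: Sequence[RegionOfInterest], path) -> None:
    pd.DataFrame([_roi_to_record(r) for r in rois]).to_csv(path, index=False)


def read_rois_csv(path) -> list[RegionOfInterest]:
    df = pd.read_csv(path, keep_default_na=False)
    return [_roi_from_record(rec) for rec in df.to_dict("records")]


def write_rois_json(rois: Sequence[RegionOfInterest], path) -> None:
    records = []
    for roi in rois:
        rec = _roi_to_record(roi)
        if roi.vertices is not None:
            rec["vertices"] = [[float(y), float(x)] for y, x in roi.vertices]
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def read_rois_json(path) -> list[RegionOfInterest]:
    with open(path) as fh:
        records = json.load(fh)
    return [_roi_from_record(rec) for rec in records]
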
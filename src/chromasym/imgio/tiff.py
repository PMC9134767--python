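"""TIFF / OME-TIFF stack reading and writing via :mod:`tifffile`.

Layout convention for plain TIFF: planes are z-major channel-interleaved,
i.e. for channels ``[a, b]`` the plane order is ``a@z0, b@z0, a@z1, b@z1...``.
OME-TIFF files carry their own axis metadata, which takes precedence.
Stacks written by :func:`write_stack` embed channel names, voxel size and
bit depth as a JSON image description so round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from ..errors import FormatError
from .model import ImageStack

__all__ = ["read_stack", "write_stack", "write_mask"]


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as an interleaved multi-page TIFF."""
    names = stack.channel_names
    nz, ny, nx = stack.shape
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    planes = np.empty((nz * len(names), ny, nx), dtype=dtype)
    for zi in range(nz):
        for ci, name in enumerate(names):
            planes[zi * len(names) + ci] = stack.channels[name][zi].astype(dtype)
    desc = json.dumps(
        {
            "channels": names,
            "voxel_size": list(stack.voxel_size),
            "bit_depth": stack.bit_depth,
            "metadata": {k: v for k, v in stack.metadata.items() if _jsonable(v)},
        }
    )
    tifffile.imwrite(path, planes, description=desc, photometric="minisblack")


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False


def read_stack(path, channel_names: list[str] | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    ``channel_names`` overrides names found in the file; for plain TIFF with
    no embedded description it is required when more than one channel is
    expected (planes are then deinterleaved in the given order).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            desc = tif.pages[0].description or ""
            is_ome = tif.is_ome
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc

    voxel_size = (1.0, 1.0, 1.0)
    bit_depth = 8 if data.dtype == np.uint8 else 16
    metadata: dict = {}
    embedded_names: list[str] | None = None

    if is_ome and ("C" in axes or "Z" in axes):
        # normalize whatever axis order OME declares to (C, Z, Y, X)
        arr = data
        want = "CZYX"
        for ax in want:
            if ax not in axes:
                arr = np.expand_dims(arr, 0)
                axes = ax + axes
        order = [axes.index(ax) for ax in want]
        extra = [i for i in range(arr.ndim) for a in [axes[i]] if a not in want]
        if extra:
            raise FormatError(f"unsupported OME axes {axes!r} in {path}")
        arr = arr.transpose(order)
        names = channel_names or [f"ch{i}" for i in range(arr.shape[0])]
        if len(names) != arr.shape[0]:
            raise FormatError(
                f"{path}: channel axis has {arr.shape[0]} planes but "
                f"{len(names)} channel names given"
            )
        channels = {name: np.ascontiguousarray(arr[i]) for i, name in enumerate(names)}
        return ImageStack(channels, voxel_size=voxel_size, bit_depth=bit_depth, metadata=metadata)

    if desc:
        try:
            info = json.loads(desc)
            embedded_names = list(info.get("channels", []))
            voxel_size = tuple(info.get("voxel_size", voxel_size))
            bit_depth = int(info.get("bit_depth", bit_depth))
            metadata = dict(info.get("metadata", {}))
        except (json.JSONDecodeError, TypeError):
            pass

    names = channel_names or embedded_names or ["ch0"]
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2D planes, got shape {data.shape}")
    n_planes = data.shape[0]
    if n_planes % len(names) != 0:
        raise FormatError(
            f"{path}: plane count {n_planes} not divisible by channel count {len(names)}"
        )
    nz = n_planes // len(names)
    channels = {
        name: np.ascontiguousarray(data[ci :: len(names)][:nz])
        for ci, name in enumerate(names)
    }
    return ImageStack(channels, voxel_size=voxel_size, bit_depth=bit_depth, metadata=metadata)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit TIFF (255 inside, 0 outside)."""
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
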
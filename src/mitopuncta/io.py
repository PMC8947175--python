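"""Multi-channel image input/output.

The analysis operates on triple-stained confocal fields: a dsDNA channel, a
histone-H2B channel (nuclear marker) and an Hsp60 channel (mitochondrial-matrix
marker).  This module reads and writes such fields as (OME-)TIFF files and
attaches the two pieces of metadata everything downstream depends on: which
channel plays which role, and the physical pixel size in micrometres (area
filters in μm² are meaningless without it).

Pixel-size precedence is: explicit :class:`ChannelMap` override > OME
``PhysicalSizeX`` metadata > plain-TIFF resolution tags.  Absence at all three
levels is an error, never a silent default.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

ROLES = ("dsdna", "h2b", "hsp60")


@dataclasses.dataclass(frozen=True)
class ChannelMap:
    """Role → channel-index mapping plus optional metadata overrides.

    Parameters
    ----------
    dsdna, h2b, hsp60 : int
        Indices of the three roles along the file's channel axis.
    pixel_size_um : float, optional
        Overrides any pixel size found in the file metadata.
    axes : str, optional
        Axis layout (e.g. ``"CYX"`` or ``"YXC"``) for files that carry no
        axis metadata.
    """

    dsdna: int = 0
    h2b: int = 1
    hsp60: int = 2
    pixel_size_um: float | None = None
    axes: str | None = None

    def __post_init__(self) -> None:
        idx = (self.dsdna, self.h2b, self.hsp60)
        if any((not isinstance(i, (int, np.integer))) or i < 0 for i in idx):
            raise ValueError("channel indices must be non-negative integers")
        if len(set(idx)) != 3:
            raise ValueError(f"channel indices must be distinct, got {idx}")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um override must be positive")
        if self.axes is not None and "C" not in self.axes.upper():
            raise ValueError("axes override must contain a 'C' axis")

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.dsdna, self.h2b, self.hsp60)


@dataclasses.dataclass
class ChannelStack:
    """One field of view: three co-registered 2-D intensity images.

    Intensities are promoted to float64 on construction (subtraction produces
    negatives that integer types cannot hold); the original dtype is recorded
    in ``source_dtype`` so integer stacks round-trip bit-exactly through
    :func:`write_stack` / :func:`read_stack`.
    """

    dsdna: np.ndarray
    h2b: np.ndarray
    hsp60: np.ndarray
    pixel_size_um: float
    image_id: str = ""
    source_dtype: np.dtype = dataclasses.field(default=np.dtype(np.float64))

    def __post_init__(self) -> None:
        arrays = {}
        for role in ROLES:
            arr = np.asarray(getattr(self, role))
            if arr.ndim != 2:
                raise ValueError(f"{role} channel must be 2-D, got shape {arr.shape}")
            arrays[role] = arr.astype(np.float64, copy=False)
        shapes = {a.shape for a in arrays.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        for role, arr in arrays.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{role} channel contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"{role} channel contains negative intensities")
            object.__setattr__(self, role, arr)
        if not (np.isscalar(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be a positive scalar")
        self.pixel_size_um = float(self.pixel_size_um)
        self.source_dtype = np.dtype(self.source_dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dsdna.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {role: getattr(self, role) for role in ROLES}


def max_project(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection of a z-stack down to a single plane.

    Convenience for data acquired as 3-D stacks; the analysis itself is
    strictly 2-D, so projection (or slice selection) must happen before a
    :class:`ChannelStack` is built.
    """
    volume = np.asarray(volume)
    if volume.ndim < 3:
        raise ValueError("max_project expects an array with a z axis")
    return volume.max(axis=axis)


def _pixel_size_from_ome(tf: tifffile.TiffFile) -> float | None:
    if not tf.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
    except Exception:  # malformed XML: fall through to resolution tags
        return None
    image = meta.get("OME", {}).get("Image")
    if isinstance(image, list):
        image = image[0] if image else None
    if not isinstance(image, dict):
        return None
    pixels = image.get("Pixels", {})
    size = pixels.get("PhysicalSizeX")
    if size is None:
        size = pixels.get("PhysicalSizeY")
    if size is None:
        return None
    size = float(size)
    return size if size > 0 else None


def _pixel_size_from_tags(tf: tifffile.TiffFile) -> float | None:
    page = tf.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
    px_per_unit = num / den
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimetre
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 2.54e4 / px_per_unit
    return None


def _resolve_channel_axis(arr: np.ndarray, axes: str | None, channel_map: ChannelMap) -> np.ndarray:
    """Return the image as (C, Y, X), resolving CYX/YXC and friends."""
    # drop singleton axes (e.g. a length-1 Z or T)
    if axes is not None and len(axes) == arr.ndim:
        keep = [i for i, n in enumerate(arr.shape) if n > 1]
        axes = "".join(axes[i] for i in keep)
    arr = np.squeeze(arr)
    if arr.ndim != 3:
        raise ValueError(
            f"expected 3-D multi-channel data with 2-D planes, got shape {arr.shape}"
        )
    if axes is not None and len(axes) == 3 and "C" in axes.upper():
        c_axis = axes.upper().index("C")
    elif channel_map.axes is not None:
        c_axis = channel_map.axes.upper().index("C")
    else:
        # heuristic: the channel axis is the smallest one
        c_axis = int(np.argmin(arr.shape))
        logger.info("no axis metadata; assuming channel axis %d of shape %s", c_axis, arr.shape)
    return np.moveaxis(arr, c_axis, 0)


def read_stack(path: str | os.PathLike, channel_map: ChannelMap | None = None) -> ChannelStack:
    """Read a multi-channel TIFF/OME-TIFF into a :class:`ChannelStack`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file has fewer than three channels, planes are not 2-D, or no
        pixel size is available from the override, OME metadata or TIFF
        resolution tags.
    """
    channel_map = channel_map or ChannelMap()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = getattr(series, "axes", None)
        data = _resolve_channel_axis(arr, axes, channel_map)
        n_channels = data.shape[0]
        if n_channels < 3:
            raise ValueError(
                f"insufficient channels: need >= 3, file has {n_channels}"
            )
        if max(channel_map.indices) >= n_channels:
            raise ValueError(
                f"channel map {channel_map.indices} out of range for {n_channels} channels"
            )
        pixel_size = channel_map.pixel_size_um
        source = "override"
        if pixel_size is None:
            pixel_size = _pixel_size_from_ome(tf)
            source = "OME metadata"
        if pixel_size is None:
            pixel_size = _pixel_size_from_tags(tf)
            source = "TIFF resolution tags"
        if pixel_size is None:
            raise ValueError(
                "no pixel size: not in channel map override, OME metadata or "
                "TIFF resolution tags"
            )
    logger.info(
        "read %s: %d channels, roles %s, pixel size %.4g um (%s)",
        path, n_channels, channel_map.indices, pixel_size, source,
    )
    src_dtype = arr.dtype
    return ChannelStack(
        dsdna=data[channel_map.dsdna],
        h2b=data[channel_map.h2b],
        hsp60=data[channel_map.hsp60],
        pixel_size_um=float(pixel_size),
        image_id=path.stem.replace(".ome", ""),
        source_dtype=src_dtype,
    )


def write_stack(stack: ChannelStack, path: str | os.PathLike) -> None:
    """Write a :class:`ChannelStack` as a 3-channel OME-TIFF with pixel size.

    Channel order on disk is (dsDNA, H2B, Hsp60); integer source dtypes are
    restored so that integer stacks round-trip bit-exactly.
    """
    path = Path(path)
    data = np.stack([stack.dsdna, stack.h2b, stack.hsp60])
    if np.issubdtype(stack.source_dtype, np.integer):
        data = data.astype(stack.source_dtype)
    else:
        data = data.astype(np.float64)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": ["dsDNA", "histone-H2B", "Hsp60"]},
        },
    )
    logger.info("wrote %s (%s, %s)", path, data.shape, data.dtype)
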
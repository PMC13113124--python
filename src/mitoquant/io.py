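"""Calibrated multi-channel z-stack containers and TIFF round-trip.

The in-memory unit of the whole pipeline is :class:`ImageStack`: a
``(channel, z, y, x)`` float array plus the physical voxel size in
micrometres.  Stacks are exchanged on disk as plain multi-page TIFF
(one page per channel-plane) with a JSON payload in the image
description tag carrying the calibration and channel names, so a stack
survives a round trip with its geometry intact.  Calibration is never
silently defaulted: a file without recognizable voxel-size metadata is
an error unless the caller supplies an override.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["ImageStack", "BinaryMask", "read_stack", "write_stack", "CalibrationMissingError"]

_DESC_KEY = "mitoquant"


class CalibrationMissingError(ValueError):
    """Raised when a TIFF carries no voxel-size metadata and no override is given."""


@dataclass
class ImageStack:
    """A calibrated multi-channel voxel grid.

    Parameters
    ----------
    voxels:
        Intensity array indexed ``(channel, z, y, x)``, finite and nonnegative.
    voxel_size:
        Physical size of one voxel as ``(dz, dy, dx)`` in µm, all > 0.
    channel_names:
        One label per channel.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be (channel, z, y, x), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] == 0:
            raise ValueError("stack must have at least one channel")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values (dz, dy, dx), got {self.voxel_size}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel's ``(z, y, x)`` array by name or index."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"unknown channel {name_or_index!r}; have {self.channel_names}") from None
        else:
            idx = int(name_or_index)
            if not 0 <= idx < self.n_channels:
                raise KeyError(f"channel index {idx} out of range for {self.n_channels} channels")
        return self.voxels[idx]


@dataclass
class BinaryMask:
    """A boolean grid sharing an image's spatial geometry and calibration.

    Works in 2D (projections; ``voxel_size`` = (dy, dx)) and 3D
    (``voxel_size`` = (dz, dy, dx)).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.voxels.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if len(self.voxel_size) != self.voxels.ndim:
            raise ValueError("voxel_size length must match mask dimensionality")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")

    @property
    def voxel_measure(self) -> float:
        """Physical measure of one voxel: area (µm²) in 2D, volume (µm³) in 3D."""
        return float(np.prod(self.voxel_size))

    def measure_um(self) -> float:
        """Physical area (2D) or volume (3D) of the foreground."""
        return float(self.voxels.sum()) * self.voxel_measure


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (pages = channels · z-planes).

    Calibration and channel names travel in a JSON image-description tag;
    x/y resolution tags are set as well for viewers that honour them.
    """
    path = Path(path)
    c, z, y, x = stack.voxels.shape
    pages = stack.voxels.reshape(c * z, y, x).astype(np.float32)
    desc = json.dumps(
        {
            _DESC_KEY: {
                "voxel_size_um": list(stack.voxel_size),
                "channel_names": list(stack.channel_names),
                "n_channels": c,
                "n_z": z,
            }
        }
    )
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        pages,
        description=desc,
        resolution=(1.0 / dx, 1.0 / dy),
        photometric="minisblack",
        metadata=None,
    )


def read_stack(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
    n_channels: int | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Calibration is taken from the JSON description tag written by
    :func:`write_stack`; ``voxel_size_override`` replaces it when given.
    A file with neither raises :class:`CalibrationMissingError` — voxel
    size is physical input, not something to guess.

    For foreign TIFFs (no description payload) the pages are treated as a
    single-channel z-stack unless ``n_channels`` divides the page count.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description if tf.pages else ""
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with ndim={pages.ndim}")

    meta = None
    if desc:
        try:
            meta = json.loads(desc).get(_DESC_KEY)
        except (json.JSONDecodeError, AttributeError):
            meta = None

    if meta is not None:
        voxel_size = tuple(meta["voxel_size_um"])
        c, z = int(meta["n_channels"]), int(meta["n_z"])
        names = list(meta["channel_names"])
    else:
        if voxel_size_override is None:
            raise CalibrationMissingError(
                f"{path} carries no voxel-size metadata; pass voxel_size_override=(dz, dy, dx)"
            )
        voxel_size = tuple(voxel_size_override)
        c = int(n_channels) if n_channels else 1
        if pages.shape[0] % c:
            raise ValueError(f"page count {pages.shape[0]} not divisible by n_channels={c}")
        z = pages.shape[0] // c
        names = list(channel_names) if channel_names else []

    if voxel_size_override is not None:
        voxel_size = tuple(float(v) for v in voxel_size_override)
    if pages.shape[0] != c * z:
        raise ValueError(f"inconsistent page count: {pages.shape[0]} pages for {c} channels × {z} planes")
    voxels = pages.reshape(c, z, pages.shape[1], pages.shape[2]).astype(np.float64)
    return ImageStack(voxels=voxels, voxel_size=voxel_size, channel_names=names)
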
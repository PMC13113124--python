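"""Filtering and thresholding operators composed by the imaging pipelines.

These are the building blocks of the confocal macro (median z-projection,
median filter, white top-hat, Triangle auto-threshold, binarization) and
of the expansion-microscopy pipeline (3D Gaussian smoothing).  All
borders are handled by reflection so per-cell crops do not grow rim
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .io import BinaryMask, ImageStack

__all__ = [
    "Image2D",
    "ThresholdResult",
    "project_z",
    "median_filter",
    "tophat_white",
    "smooth_3d",
    "triangle_threshold",
    "binarize",
    "DegenerateHistogramError",
]

N_BINS = 256


class DegenerateHistogramError(ValueError):
    """Raised when an image has a single intensity value and cannot be thresholded."""


@dataclass
class Image2D:
    """A single-channel 2D image with physical pixel size (dy, dx) in µm."""

    pixels: np.ndarray
    pixel_size: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        self.pixel_size = (float(self.pixel_size[0]), float(self.pixel_size[1]))
        if any(v <= 0 for v in self.pixel_size):
            raise ValueError("pixel_size components must be > 0")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]


@dataclass
class ThresholdResult:
    """Outcome of an auto-threshold: the cut value plus its histogram context."""

    threshold: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    method: str
    bin_index: int = field(default=-1)


def project_z(stack: ImageStack, channel: str | int, statistic: str = "median") -> Image2D:
    """Project one channel along z with the given per-pixel statistic.

    ``median`` is the macro's default for intensity work; ``max`` is used
    for the morphology projection that feeds phenotype classification.
    """
    planes = stack.channel(channel)
    if planes.shape[0] < 1:
        raise ValueError("stack must contain at least one z-plane")
    if statistic == "median":
        proj = np.median(planes, axis=0)
    elif statistic == "max":
        proj = planes.max(axis=0)
    else:
        raise ValueError(f"unknown projection statistic {statistic!r} (use 'median' or 'max')")
    return Image2D(pixels=proj, pixel_size=(stack.voxel_size[1], stack.voxel_size[2]))


def _disk_footprint(radius_px: int) -> np.ndarray:
    # Euclidean-distance disk, matching the "radius" phrasing of the macro.
    return disk(radius_px)


def median_filter(img: Image2D, radius_px: int) -> Image2D:
    """Median within a disk of the given pixel radius; radius 0 is the identity."""
    radius_px = int(radius_px)
    if radius_px < 0:
        raise ValueError("median radius must be >= 0")
    if radius_px == 0:
        return Image2D(img.pixels.copy(), img.pixel_size)
    out = ndimage.median_filter(img.pixels, footprint=_disk_footprint(radius_px), mode="reflect")
    return Image2D(out, img.pixel_size)


def tophat_white(img: Image2D, radius_px: int) -> Image2D:
    """White top-hat: image minus its grayscale opening by a disk.

    Removes background structure wider than the disk while keeping small
    bright objects; the result is pointwise ≥ 0 and ≤ the input.
    """
    radius_px = int(radius_px)
    if radius_px < 1:
        raise ValueError("top-hat radius must be >= 1")
    opened = ndimage.grey_opening(img.pixels, footprint=_disk_footprint(radius_px), mode="reflect")
    return Image2D(img.pixels - opened, img.pixel_size)


def smooth_3d(stack: ImageStack, sigma_vox: float | tuple[float, float, float]) -> ImageStack:
    """Gaussian-smooth every channel in 3D; sigma 0 is the identity."""
    sigma = np.broadcast_to(np.asarray(sigma_vox, dtype=float), (3,))
    if np.any(sigma < 0):
        raise ValueError("smoothing sigma must be >= 0")
    if np.all(sigma == 0):
        return ImageStack(stack.voxels.copy(), stack.voxel_size, list(stack.channel_names))
    out = np.empty_like(stack.voxels)
    for c in range(stack.n_channels):
        out[c] = ndimage.gaussian_filter(stack.voxels[c], sigma=tuple(sigma), mode="reflect")
    return ImageStack(out, stack.voxel_size, list(stack.channel_names))


def triangle_threshold(img_or_hist, bin_edges: np.ndarray | None = None) -> ThresholdResult:
    """Triangle auto-threshold on a 256-bin min–max histogram.

    The threshold bin maximizes the perpendicular distance between the
    (peak-normalized) histogram and the straight line joining the peak
    bin to the farthest nonzero bin, taken on the longer-tail side of
    the peak; ties go to the lowest qualifying bin.  Accepts an image
    array (any dimensionality) or a precomputed histogram with its bin
    edges.  Peak-height normalization makes the chosen bin invariant to
    uniform rescaling of the counts.
    """
    if bin_edges is not None:
        hist = np.asarray(img_or_hist, dtype=np.float64)
        edges = np.asarray(bin_edges, dtype=np.float64)
        if hist.ndim != 1 or edges.shape[0] != hist.shape[0] + 1:
            raise ValueError("histogram and bin_edges shapes are inconsistent")
    else:
        data = np.asarray(getattr(img_or_hist, "pixels", img_or_hist), dtype=np.float64).ravel()
        lo, hi = float(data.min()), float(data.max())
        if hi <= lo:
            raise DegenerateHistogramError("constant image: degenerate histogram")
        hist, edges = np.histogram(data, bins=N_BINS, range=(lo, hi))
        hist = hist.astype(np.float64)

    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")

    bin_index = _triangle_bin(hist)
    threshold = 0.5 * (edges[bin_index] + edges[bin_index + 1])
    return ThresholdResult(
        threshold=float(threshold),
        histogram=hist,
        bin_edges=edges,
        method="triangle",
        bin_index=int(bin_index),
    )


def _triangle_bin(hist: np.ndarray) -> int:
    """Index of the triangle-threshold bin of a 1D count histogram."""
    h = hist / hist.max()  # peak-normalized: scaling counts cannot move the argmax
    peak = int(np.argmax(h))  # np.argmax returns the lowest index on ties
    nonzero = np.flatnonzero(hist)
    left, right = int(nonzero[0]), int(nonzero[-1])
    # Work on the side with the longer run from peak to extreme nonzero bin;
    # on a tie the brighter side is taken (foreground sits above background).
    if (right - peak) >= (peak - left):
        tail = right
    else:
        tail = left
    lo, hi = (peak, tail) if peak <= tail else (tail, peak)
    bins = np.arange(lo, hi + 1)
    # Perpendicular distance from each histogram point to the peak→tail chord.
    dx, dy = float(tail - peak), float(h[tail] - h[peak])
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (h[bins] - h[peak]) - dy * (bins - peak)) / norm
    return int(bins[np.argmax(dist)])


def binarize(img: Image2D | ImageStack | np.ndarray, threshold: float,
             voxel_size: tuple[float, ...] | None = None) -> BinaryMask:
    """Foreground = intensity strictly greater than the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if isinstance(img, Image2D):
        return BinaryMask(img.pixels > threshold, img.pixel_size)
    if isinstance(img, ImageStack):
        if img.n_channels != 1:
            raise ValueError("binarize on a stack requires a single channel; pass stack.channel(...)")
        return BinaryMask(img.voxels[0] > threshold, img.voxel_size)
    arr = np.asarray(img)
    if voxel_size is None:
        raise ValueError("voxel_size is required when binarizing a bare array")
    return BinaryMask(arr > threshold, voxel_size)
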
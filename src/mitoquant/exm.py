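"""Expansion-microscopy quantification: calibration and 3D c-Abl metrics.

A gel's expansion factor is measured macroscopically as the ratio of its
area after expansion to the coverslip area; because isotropic expansion
scales areas by the square of the linear factor, voxel dimensions are
calibrated by the square root of that area ratio (an option treats the
reported ratio as already linear).  On the calibrated two-channel volume
the pipeline computes the four cluster metrics: cluster density
(µm⁻³), mean cluster volume (µm³), the mitochondrial-to-non-mitochondrial
c-Abl volume ratio (association), and the percentage of the
mitochondrial volume occupied by c-Abl (occupancy) — all at biological
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .io import BinaryMask, ImageStack
from .objects import label_components, mask_and, mask_and_not, measure_objects
from .preprocess import binarize, smooth_3d, triangle_threshold

__all__ = ["ExpansionCalibration", "ExMQuant", "calibrate_expansion", "apply_calibration", "exm_pipeline"]


@dataclass(frozen=True)
class ExpansionCalibration:
    """Gel expansion measured from pre/post areas (mm²)."""

    area_pre: float
    area_post: float

    def __post_init__(self) -> None:
        if self.area_pre <= 0:
            raise ValueError("pre-expansion area must be > 0")
        if self.area_post < self.area_pre:
            raise ValueError("gel shrank: post-expansion area below pre-expansion area")

    @property
    def area_ratio(self) -> float:
        return self.area_post / self.area_pre

    @property
    def linear_factor(self) -> float:
        return math.sqrt(self.area_ratio)


def calibrate_expansion(
    area_pre: float,
    area_post: float,
    ratio_is_linear: bool = False,
) -> ExpansionCalibration:
    """Build a calibration from gel areas.

    With ``ratio_is_linear=True`` the area ratio is taken as the linear
    factor itself (some labs report it that way); the returned record is
    then constructed so ``linear_factor`` equals ``area_post/area_pre``.
    """
    if ratio_is_linear:
        lin = area_post / area_pre
        if lin < 1:
            raise ValueError("gel shrank: linear factor below 1")
        return ExpansionCalibration(area_pre=1.0, area_post=lin * lin)
    return ExpansionCalibration(area_pre=area_pre, area_post=area_post)


def apply_calibration(stack: ImageStack, cal: ExpansionCalibration) -> ImageStack:
    """Rescale voxel dimensions to biological units (divide by the linear factor)."""
    f = cal.linear_factor
    return ImageStack(stack.voxels.copy(),
                      tuple(v / f for v in stack.voxel_size),
                      list(stack.channel_names))


@dataclass
class ExMQuant:
    """The four biological-scale cluster metrics plus bookkeeping.

    ``association_ratio`` is ``inf`` (flagged) when every c-Abl voxel is
    mitochondrial; ``mean_cluster_volume_um3`` is NaN (flagged) when no
    cluster survives segmentation.
    """

    cluster_density_per_um3: float
    mean_cluster_volume_um3: float
    association_ratio: float
    occupancy_percent: float
    n_clusters: int
    analyzed_volume_um3: float
    thresholds: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def exm_pipeline(
    stack: ImageStack,
    cal: ExpansionCalibration,
    thresholds: dict[str, float] | None = None,
    cabl_channel: str | int = "cabl",
    mito_channel: str | int = "mito",
    config: PipelineConfig = PipelineConfig(),
    cell_mask: BinaryMask | None = None,
) -> ExMQuant:
    """Smooth, threshold, split by the mitochondrial mask, and measure.

    ``thresholds`` maps channel names to numeric cuts, standing in for
    interactive threshold selection; channels without an entry fall back
    to the Triangle algorithm.  ``cell_mask`` (3D, acquisition geometry)
    restricts the analyzed volume used for cluster density.
    """
    if stack.n_channels < 2:
        raise ValueError("ExM pipeline needs the c-Abl and mitochondrial channels")
    if config.smooth_sigma_um is not None:
        sigma = tuple(config.smooth_sigma_um / v for v in stack.voxel_size)
    else:
        sigma = config.smooth_sigma_vox
    smoothed = smooth_3d(stack, sigma)
    calibrated = apply_calibration(smoothed, cal)
    thresholds = dict(thresholds or {})

    masks: dict[str, BinaryMask] = {}
    used: dict[str, float] = {}
    for ch in (cabl_channel, mito_channel):
        name = ch if isinstance(ch, str) else calibrated.channel_names[ch]
        data = calibrated.channel(ch)
        thr = thresholds.get(name)
        if thr is None:
            thr = triangle_threshold(data).threshold
        used[name] = float(thr)
        masks[name] = binarize(data, thr, voxel_size=calibrated.voxel_size)
    cabl_name = cabl_channel if isinstance(cabl_channel, str) else calibrated.channel_names[cabl_channel]
    mito_name = mito_channel if isinstance(mito_channel, str) else calibrated.channel_names[mito_channel]
    cabl, mito = masks[cabl_name], masks[mito_name]
    if cell_mask is not None:
        restrict = BinaryMask(cell_mask.voxels, calibrated.voxel_size)
        cabl = mask_and(cabl, restrict)
        mito = mask_and(mito, restrict)
        analyzed_volume = restrict.measure_um()
    else:
        analyzed_volume = float(np.prod(calibrated.spatial_shape)) * calibrated.voxel_volume_um3

    flags: list[str] = []
    labels = label_components(cabl, config.connectivity_3d)
    measured = measure_objects(labels, min_size_vox=config.min_size_vox)
    n_clusters = measured.n_objects
    if n_clusters == 0:
        flags.append("empty c-Abl mask: cluster volume undefined")
        mean_volume = float("nan")
    else:
        mean_volume = float(measured.table["size_um"].mean())

    v_in = mask_and(cabl, mito).measure_um()
    v_out = mask_and_not(cabl, mito).measure_um()
    if v_out == 0.0:
        association = float("inf") if v_in > 0 else 0.0
        flags.append("no non-mitochondrial c-Abl volume: association ratio unbounded"
                     if v_in > 0 else "empty c-Abl mask: association ratio 0")
    else:
        association = v_in / v_out
    v_mito = mito.measure_um()
    if v_mito == 0.0:
        occupancy = float("nan")
        flags.append("empty mitochondrial mask: occupancy undefined")
    else:
        occupancy = 100.0 * v_in / v_mito

    return ExMQuant(
        cluster_density_per_um3=n_clusters / analyzed_volume,
        mean_cluster_volume_um3=mean_volume,
        association_ratio=association,
        occupancy_percent=occupancy,
        n_clusters=n_clusters,
        analyzed_volume_um3=analyzed_volume,
        thresholds=used,
        flags=flags,
    )
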
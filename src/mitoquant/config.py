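"""Pipeline defaults, in one place.

The confocal macro constants (median radius 1 px, top-hat radius 5 px,
30 µm neurite segment, 0.1 µm z-step) and the ExM acquisition defaults
(1 µm z-step) are fixed acquisition/processing parameters of the
workflow; everything else is an analysis choice with a documented
default.  A :class:`PipelineConfig` can be loaded from a YAML mapping so
runs are reproducible from a config file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults for every tunable stage of the pipelines.

    Attributes
    ----------
    median_radius_px:
        Disk radius of the despeckling median filter on the z-projection.
    tophat_radius_px:
        Disk radius of the white top-hat that flattens background before
        thresholding; structures wider than the disk are suppressed.
    smooth_sigma_um / smooth_sigma_vox:
        3D pre-threshold Gaussian smoothing for the expansion-microscopy
        pipeline.  The default is physically isotropic
        (``smooth_sigma_um``, acquisition-scale µm): on strongly
        anisotropic grids a voxel-unit sigma would blur the undersampled
        axis by a full step and erode thin objects.  Set
        ``smooth_sigma_um`` to None to fall back to the voxel-unit
        ``smooth_sigma_vox``.
    threshold_method:
        Auto-threshold algorithm for mask creation (``"triangle"``).
    threshold_override:
        Numeric threshold that, when set, bypasses the auto method — the
        reproducible stand-in for interactive threshold selection.
    segment_length_um:
        Length of the neurite segment analysed for object-based
        LC3–mitochondria colocalization.
    confocal_z_step_um / exm_z_step_um:
        Acquisition z-steps of the two imaging modes.
    xy_pixel_um:
        In-plane pixel size used for synthetic fixtures.
    min_size_vox:
        Objects smaller than this many voxels are discarded as shot-noise
        specks (set 0 to keep everything).
    connectivity_2d / connectivity_3d:
        Pixel/voxel adjacency for particle analysis (8 and 26 match common
        particle-counter behaviour).
    area_cut_um2 / frac_cut:
        Fragmentation surrogate: a cell is called fragmented when more
        than ``frac_cut`` of its mitochondrial area sits in objects
        smaller than ``area_cut_um2``.
    coloc_min_overlap_vox:
        Voxels of overlap required to call a mitochondrion LC3-positive.
    """

    median_radius_px: int = 1
    tophat_radius_px: int = 5
    smooth_sigma_um: float | None = 0.2
    smooth_sigma_vox: float = 1.0
    threshold_method: str = "triangle"
    threshold_override: float | None = None
    segment_length_um: float = 30.0
    confocal_z_step_um: float = 0.1
    exm_z_step_um: float = 1.0
    xy_pixel_um: float = 0.1
    min_size_vox: int = 4
    connectivity_2d: int = 8
    connectivity_3d: int = 26
    area_cut_um2: float = 1.0
    frac_cut: float = 0.5
    coloc_min_overlap_vox: int = 1
    expansion_ratio_is_linear: bool = False

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    values: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(loaded) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    return PipelineConfig(**values)
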
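"""Synthetic fluorescence z-stacks with known ground truth.

Every imaging experiment the analysis pipelines target has a generator
here: punctate vs tubular mitochondrial networks (fragmentation
phenotyping and morphometry), neurite scenes with LC3 puncta at an exact
colocalization fraction (object-based mitophagy readout), expanded-scale
two-channel volumes with c-Abl-like clusters at a controlled
mitochondrial-association fraction, and a soma+neurite neuron geometry
for soma masking.  Objects are rendered as uniform-amplitude voxel
supports, optionally blurred by an isotropic Gaussian PSF surrogate and
degraded with Poisson photon noise plus Gaussian read noise; the placed
voxel sets, centroids and parameters are returned as
:class:`SceneTruth`, so recovery by the measurement pipelines can be
tested against construction.

All randomness flows through one ``numpy`` Generator seeded by the
caller: identical parameters and seed give bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage

from .io import ImageStack

__all__ = [
    "NoiseParams",
    "MorphologyParams",
    "SceneTruth",
    "SceneOvercrowdedError",
    "generate_mito_scene",
    "generate_coloc_scene",
    "generate_exm_scene",
    "generate_neuron_scene",
]


class SceneOvercrowdedError(RuntimeError):
    """Raised when non-overlapping placement fails within the retry budget."""


@dataclass(frozen=True)
class NoiseParams:
    """Poisson–Gaussian camera noise model.

    The noise-free intensity ``I`` is converted to expected photons
    ``g·I`` (``g`` = ``photon_gain``, photons per intensity unit), Poisson
    sampled, scaled back, and additive Gaussian read noise of SD
    ``read_noise_sd`` (intensity units) is applied.
    """

    photon_gain: float
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.photon_gain <= 0:
            raise ValueError("photon_gain must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    @classmethod
    def for_snr(cls, snr: float, amplitude: float, background: float,
                read_noise_sd: float = 2.0) -> "NoiseParams":
        """Gain giving peak SNR = amplitude / noise-SD at an object voxel."""
        var_target = (amplitude / snr) ** 2 - read_noise_sd**2
        if var_target <= 0:
            raise ValueError("requested SNR unreachable with this read noise")
        gain = (amplitude + background) / var_target
        return cls(photon_gain=gain, read_noise_sd=read_noise_sd)

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        g = self.photon_gain
        noisy = rng.poisson(img * g).astype(np.float64) / g
        noisy += rng.normal(0.0, self.read_noise_sd, size=img.shape)
        return np.clip(noisy, 0.0, None)


@dataclass(frozen=True)
class MorphologyParams:
    """Geometry and rendering parameters of a mitochondrial scene.

    ``mode`` selects the phenotype: ``"punctate"`` renders discrete
    ellipsoidal blobs (fragmented networks), ``"tubular"`` renders
    dilated random-walk polylines (elongated interconnected networks).
    Lengths and diameters are sampled per object from the given
    mean ± SD (µm).  The default grid is a confocal-style 3-plane stack
    with 0.1 µm isotropic voxels covering a 25.6 µm field.
    """

    mode: str = "punctate"
    n_objects: int = 50
    tubule_length_um: tuple[float, float] = (5.0, 1.0)
    tubule_radius_um: float = 0.15
    blob_diameter_um: tuple[float, float] = (0.5, 0.1)
    intensity_amplitude: float = 100.0
    background_level: float = 10.0
    psf_sigma_um: float = 0.0
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    stack_shape: tuple[int, int, int] = (3, 256, 256)
    noise: NoiseParams | None = None
    min_gap_um: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("punctate", "tubular"):
            raise ValueError(f"mode must be 'punctate' or 'tubular', got {self.mode!r}")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        for name in ("tubule_radius_um", "intensity_amplitude", "min_gap_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if any(v <= 0 for v in self.voxel_size) or any(s <= 0 for s in self.stack_shape):
            raise ValueError("voxel_size and stack_shape must be positive")


@dataclass
class SceneTruth:
    """Ground truth of a generated scene, recorded at construction time.

    ``object_voxel_sets[channel]`` holds one ``(n, 3)`` integer index
    array per placed object; centroids are physical (µm).  For expanded
    scenes, coordinates and volumes are at biological scale while the
    rendered stack is at expanded scale.  ``extras`` carries
    scene-specific arrays (soma mask, neurite centerline, segment mask,
    mitochondrial truth mask, per-object amplitudes).
    """

    n_objects_per_channel: dict[str, int] = field(default_factory=dict)
    object_centroids: dict[str, list[tuple[float, ...]]] = field(default_factory=dict)
    object_voxel_sets: dict[str, list[np.ndarray]] = field(default_factory=dict)
    true_coloc_fraction: float | None = None
    true_cluster_volumes_um3: list[float] | None = None
    true_expansion_factor_linear: float | None = None
    phenotype_label: str | None = None
    noise_params: NoiseParams | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def channel_mask(self, channel: str, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean union of the truth voxel sets of one channel."""
        out = np.zeros(shape, dtype=bool)
        for idx in self.object_voxel_sets.get(channel, []):
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out


# --------------------------------------------------------------------------
# placement and rasterization helpers

def _ellipsoid_indices(center_vox: np.ndarray, radii_vox: np.ndarray,
                       shape: tuple[int, ...]) -> np.ndarray:
    """Voxel indices whose centers lie inside an axis-aligned ellipsoid."""
    lo = np.maximum(np.floor(center_vox - radii_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + radii_vox).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return np.zeros((0, len(shape)), dtype=np.int64)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(len(shape))], indexing="ij")
    r2 = sum(((g - c) / max(r, 1e-9)) ** 2 for g, c, r in zip(grids, center_vox, radii_vox))
    sel = r2 <= 1.0
    return np.stack([g[sel] for g in grids], axis=1).astype(np.int64)


def _polyline_indices(points_vox: np.ndarray, radii_vox: np.ndarray,
                      shape: tuple[int, ...]) -> np.ndarray:
    """Union of small ellipsoids stamped along a polyline (a dilated tube)."""
    parts = [_ellipsoid_indices(p, radii_vox, shape) for p in points_vox]
    if not parts:
        return np.zeros((0, len(shape)), dtype=np.int64)
    allpts = np.concatenate(parts, axis=0)
    # dedupe via flat raster keys: row-wise unique on (n, 3) is far slower
    flat = np.unique(np.ravel_multi_index(tuple(allpts.T), shape))
    return np.stack(np.unravel_index(flat, shape), axis=1).astype(np.int64)


class _Placer:
    """Tracks occupied-plus-gap space so objects stay disjoint and separated."""

    def __init__(self, shape: tuple[int, int, int], retry_budget: int):
        self.shape = shape
        self.forbidden = np.zeros(shape, dtype=bool)
        self.attempts_left = retry_budget

    def try_place(self, voxels: np.ndarray, halo: np.ndarray) -> bool:
        self.attempts_left -= 1
        if self.attempts_left < 0:
            raise SceneOvercrowdedError("scene overcrowded: placement retry budget exhausted")
        if voxels.shape[0] == 0:
            return False
        if self.forbidden[voxels[:, 0], voxels[:, 1], voxels[:, 2]].any():
            return False
        self.forbidden[halo[:, 0], halo[:, 1], halo[:, 2]] = True
        return True


def _render(shape: tuple[int, int, int], voxel_size: tuple[float, float, float],
            channels: dict[str, list[tuple[np.ndarray, float]]],
            background: float, psf_sigma_um: float,
            noise: NoiseParams | None, rng: np.random.Generator,
            channel_names: list[str]) -> ImageStack:
    """Paint per-object supports, add background, blur, then add noise."""
    stack = np.full((len(channel_names), *shape), float(background))
    for c, name in enumerate(channel_names):
        for idx, amp in channels.get(name, []):
            if idx.shape[0]:
                stack[c, idx[:, 0], idx[:, 1], idx[:, 2]] = background + amp
    if psf_sigma_um > 0:
        sigma_vox = tuple(psf_sigma_um / v for v in voxel_size)
        for c in range(stack.shape[0]):
            stack[c] = ndimage.gaussian_filter(stack[c], sigma=sigma_vox, mode="reflect")
    if noise is not None:
        for c in range(stack.shape[0]):
            stack[c] = noise.apply(stack[c], rng)
    return ImageStack(stack, voxel_size, channel_names)


def _sample_blob_radii(params: MorphologyParams, rng: np.random.Generator) -> np.ndarray:
    mean, sd = params.blob_diameter_um
    # floor keeps the median-projection footprint above the speck filter
    d = max(float(rng.normal(mean, sd)), 0.4)
    return np.array([d / 2 / v for v in params.voxel_size])


def _punctum(params: MorphologyParams, rng: np.random.Generator,
             placer: _Placer, gap_vox: np.ndarray,
             x_range_vox: tuple[float, float] | None = None,
             y_range_vox: tuple[float, float] | None = None) -> np.ndarray:
    """Place one non-overlapping ellipsoidal punctum; returns its voxel indices."""
    shape = params.stack_shape
    while True:
        radii = _sample_blob_radii(params, rng)
        margin = radii + 1
        zc = shape[0] / 2 - 0.5 if shape[0] <= 3 else rng.uniform(margin[0], shape[0] - 1 - margin[0])
        ylo, yhi = y_range_vox or (margin[1], shape[1] - 1 - margin[1])
        xlo, xhi = x_range_vox or (margin[2], shape[2] - 1 - margin[2])
        center = np.array([zc, rng.uniform(ylo, yhi), rng.uniform(xlo, xhi)])
        vox = _ellipsoid_indices(center, radii, shape)
        halo = _ellipsoid_indices(center, radii + gap_vox, shape)
        if vox.shape[0] and placer.try_place(vox, halo):
            return vox


def _tubule(params: MorphologyParams, rng: np.random.Generator,
            placer: _Placer, gap_vox: np.ndarray) -> np.ndarray:
    """Place one tubule as a dilated persistent random walk in the xy plane."""
    shape = params.stack_shape
    dz, dy, dx = params.voxel_size
    r_vox = np.array([params.tubule_radius_um / dz, params.tubule_radius_um / dy,
                      params.tubule_radius_um / dx])
    if shape[0] <= 3:  # thin stack: let the tubule span all planes
        r_vox[0] = max(r_vox[0], shape[0])
    step_um = dx  # one in-plane voxel per step
    mean, sd = params.tubule_length_um
    while True:
        length = max(float(rng.normal(mean, sd)), 1.0)
        n_steps = max(int(round(length / step_um)), 2)
        margin = r_vox + 1
        zc = shape[0] / 2 - 0.5 if shape[0] <= 3 else rng.uniform(margin[0], shape[0] - 1 - margin[0])
        pos = np.array([zc,
                        rng.uniform(margin[1], shape[1] - 1 - margin[1]),
                        rng.uniform(margin[2], shape[2] - 1 - margin[2])])
        theta = rng.uniform(0, 2 * math.pi)
        pts = [pos.copy()]
        ok = True
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.25)  # direction persistence
            pos = pos + np.array([0.0, math.sin(theta), math.cos(theta)])
            if not (margin[1] <= pos[1] <= shape[1] - 1 - margin[1]
                    and margin[2] <= pos[2] <= shape[2] - 1 - margin[2]):
                ok = False
                break
            pts.append(pos.copy())
        if not ok:
            placer.attempts_left -= 1
            if placer.attempts_left < 0:
                raise SceneOvercrowdedError("scene overcrowded: placement retry budget exhausted")
            continue
        pts = np.asarray(pts)
        vox = _polyline_indices(pts, r_vox, shape)
        halo = _polyline_indices(pts, r_vox + gap_vox, shape)
        if vox.shape[0] and placer.try_place(vox, halo):
            return vox


def _centroid_um(vox: np.ndarray, voxel_size: tuple[float, ...]) -> tuple[float, ...]:
    return tuple(float(m) for m in vox.mean(axis=0) * np.asarray(voxel_size))


# --------------------------------------------------------------------------
# scene generators

def generate_mito_scene(
    params: MorphologyParams,
    seed: int,
    second_channel: bool = False,
) -> tuple[ImageStack, SceneTruth]:
    """One cell's mitochondrial network with known object placements.

    Returns a single-channel stack (``mito``), or with
    ``second_channel=True`` a two-channel stack whose second channel
    (``potential``) re-renders the same objects with an independent
    per-object intensity scaling, emulating a membrane-potential-dependent
    dye next to a structural marker.
    """
    rng = np.random.default_rng(seed)
    shape = params.stack_shape
    gap_vox = np.array([params.min_gap_um / v for v in params.voxel_size])
    placer = _Placer(shape, retry_budget=max(100 * params.n_objects, 100))

    objects: list[np.ndarray] = []
    for _ in range(params.n_objects):
        if params.mode == "punctate":
            objects.append(_punctum(params, rng, placer, gap_vox))
        else:
            objects.append(_tubule(params, rng, placer, gap_vox))

    names = ["mito"]
    channels = {"mito": [(v, params.intensity_amplitude) for v in objects]}
    truth = SceneTruth(
        n_objects_per_channel={"mito": len(objects)},
        object_centroids={"mito": [_centroid_um(v, params.voxel_size) for v in objects]},
        object_voxel_sets={"mito": objects},
        phenotype_label="fragmented" if params.mode == "punctate" else "tubular",
        noise_params=params.noise,
    )
    if second_channel:
        names.append("potential")
        scales = rng.uniform(0.4, 1.0, size=len(objects))
        channels["potential"] = [
            (v, params.intensity_amplitude * s) for v, s in zip(objects, scales)
        ]
        truth.n_objects_per_channel["potential"] = len(objects)
        truth.object_centroids["potential"] = list(truth.object_centroids["mito"])
        truth.object_voxel_sets["potential"] = objects
        truth.extras["potential_scales"] = scales

    stack = _render(shape, params.voxel_size, channels, params.background_level,
                    params.psf_sigma_um, params.noise, rng, names)
    return stack, truth


def generate_coloc_scene(
    n_mito: int,
    coloc_fraction: float,
    geometry: MorphologyParams | None = None,
    seed: int = 0,
    lc3_diameter_um: tuple[float, float] = (0.4, 0.05),
    n_decoy_lc3: int | None = None,
    segment_length_um: float = 30.0,
    neurite_width_um: float = 3.0,
) -> tuple[ImageStack, SceneTruth]:
    """Mitochondria and LC3 puncta on a neurite strip at an exact overlap fraction.

    Exactly ``k = round(coloc_fraction · n_mito)`` mitochondria receive an
    LC3 punctum centred on them (guaranteeing ≥ 1 shared voxel); the
    remaining LC3 puncta are decoys placed clear of every mitochondrion.
    The truth records the analysis segment mask so the downstream
    colocalization readout can be checked against ``k / n_mito``.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    if n_mito < 0:
        raise ValueError("n_mito must be >= 0")
    if geometry is None:
        # dense neurite packing: a small clearance is enough without optics
        geometry = MorphologyParams(mode="punctate", n_objects=n_mito,
                                    stack_shape=(3, 128, 384), min_gap_um=0.2)
    rng = np.random.default_rng(seed)
    shape = geometry.stack_shape
    dz, dy, dx = geometry.voxel_size
    if shape[2] * dx < segment_length_um:
        raise ValueError("stack is shorter than the analysis segment")

    # horizontal neurite strip through the middle of the field
    y_mid = shape[1] / 2
    half_w = neurite_width_um / 2 / dy
    seg_len_vox = segment_length_um / dx
    x0 = (shape[2] - seg_len_vox) / 2
    x1 = x0 + seg_len_vox
    k = int(round(coloc_fraction * n_mito))

    gap_um = geometry.min_gap_um + lc3_diameter_um[0] / 2  # keep LC3-on-A clear of mito B
    gap_vox = np.array([gap_um / v for v in geometry.voxel_size])
    placer = _Placer(shape, retry_budget=max(100 * (n_mito + 10), 200))

    mito: list[np.ndarray] = []
    for _ in range(n_mito):
        mito.append(_punctum(geometry, rng, placer, gap_vox,
                             x_range_vox=(x0 + 2, x1 - 2),
                             y_range_vox=(y_mid - half_w + 1, y_mid + half_w - 1)))

    lc3: list[np.ndarray] = []
    lc3_geom = replace(geometry, blob_diameter_um=lc3_diameter_um)
    which = rng.permutation(n_mito)[:k] if n_mito else np.array([], dtype=int)
    for i in which:
        center = mito[i].mean(axis=0)  # centre the punctum on the mitochondrion
        radii = _sample_blob_radii(lc3_geom, rng)
        vox = _ellipsoid_indices(center, radii, shape)
        if vox.shape[0] == 0:  # degenerate sampling: fall back to one shared voxel
            vox = mito[i][:1].copy()
        lc3.append(vox)
    n_decoys = n_decoy_lc3 if n_decoy_lc3 is not None else max(n_mito - k, 0)
    for _ in range(n_decoys):
        lc3.append(_punctum(lc3_geom, rng, placer, gap_vox))

    zz, yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             np.arange(shape[2]), indexing="ij")
    segment_mask = ((np.abs(yy - y_mid) <= half_w) & (xx >= x0) & (xx <= x1))

    channels = {
        "mito": [(v, geometry.intensity_amplitude) for v in mito],
        "lc3": [(v, geometry.intensity_amplitude) for v in lc3],
    }
    stack = _render(shape, geometry.voxel_size, channels, geometry.background_level,
                    geometry.psf_sigma_um, geometry.noise, rng, ["mito", "lc3"])
    truth = SceneTruth(
        n_objects_per_channel={"mito": n_mito, "lc3": len(lc3)},
        object_centroids={
            "mito": [_centroid_um(v, geometry.voxel_size) for v in mito],
            "lc3": [_centroid_um(v, geometry.voxel_size) for v in lc3],
        },
        object_voxel_sets={"mito": mito, "lc3": lc3},
        true_coloc_fraction=(k / n_mito) if n_mito else None,
        noise_params=geometry.noise,
        extras={
            "segment_mask": segment_mask,
            "segment_length_um": segment_length_um,
            "n_positive": k,
        },
    )
    return stack, truth


def generate_exm_scene(
    cluster_density: float,
    mean_cluster_volume: float,
    assoc_fraction: float,
    expansion_factor_linear: float,
    seed: int = 0,
    bio_extent_um: tuple[float, float, float] = (10.0, 9.6, 9.6),
    voxel_size: tuple[float, float, float] = (1.0, 0.1, 0.1),
    n_empty_mito_regions: int = 2,
    mito_radius_um: float = 1.2,
    mito_shell_um: float = 0.4,
    intensity_amplitude: float = 100.0,
    background_level: float = 10.0,
    noise: NoiseParams | None = None,
    volume_cv: float = 0.25,
) -> tuple[ImageStack, SceneTruth]:
    """An expanded two-channel volume: c-Abl-like clusters vs a mitochondrial mask.

    The specimen is laid out entirely at biological scale — sphere
    centres and radii inside ``bio_extent_um`` — so one seed defines one
    biological scene regardless of the expansion factor; rendering then
    multiplies all coordinates by ``expansion_factor_linear`` and samples
    them on the acquisition grid ``voxel_size`` (expanded-scale µm).
    ``round(density · Ω)`` spherical clusters with volumes drawn around
    ``mean_cluster_volume`` (biological µm³) are placed.  A fraction
    ``assoc_fraction`` of them is mitochondrial by construction: each
    such cluster is wrapped in a mitochondrial blob extending
    ``mito_shell_um`` beyond its surface (mitochondria enveloping
    recruited clusters), and ``n_empty_mito_regions`` cluster-free
    mitochondrial spheres of radius ``mito_radius_um`` are added; the
    remaining clusters stay strictly outside the mitochondrial mask.
    Clearances are anisotropic (wider along z, where the 1 µm step
    undersamples gaps) so smoothed clusters never merge.  Truth
    (centroids, volumes) is recorded at biological scale.
    """
    if expansion_factor_linear <= 1:
        raise ValueError("expansion_factor_linear must be > 1")
    if not 0.0 <= assoc_fraction <= 1.0:
        raise ValueError("assoc_fraction must lie in [0, 1]")
    if cluster_density < 0 or mean_cluster_volume <= 0:
        raise ValueError("cluster_density must be >= 0 and mean_cluster_volume > 0")
    f = float(expansion_factor_linear)
    extent = np.asarray(bio_extent_um, dtype=float)
    omega = float(np.prod(extent))
    n_clusters = int(round(cluster_density * omega))
    if cluster_density > 0 and n_clusters < 1:
        raise ValueError("density × volume yields < 1 expected cluster")
    n_assoc = int(round(assoc_fraction * n_clusters))

    rng = np.random.default_rng(seed)
    gap_z, gap_xy = 1.0, 0.3  # biological µm

    def directional_gap(delta: np.ndarray) -> float:
        d = np.linalg.norm(delta)
        uz2 = (delta[0] / d) ** 2 if d > 0 else 1.0
        return math.sqrt(gap_z**2 * uz2 + gap_xy**2 * (1 - uz2))

    # biological-scale layout: (center, radius, kind) with kind the
    # exclusion radius used against later placements
    placed: list[tuple[np.ndarray, float]] = []  # (center, hard radius incl. shell)

    def far_enough(center: np.ndarray, radius: float) -> bool:
        for c0, r0 in placed:
            delta = center - c0
            if np.linalg.norm(delta) < radius + r0 + directional_gap(delta):
                return False
        return True

    budget = max(200 * (n_clusters + n_empty_mito_regions), 400)

    def place(radius: float, margin: float) -> np.ndarray:
        nonlocal budget
        lo = margin
        hi = extent - margin
        if np.any(lo >= hi):
            raise ValueError("object does not fit the biological extent")
        while True:
            budget -= 1
            if budget < 0:
                raise SceneOvercrowdedError(
                    "scene overcrowded: placement retry budget exhausted")
            center = rng.uniform(lo, hi)
            if far_enough(center, radius):
                return center

    def sample_radius() -> tuple[float, float]:
        v_bio = max(float(rng.normal(mean_cluster_volume, volume_cv * mean_cluster_volume)),
                    0.1 * mean_cluster_volume)
        return v_bio, (3 * v_bio / (4 * math.pi)) ** (1 / 3)

    cluster_spheres: list[tuple[np.ndarray, float]] = []
    volumes_bio: list[float] = []
    mito_spheres: list[tuple[np.ndarray, float]] = []

    for _ in range(n_assoc):  # wrapped in a mitochondrial shell
        v_bio, r = sample_radius()
        center = place(r + mito_shell_um, r + mito_shell_um + gap_xy)
        placed.append((center, r + mito_shell_um))
        cluster_spheres.append((center, r))
        volumes_bio.append(v_bio)
        mito_spheres.append((center, r + mito_shell_um))
    for _ in range(n_empty_mito_regions):  # cluster-free mitochondria
        center = place(mito_radius_um, mito_radius_um + gap_xy)
        placed.append((center, mito_radius_um))
        mito_spheres.append((center, mito_radius_um))
    for _ in range(n_clusters - n_assoc):  # strictly non-mitochondrial
        v_bio, r = sample_radius()
        center = place(r, r + gap_xy)
        placed.append((center, r))
        cluster_spheres.append((center, r))
        volumes_bio.append(v_bio)

    # rasterize at expanded scale
    vz = np.asarray(voxel_size, dtype=float)
    shape = tuple(int(round(e * f / v)) for e, v in zip(extent, vz))
    clusters = [_ellipsoid_indices(c * f / vz, np.full(3, r) * f / vz, shape)
                for c, r in cluster_spheres]
    mito_regions = [_ellipsoid_indices(c * f / vz, np.full(3, r) * f / vz, shape)
                    for c, r in mito_spheres]
    mito_mask = np.zeros(shape, dtype=bool)
    for vox in mito_regions:
        mito_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True

    channels = {
        "cabl": [(v, intensity_amplitude) for v in clusters],
        "mito": [(v, intensity_amplitude) for v in mito_regions],
    }
    stack = _render(shape, tuple(vz), channels, background_level,
                    psf_sigma_um=0.0, noise=noise, rng=rng,
                    channel_names=["cabl", "mito"])
    truth = SceneTruth(
        n_objects_per_channel={"cabl": n_clusters, "mito": len(mito_regions)},
        object_centroids={
            "cabl": [tuple(c) for c, _ in cluster_spheres],
            "mito": [tuple(c) for c, _ in mito_spheres],
        },
        object_voxel_sets={"cabl": clusters, "mito": mito_regions},
        true_cluster_volumes_um3=volumes_bio,
        true_expansion_factor_linear=f,
        noise_params=noise,
        extras={
            "mito_mask": mito_mask,
            "bio_volume_um3": omega,
            "true_cluster_density_per_um3": n_clusters / omega,
            "assoc_fraction": assoc_fraction,
            "n_assoc": n_assoc,
            "intensity_amplitude": intensity_amplitude,
            "background_level": background_level,
        },
    )
    return stack, truth


def generate_neuron_scene(
    soma_radius_um: float = 8.0,
    neurite_length_um: float = 40.0,
    seed: int = 0,
    neurite_radius_um: float = 0.8,
    n_mito: int = 12,
    n_lc3: int = 8,
    coloc_fraction: float = 0.5,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
    intensity_amplitude: float = 100.0,
    background_level: float = 10.0,
    psf_sigma_um: float = 0.0,
    noise: NoiseParams | None = None,
    mito_in_neurite: bool = True,
) -> tuple[ImageStack, SceneTruth]:
    """A neuron: filled soma + straight neurite (tubulin), mitochondria, LC3.

    Channels are ``tubulin`` (soma ∪ neurite support), ``mito`` and
    ``lc3``; mitochondria sit along the neurite (or only in the soma when
    ``mito_in_neurite=False``, the degenerate empty-segment case).  Truth
    carries the soma mask, the neurite centerline voxels, and a 30 µm
    segment mask starting at the soma edge.
    """
    if soma_radius_um <= 0 or neurite_length_um <= 0:
        raise ValueError("geometry dimensions must be > 0")
    if neurite_length_um < 30.0:
        raise ValueError("neurite_length_um must be >= 30 so a full analysis segment exists")
    dz, dy, dx = voxel_size
    margin_um = 1.0
    nx = int(round((2 * soma_radius_um + neurite_length_um + 2 * margin_um) / dx))
    ny = int(round((2 * soma_radius_um + 2 * margin_um) / dy))
    shape = (3, ny, nx)
    rng = np.random.default_rng(seed)

    y_mid = ny / 2 - 0.5
    soma_cx = (margin_um + soma_radius_um) / dx
    soma_center = np.array([shape[0] / 2 - 0.5, y_mid, soma_cx])
    # z-radius far beyond the stack: the soma fills every plane uniformly
    soma_r_vox = np.array([1e6, soma_radius_um / dy, soma_radius_um / dx])
    if soma_center[2] + soma_r_vox[2] >= nx or soma_r_vox[1] >= ny / 2:
        raise SceneOvercrowdedError("scene overcrowded: soma does not fit the stack")
    soma_vox = _ellipsoid_indices(soma_center, soma_r_vox, shape)

    # straight neurite along +x from the soma edge
    x_start = soma_center[2]
    x_end = x_start + (soma_radius_um + neurite_length_um) / dx
    if x_end >= nx - 1:
        raise SceneOvercrowdedError("scene overcrowded: neurite does not fit the stack")
    xs = np.arange(int(round(x_start)), int(round(x_end)) + 1)
    centerline = np.stack([np.full_like(xs, shape[0] // 2), np.full_like(xs, int(round(y_mid))), xs], axis=1)
    r_n = np.array([1e6, neurite_radius_um / dy, neurite_radius_um / dx])
    neurite_vox = _polyline_indices(
        np.stack([np.full(xs.shape, soma_center[0]), np.full(xs.shape, y_mid), xs], axis=1),
        r_n, shape)
    tubulin_mask = np.zeros(shape, dtype=bool)
    tubulin_mask[soma_vox[:, 0], soma_vox[:, 1], soma_vox[:, 2]] = True
    tubulin_mask[neurite_vox[:, 0], neurite_vox[:, 1], neurite_vox[:, 2]] = True
    tubulin_vox = np.argwhere(tubulin_mask)

    # 30 µm analysis segment starting at the soma edge
    seg_x0 = soma_center[2] + soma_radius_um / dx
    seg_x1 = seg_x0 + 30.0 / dx
    zz, yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(ny), np.arange(nx), indexing="ij")
    seg_half_w = (neurite_radius_um + 0.3) / dy
    segment_mask = (np.abs(yy - y_mid) <= seg_half_w) & (xx >= seg_x0) & (xx <= seg_x1)

    geom = MorphologyParams(mode="punctate", n_objects=0, voxel_size=voxel_size,
                            stack_shape=shape, intensity_amplitude=intensity_amplitude,
                            background_level=background_level, psf_sigma_um=psf_sigma_um,
                            noise=noise)
    gap_vox = np.array([geom.min_gap_um / v for v in voxel_size]) + np.array(
        [0.4 / v for v in voxel_size])
    placer = _Placer(shape, retry_budget=max(100 * (n_mito + n_lc3), 200))
    soma_y = (y_mid - soma_r_vox[1] * 0.6, y_mid + soma_r_vox[1] * 0.6)
    soma_x = (soma_center[2] - soma_r_vox[2] * 0.6, soma_center[2] + soma_r_vox[2] * 0.6)
    mito: list[np.ndarray] = []
    for _ in range(n_mito):
        if mito_in_neurite:
            vox = _punctum(geom, rng, placer, gap_vox,
                           x_range_vox=(seg_x0 + 4, seg_x1 - 4),
                           y_range_vox=(y_mid - 2, y_mid + 2))
        else:
            vox = _punctum(geom, rng, placer, gap_vox, x_range_vox=soma_x, y_range_vox=soma_y)
        mito.append(vox)
    k = int(round(coloc_fraction * n_mito)) if mito_in_neurite else 0
    lc3: list[np.ndarray] = []
    lc3_geom = replace(geom, blob_diameter_um=(0.4, 0.05))
    for i in (rng.permutation(n_mito)[:k] if n_mito else []):
        center = mito[i].mean(axis=0)
        vox = _ellipsoid_indices(center, _sample_blob_radii(lc3_geom, rng), shape)
        lc3.append(vox if vox.shape[0] else mito[i][:1].copy())
    for _ in range(max(n_lc3 - k, 0)):
        lc3.append(_punctum(lc3_geom, rng, placer, gap_vox))

    channels = {
        "tubulin": [(tubulin_vox, intensity_amplitude)],
        "mito": [(v, intensity_amplitude) for v in mito],
        "lc3": [(v, intensity_amplitude) for v in lc3],
    }
    stack = _render(shape, voxel_size, channels, background_level, psf_sigma_um,
                    noise, rng, ["tubulin", "mito", "lc3"])
    soma_mask = np.zeros(shape, dtype=bool)
    soma_mask[soma_vox[:, 0], soma_vox[:, 1], soma_vox[:, 2]] = True
    truth = SceneTruth(
        n_objects_per_channel={"tubulin": 1, "mito": n_mito, "lc3": len(lc3)},
        object_centroids={"mito": [_centroid_um(v, voxel_size) for v in mito]},
        object_voxel_sets={"tubulin": [tubulin_vox], "mito": mito, "lc3": lc3},
        true_coloc_fraction=(k / n_mito) if n_mito else None,
        noise_params=noise,
        extras={
            "soma_mask": soma_mask,
            "neurite_centerline": centerline,
            "segment_mask": segment_mask,
            "segment_length_um": 30.0,
            "n_positive": k,
        },
    )
    return stack, truth
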
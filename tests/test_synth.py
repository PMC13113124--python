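"""Scene-generator contracts: determinism, truth bookkeeping, conservation."""

import numpy as np
import pytest

from mitoquant import (
    MorphologyParams,
    NoiseParams,
    SceneOvercrowdedError,
    generate_coloc_scene,
    generate_exm_scene,
    generate_mito_scene,
    generate_neuron_scene,
)


def test_empty_scene_is_constant_background():
    params = MorphologyParams(n_objects=0, background_level=10.0)
    stack, truth = generate_mito_scene(params, seed=3)
    assert np.all(stack.voxels == 10.0)
    assert truth.n_objects_per_channel["mito"] == 0
    assert truth.object_voxel_sets["mito"] == []


@pytest.mark.parametrize("mode", ["punctate", "tubular"])
def test_determinism_and_seed_sensitivity(mode):
    params = MorphologyParams(mode=mode, n_objects=8)
    s1, t1 = generate_mito_scene(params, seed=1)
    s1b, _ = generate_mito_scene(params, seed=1)
    s2, t2 = generate_mito_scene(params, seed=2)
    assert np.array_equal(s1.voxels, s1b.voxels)
    assert not np.array_equal(s1.voxels, s2.voxels)
    assert t1.object_centroids["mito"] != t2.object_centroids["mito"]


def test_truth_bookkeeping_invariants():
    params = MorphologyParams(n_objects=30)
    stack, truth = generate_mito_scene(params, seed=5)
    sets = truth.object_voxel_sets["mito"]
    assert truth.n_objects_per_channel["mito"] == len(sets) == 30
    assert len(truth.object_centroids["mito"]) == 30
    shape = stack.spatial_shape
    seen = np.zeros(shape, dtype=int)
    for vox in sets:
        assert vox.shape[0] > 0
        assert np.all(vox >= 0) and np.all(vox < np.array(shape))
        seen[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    assert seen.max() == 1  # disjoint unless overlap requested


def test_intensity_conservation_noise_free():
    params = MorphologyParams(n_objects=12, psf_sigma_um=0.0, noise=None,
                              background_level=7.0, intensity_amplitude=55.0)
    stack, truth = generate_mito_scene(params, seed=9)
    n_vox = np.prod(stack.spatial_shape)
    n_obj_vox = sum(v.shape[0] for v in truth.object_voxel_sets["mito"])
    expected = 55.0 * n_obj_vox + 7.0 * n_vox
    assert stack.voxels[0].sum() == pytest.approx(expected, rel=1e-12)


def test_second_channel_shares_geometry():
    params = MorphologyParams(n_objects=6)
    stack, truth = generate_mito_scene(params, seed=2, second_channel=True)
    assert stack.channel_names == ["mito", "potential"]
    assert truth.n_objects_per_channel["potential"] == 6
    assert len(truth.extras["potential_scales"]) == 6


def test_overcrowded_scene_raises():
    params = MorphologyParams(n_objects=300, stack_shape=(3, 32, 32))
    with pytest.raises(SceneOvercrowdedError, match="overcrowded"):
        generate_mito_scene(params, seed=0)


def test_validation_errors():
    with pytest.raises(ValueError):
        MorphologyParams(n_objects=-1)
    with pytest.raises(ValueError):
        MorphologyParams(mode="weird")
    with pytest.raises(ValueError):
        generate_coloc_scene(10, 1.2, seed=0)
    with pytest.raises(ValueError):
        generate_exm_scene(0.015, 2.0, 0.5, expansion_factor_linear=0.9, seed=0)
    with pytest.raises(ValueError):
        NoiseParams(photon_gain=-1)


def test_coloc_scene_exact_positive_count():
    stack, truth = generate_coloc_scene(10, 0.4, seed=1)
    assert truth.extras["n_positive"] == 4
    assert truth.true_coloc_fraction == pytest.approx(0.4)
    shape = stack.spatial_shape
    mito = truth.channel_mask("mito", shape)
    lc3 = truth.channel_mask("lc3", shape)
    positive = sum((mito[v[:, 0], v[:, 1], v[:, 2]]).any()
                   for v in truth.object_voxel_sets["lc3"])
    assert positive == 4


def test_coloc_fraction_zero_means_no_overlap():
    stack, truth = generate_coloc_scene(12, 0.0, seed=6)
    shape = stack.spatial_shape
    mito = truth.channel_mask("mito", shape)
    lc3 = truth.channel_mask("lc3", shape)
    assert not (mito & lc3).any()


def test_exm_full_association_is_subset_of_mito_mask():
    stack, truth = generate_exm_scene(0.01, 2.0, 1.0, 4.0, seed=3)
    mito_mask = truth.extras["mito_mask"]
    for vox in truth.object_voxel_sets["cabl"]:
        assert mito_mask[vox[:, 0], vox[:, 1], vox[:, 2]].all()


def test_exm_realized_count_matches_density():
    d, extent = 0.015, (10.0, 9.6, 9.6)
    stack, truth = generate_exm_scene(d, 2.0, 0.5, 2.0, seed=4, bio_extent_um=extent)
    omega = np.prod(extent)
    assert truth.n_objects_per_channel["cabl"] == round(d * omega)
    assert truth.extras["true_cluster_density_per_um3"] == pytest.approx(
        round(d * omega) / omega)


def test_exm_rendered_separations_scale_with_expansion():
    f = 4.0
    stack, truth = generate_exm_scene(0.01, 2.0, 0.0, f, seed=8)
    vz = np.array(stack.voxel_size)
    rendered = [v.mean(axis=0) * vz for v in truth.object_voxel_sets["cabl"]]
    bio = [np.array(c) for c in truth.object_centroids["cabl"]]
    for i in range(len(bio) - 1):
        d_r = np.linalg.norm(rendered[i] - rendered[i + 1])
        d_b = np.linalg.norm(bio[i] - bio[i + 1])
        # voxelized centroids approximate the exact expanded centres
        assert d_r / d_b == pytest.approx(f, rel=0.02)


def test_neuron_scene_geometry():
    stack, truth = generate_neuron_scene(soma_radius_um=8.0, neurite_length_um=40.0, seed=1)
    assert stack.channel_names == ["tubulin", "mito", "lc3"]
    # noise-free: tubulin foreground equals the truth soma∪neurite support
    tub_mask = truth.channel_mask("tubulin", stack.spatial_shape)
    assert np.array_equal(stack.channel("tubulin") > 10.0, tub_mask)
    # 30 µm segment at 0.1 µm pixels spans 300 voxels along x
    seg = truth.extras["segment_mask"]
    xs = np.nonzero(seg.any(axis=(0, 1)))[0]
    assert xs.max() - xs.min() == pytest.approx(300, abs=1)
    with pytest.raises(ValueError):
        generate_neuron_scene(neurite_length_um=20.0, seed=0)


def test_noise_model_snr_construction():
    np_ = NoiseParams.for_snr(5.0, 100.0, 10.0)
    rng = np.random.default_rng(0)
    flat = np.full((64, 64), 110.0)
    noisy = np_.apply(flat, rng)
    measured_snr = 100.0 / noisy.std()
    assert measured_snr == pytest.approx(5.0, rel=0.1)
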
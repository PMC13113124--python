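"""Filtering and thresholding operators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from mitoquant import (
    DegenerateHistogramError,
    Image2D,
    ImageStack,
    binarize,
    median_filter,
    project_z,
    smooth_3d,
    tophat_white,
    triangle_threshold,
)

PX = (0.1, 0.1)


def _disk_offsets(radius):
    offs = [(dy, dx) for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dy * dy + dx * dx <= radius * radius]
    return offs


def _reflect(i, n):
    # half-sample symmetric reflection, as used by scipy's 'reflect' mode
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def _neighborhood_values(img, y, x, offsets):
    ny, nx = img.shape
    return [img[_reflect(y + dy, ny), _reflect(x + dx, nx)] for dy, dx in offsets]


def triangle_oracle(hist):
    """Exhaustive per-bin perpendicular-distance maximization."""
    h = np.asarray(hist, float) / max(hist)
    peak = min(i for i, v in enumerate(h) if v == h.max())
    nz = [i for i, v in enumerate(hist) if v > 0]
    left, right = nz[0], nz[-1]
    tail = right if (right - peak) >= (peak - left) else left
    lo, hi = sorted((peak, tail))
    # line through (peak, h[peak]) and (tail, h[tail]): a·x + b·y + c = 0
    a = h[tail] - h[peak]
    b = peak - tail
    c = -(a * peak + b * h[peak])
    best_bin, best_d = None, -1.0
    for bin_ in range(lo, hi + 1):
        d = abs(a * bin_ + b * h[bin_] + c) / np.hypot(a, b)
        if d > best_d + 1e-15:
            best_d, best_bin = d, bin_
    return best_bin


# --------------------------------------------------------------------------
# z-projection

def test_project_z_order_statistics():
    vox = np.zeros((1, 3, 2, 2))
    vox[0, :, 0, 0] = [1, 2, 9]
    vox[0, :, 0, 1] = [5, 5, 5]
    stack = ImageStack(vox, (0.1, 0.1, 0.1))
    med = project_z(stack, 0, "median")
    mx = project_z(stack, 0, "max")
    assert med.pixels[0, 0] == 2 and mx.pixels[0, 0] == 9
    assert med.pixels[0, 1] == 5 and mx.pixels[0, 1] == 5
    assert med.pixel_size == (0.1, 0.1)


def test_project_z_matches_per_pixel_sort(rng):
    vox = rng.random((1, 3, 7, 5)) * 50
    stack = ImageStack(vox, (0.1, 0.1, 0.1))
    med = project_z(stack, 0, "median").pixels
    for y in range(7):
        for x in range(5):
            assert med[y, x] == sorted(vox[0, :, y, x])[1]
    with pytest.raises(ValueError):
        project_z(stack, 0, "mean")


# --------------------------------------------------------------------------
# median filter

def test_median_filter_radius_zero_is_identity(rng):
    img = Image2D(rng.random((9, 9)), PX)
    assert np.array_equal(median_filter(img, 0).pixels, img.pixels)
    with pytest.raises(ValueError):
        median_filter(img, -1)


def test_median_filter_removes_isolated_bright_pixel():
    img = np.full((9, 9), 3.0)
    img[4, 4] = 100.0
    out = median_filter(Image2D(img, PX), 1)
    assert np.all(out.pixels == 3.0)


def test_median_filter_matches_bruteforce_disk(rng):
    img = rng.random((16, 16)) * 10
    for radius in (1, 2):
        out = median_filter(Image2D(img, PX), radius).pixels
        offs = _disk_offsets(radius)
        for y in range(16):
            for x in range(16):
                assert out[y, x] == np.median(_neighborhood_values(img, y, x, offs))


# --------------------------------------------------------------------------
# white top-hat

def test_tophat_flat_image_is_zero():
    out = tophat_white(Image2D(np.full((12, 12), 7.0), PX), 5)
    assert np.allclose(out.pixels, 0.0)


def test_tophat_preserves_isolated_peak():
    img = np.full((16, 16), 2.0)
    img[8, 8] = 2.0 + 50.0
    out = tophat_white(Image2D(img, PX), 5)
    assert out.pixels[8, 8] == pytest.approx(50.0)
    out_masked = out.pixels.copy()
    out_masked[8, 8] = 0.0
    assert np.allclose(out_masked, 0.0)


def test_tophat_matches_erosion_dilation_oracle(rng):
    img = rng.random((16, 16)) * 20
    radius = 3
    offs = _disk_offsets(radius)
    eroded = np.array([[min(_neighborhood_values(img, y, x, offs)) for x in range(16)]
                       for y in range(16)])
    opened = np.array([[max(_neighborhood_values(eroded, y, x, offs)) for x in range(16)]
                       for y in range(16)])
    out = tophat_white(Image2D(img, PX), radius).pixels
    assert np.allclose(out, img - opened)


def test_tophat_bounds(rng):
    img = rng.random((20, 20)) * 30
    out = tophat_white(Image2D(img, PX), 5).pixels
    assert np.all(out >= 0) and np.all(out <= img + 1e-12)
    with pytest.raises(ValueError):
        tophat_white(Image2D(img, PX), 0)


# --------------------------------------------------------------------------
# 3D smoothing

def test_smooth_3d_identity_and_normalization(rng):
    stack = ImageStack(rng.random((1, 4, 6, 6)), (1.0, 0.1, 0.1))
    assert np.array_equal(smooth_3d(stack, 0).voxels, stack.voxels)
    impulse = np.zeros((1, 9, 9, 9))
    impulse[0, 4, 4, 4] = 1.0
    out = smooth_3d(ImageStack(impulse, (1, 1, 1)), 1.0)
    assert out.voxels.sum() == pytest.approx(1.0, abs=1e-6)


def test_smooth_3d_matches_dense_convolution(rng):
    vol = rng.random((1, 8, 8, 8))
    stack = ImageStack(vol, (1, 1, 1))
    sigma = 1.2
    out = smooth_3d(stack, sigma).voxels[0]
    # dense-kernel oracle: outer product of 1D impulse responses
    n = int(4 * sigma + 0.5)
    imp = np.zeros(2 * n + 1)
    imp[n] = 1.0
    k1 = ndimage.gaussian_filter1d(imp, sigma)
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    ref = ndimage.convolve(vol[0], kernel, mode="reflect")
    assert np.allclose(out, ref, atol=1e-10)


# --------------------------------------------------------------------------
# Triangle threshold

def test_triangle_two_delta_histogram_separates_modes():
    hist = np.zeros(256)
    hist[10] = 1000
    hist[200] = 50
    res = triangle_threshold(hist, bin_edges=np.arange(257.0))
    assert 10 < res.bin_index < 200


def test_triangle_matches_exhaustive_oracle(rng):
    for _ in range(50):
        hist = rng.integers(0, 1000, size=256).astype(float)
        hist[rng.integers(0, 256)] += rng.integers(1000, 5000)
        res = triangle_threshold(hist, bin_edges=np.arange(257.0))
        assert res.bin_index == triangle_oracle(hist)


def test_triangle_constant_image_raises():
    with pytest.raises(DegenerateHistogramError):
        triangle_threshold(np.full((8, 8), 3.0))


@settings(derandomize=True, max_examples=30)
@given(scale=st.floats(min_value=0.1, max_value=1000.0),
       seed=st.integers(min_value=0, max_value=10_000))
def test_triangle_invariant_to_count_rescaling(scale, seed):
    r = np.random.default_rng(seed)
    hist = r.integers(0, 500, size=256).astype(float)
    hist[r.integers(0, 256)] += 2000
    edges = np.arange(257.0)
    assert (triangle_threshold(hist, bin_edges=edges).bin_index
            == triangle_threshold(hist * scale, bin_edges=edges).bin_index)


# --------------------------------------------------------------------------
# binarize

def test_binarize_extremes_and_oracle(rng):
    img = Image2D(rng.random((10, 10)) * 9, PX)
    assert not binarize(img, img.pixels.max()).voxels.any()
    assert binarize(img, img.pixels.min() - 1).voxels.all()
    thr = 4.5
    assert np.array_equal(binarize(img, thr).voxels, img.pixels > thr)
    with pytest.raises(ValueError):
        binarize(img, float("nan"))
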
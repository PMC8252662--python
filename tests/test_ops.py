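"""Image operators: projections, smoothing, maxima, matching, thresholds."""

import numpy as np
import pytest
from scipy import ndimage

from optolight import ops
from optolight.ops import (
    BinaryMask,
    DegenerateHistogramError,
    ImageStack,
    RegionSpec,
    auto_threshold,
    count_cotransfected,
    count_maxima,
    densest_plane,
    disk_footprint,
    gaussian_smooth,
    histogram_match,
    isodata_threshold_index,
    max_project,
    median_filter_binary,
    remove_small_clusters,
    signal_area,
)


def _stack(data, pixel_size=1.0, channels=("c",)):
    data = np.asarray(data, dtype=float)
    ts = tuple(float(i) for i in range(data.shape[0]))
    return ImageStack(data, pixel_size, ts, channels)


def _gauss_blob(shape, y, x, amp=1.0, sigma=2.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))


# ---------------------------------------------------------------------------
# projection and smoothing


def test_max_project_single_slice_is_identity():
    img = np.random.default_rng(0).uniform(size=(1, 16, 16))
    st = _stack(img[None, :, None])
    np.testing.assert_array_equal(max_project(st, "c", 0), img[0])


def test_max_project_is_pointwise_union_of_disjoint_blobs():
    a = _gauss_blob((32, 32), 8, 8)
    b = _gauss_blob((32, 32), 24, 24)
    st = _stack(np.stack([a, b])[None, :, None])
    proj = max_project(st, "c", 0)
    np.testing.assert_allclose(proj, np.maximum(a, b))
    assert proj[8, 8] == pytest.approx(1.0)
    assert proj[24, 24] == pytest.approx(1.0)


def test_max_project_counts_rendered_cells(small_irradiated_stack, conditions):
    """Generator oracle: projected nuclei maxima = ground-truth cell count."""
    stack, truth, gen = small_irradiated_stack
    proj = gaussian_smooth(max_project(stack, "nuclei", 0), 1.0)
    n, _ = count_maxima(proj, 15.0)
    assert abs(n - len(truth)) / len(truth) < 0.05


def test_gaussian_smooth_identity_and_conservation():
    rng = np.random.default_rng(1)
    img = rng.uniform(size=(40, 40))
    np.testing.assert_array_equal(gaussian_smooth(img, 0.0), img)
    np.testing.assert_allclose(gaussian_smooth(np.full((20, 20), 3.3), 1.0), 3.3)
    smoothed = gaussian_smooth(img, 1.0)
    assert smoothed.sum() == pytest.approx(img.sum(), rel=1e-6)  # reflect boundary


def test_gaussian_kernel_mass_within_three_sigma():
    img = np.zeros((41, 41))
    img[20, 20] = 1.0
    sm = gaussian_smooth(img, 2.0)
    yy, xx = np.mgrid[:41, :41]
    inside = (yy - 20) ** 2 + (xx - 20) ** 2 <= (3 * 2.0) ** 2
    assert sm[inside].sum() >= 0.98


def test_gaussian_smooth_commutes_with_translation():
    rng = np.random.default_rng(2)
    img = rng.uniform(size=(48, 48))
    shifted = np.roll(img, (5, -3), axis=(0, 1))
    a = np.roll(gaussian_smooth(img, 1.5), (5, -3), axis=(0, 1))
    b = gaussian_smooth(shifted, 1.5)
    # compare beyond the truncated kernel's reach of the wrapped-in boundary
    np.testing.assert_allclose(a[12:-12, 12:-12], b[12:-12, 12:-12], atol=1e-10)


# ---------------------------------------------------------------------------
# maxima counting


def test_count_maxima_blank_image_is_zero():
    assert count_maxima(np.zeros((16, 16)), 1.0)[0] == 0


def test_count_maxima_well_separated_blobs():
    rng = np.random.default_rng(3)
    img = np.zeros((100, 100))
    pts = [(10 + 18 * i, 10 + 18 * j) for i in range(5) for j in range(5)]
    for y, x in pts:
        img += _gauss_blob(img.shape, y, x, amp=rng.uniform(0.8, 1.2), sigma=1.5)
    n, coords = count_maxima(img, 0.3)
    assert n == 25
    # every detection lies near a true centre
    dists = np.sqrt(((coords[:, None] - np.array(pts)[None]) ** 2).sum(-1)).min(1)
    assert dists.max() < 1.5


def test_two_blob_prominence_sweep_matches_brute_force():
    """Oracle: the saddle between two peaks decides one vs two detections."""
    for dist, sigma in [(8, 2.0), (6, 2.0), (10, 3.0)]:
        img = _gauss_blob((40, 60), 20, 20, 1.0, sigma) + _gauss_blob(
            (40, 60), 20, 20 + dist, 0.83, sigma
        )
        # brute force: lower peak height minus the best separating saddle
        row = img[20]
        i1, i2 = 20, 20 + dist
        saddle = row[i1 : i2 + 1].min()
        lower_peak = img[20, i2]
        true_prominence = lower_peak - saddle
        for prom in np.array([0.3, 0.6, 1.3, 1.9]) * true_prominence:
            n, _ = count_maxima(img, prom)
            expected = 2 if prom < true_prominence else 1
            assert n == expected, (dist, sigma, prom, true_prominence)


def test_plateau_maximum_counted_once_at_centroid():
    img = np.zeros((20, 20))
    img[8:12, 8:12] = 5.0
    n, coords = count_maxima(img, 1.0)
    assert n == 1
    np.testing.assert_allclose(coords[0], [9.5, 9.5])


# ---------------------------------------------------------------------------
# co-transfection counting


def test_identical_channels_give_both_equals_either():
    img = sum(_gauss_blob((50, 50), y, x, 1.0, 1.5)
              for y, x in [(10, 10), (25, 30), (40, 15)])
    counts = count_cotransfected(img, img.copy(), 0.3)
    assert counts.n_first == counts.n_second == counts.n_both == 3
    assert counts.n_either == 3


def test_disjoint_channels_give_zero_both():
    a = _gauss_blob((50, 50), 10, 10, 1.0, 1.5)
    b = _gauss_blob((50, 50), 40, 40, 1.0, 1.5)
    counts = count_cotransfected(a, b, 0.3)
    assert counts.n_both == 0
    assert counts.n_either == 2


def test_channel_shape_mismatch_raises():
    with pytest.raises(ValueError):
        count_cotransfected(np.zeros((10, 10)), np.zeros((12, 10)), 1.0)


def test_cotransfection_counts_recover_truth(small_irradiated_stack):
    stack, truth, gen = small_irradiated_stack
    p1 = gaussian_smooth(max_project(stack, "iRFP", 0), 1.0)
    p2 = gaussian_smooth(max_project(stack, "EGFP", 0), 1.0)
    counts = count_cotransfected(p1, p2, 15.0)
    true_both = int(truth.co_transfected.sum())
    assert abs(counts.n_both - true_both) <= max(2, 0.1 * true_both)


# ---------------------------------------------------------------------------
# histogram matching


def test_match_to_self_is_identity():
    rng = np.random.default_rng(4)
    frames = rng.uniform(0, 255, size=(3, 32, 32))
    out = histogram_match(frames, reference_index=1)
    np.testing.assert_array_equal(out[1], frames[1])


def test_matched_quantiles_equal_reference_quantiles():
    rng = np.random.default_rng(5)
    frames = np.stack([
        rng.normal(50, 5, (64, 64)),
        rng.normal(90, 20, (64, 64)),
        rng.gamma(4.0, 10.0, (64, 64)),
    ])
    out = histogram_match(frames, reference_index=0)
    q = np.linspace(0.05, 0.95, 10)
    ref_q = np.quantile(frames[0], q)
    for i in (1, 2):
        np.testing.assert_allclose(np.quantile(out[i], q), ref_q, atol=1.0)


def test_monotone_transform_of_reference_is_recovered():
    """Sorting oracle: matching undoes a monotone intensity distortion."""
    rng = np.random.default_rng(6)
    ref = rng.uniform(10, 200, size=(64, 64))
    distorted = 3.0 * np.sqrt(ref) + 7.0
    out = histogram_match(np.stack([distorted, ref]), reference_index=1)
    np.testing.assert_allclose(out[0], ref, atol=1.0)


def test_constant_reference_raises():
    frames = np.stack([np.random.default_rng(0).uniform(size=(8, 8)), np.ones((8, 8))])
    with pytest.raises(DegenerateHistogramError):
        histogram_match(frames, reference_index=1)


# ---------------------------------------------------------------------------
# thresholding


def _isodata_fixed_points(hist):
    """Brute force: every clamped fixed point of the intermeans map."""
    hist = np.asarray(hist, float)
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    bins = np.arange(hist.size)
    csum = np.cumsum(hist)
    cm = np.cumsum(hist * bins)
    fixed = []
    for t in range(lo, hi):
        ml = cm[t] / csum[t]
        mh = (cm[-1] - cm[t]) / (csum[-1] - csum[t])
        t_new = min(max(round((ml + mh) / 2), lo), hi - 1)
        if t_new == t:
            fixed.append(t)
    return fixed


def test_two_delta_histogram_threshold_between_modes():
    img = np.concatenate([np.full(500, 10), np.full(500, 200)]).astype(np.uint8)
    img = img.reshape(25, 40)
    bm = auto_threshold(img)
    assert 10 < bm.threshold < 200
    assert bm.mask.sum() == 500
    assert img[bm.mask].min() == 200


def test_blank_image_yields_empty_mask_with_warning():
    with pytest.warns(UserWarning, match="constant image"):
        bm = auto_threshold(np.full((16, 16), 7.0))
    assert not bm.mask.any()


def test_isodata_iteration_lands_on_brute_force_fixed_point():
    rng = np.random.default_rng(7)
    for _ in range(50):
        hist = rng.integers(0, 500, size=256).astype(float)
        hist[rng.uniform(size=256) < rng.uniform(0.2, 0.9)] = 0
        if np.count_nonzero(hist) < 2:
            continue
        t = isodata_threshold_index(hist)
        fixed = _isodata_fixed_points(hist)
        assert t in fixed


def test_synthetic_blob_field_area_close_to_truth(conditions):
    """Generator oracle: thresholded area tracks the painted disk area."""
    from conftest import tiny_config
    from optolight.simulate import render_field, sample_cells, single_region_field

    gen = tiny_config(seed=31, f_leak=1.0, poisson_scale=0.0, read_noise_sd=1.0)
    fs = single_region_field(gen, "0", False)
    cells = sample_cells(gen, fs)
    stack, truth = render_field(cells, fs, gen, [0.0, 2880.0], conditions,
                                channels=("mCherry",))
    img = max_project(stack, "mCherry", 1)
    bm = auto_threshold(img)
    pos = truth[truth.detect_leak]
    painted = np.pi * (pos.radius_um / gen.pixel_size_um) ** 2
    assert bm.mask.sum() == pytest.approx(painted.sum(), rel=0.25)


# ---------------------------------------------------------------------------
# median filter, areas, clusters, planes


def test_median_filter_footprint_is_nine_pixel_disk():
    assert disk_footprint(1.5).sum() == 9
    assert disk_footprint(1.5).shape == (3, 3)


def test_median_filter_majority_vote_cases():
    all_true = median_filter_binary(np.ones((8, 8), bool))
    assert all_true.mask.all()
    lone = np.zeros((9, 9), bool)
    lone[4, 4] = True
    assert not median_filter_binary(lone).mask.any()
    square = np.zeros((20, 20), bool)
    square[5:15, 5:15] = True
    out = median_filter_binary(square)
    # solid shapes survive up to boundary erosion (interior corners lose the vote)
    perimeter = 4 * 10 - 4
    assert square.sum() - out.mask.sum() <= perimeter
    assert out.mask[6:14, 6:14].all()


def test_median_filter_matches_brute_force_majority():
    rng = np.random.default_rng(8)
    for p in (0.2, 0.5, 0.8):
        mask = rng.uniform(size=(32, 32)) < p
        out = median_filter_binary(mask).mask
        padded = np.pad(mask.astype(int), 1, mode="symmetric")
        expect = np.zeros_like(mask)
        for i in range(32):
            for j in range(32):
                expect[i, j] = padded[i : i + 3, j : j + 3].sum() >= 5
        np.testing.assert_array_equal(out, expect)


def test_signal_area_examples():
    assert signal_area(np.zeros((10, 10), bool), 2.0) == (0, 0.0)
    rect = np.zeros((20, 30), bool)
    rect[2:7, 3:11] = True
    n, um2 = signal_area(rect, 1.5)
    assert n == 5 * 8
    assert um2 == pytest.approx(40 * 1.5**2)
    yy, xx = np.mgrid[:64, :64]
    disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 100
    n, _ = signal_area(disk, 1.0)
    assert abs(n - 100 * np.pi) / (100 * np.pi) < 0.05


def test_signal_area_region_rounding_outward():
    mask = np.ones((50, 50), bool)
    region = RegionSpec((1.0, 1.0), 8.0, 8.0, False, "0", name="r")
    n, _ = signal_area(mask, 2.0, region)  # 0.5..4.5 px → rows/cols 0..5
    assert n == 25
    outside = RegionSpec((90.0, 0.0), 20.0, 20.0, False, "0", name="r")
    with pytest.raises(ValueError):
        signal_area(mask, 2.0, outside)


def test_remove_small_clusters_mask_and_image():
    mask = np.zeros((20, 20), bool)
    mask[1:4, 1:2] = True  # 3 px
    mask[10:15, 10:20] = True  # 50 px
    out, keep = remove_small_clusters(mask, 10)
    assert out.sum() == 50
    # identity at min_area = 0
    out0, _ = remove_small_clusters(mask, 0)
    np.testing.assert_array_equal(out0, mask)
    # 8-connectivity: diagonal pixels belong to one cluster
    diag = np.zeros((10, 10), bool)
    diag[np.arange(5), np.arange(5)] = True
    out8, _ = remove_small_clusters(diag, 4)
    assert out8.sum() == 5
    # intensity-image variant zeroes the small cluster's pixels
    img = np.where(mask, 100.0, 1.0) + np.random.default_rng(0).normal(0, 0.1, mask.shape)
    cleaned, kept = remove_small_clusters(img, 10)
    assert cleaned[2, 1] == 0.0
    assert cleaned[12, 15] > 50


def test_densest_plane_selection():
    data = np.zeros((1, 4, 1, 40, 40))
    for k, n_blobs in enumerate([1, 3, 5, 2]):
        for b in range(n_blobs):
            data[0, k, 0] += _gauss_blob((40, 40), 8 + 6 * b, 8 + 6 * b, 10.0, 1.2)
    st = _stack(data, channels=("nuclei",))
    assert densest_plane(st, "nuclei", 0, prominence=1.0) == 2
    blank = _stack(np.zeros((1, 3, 1, 16, 16)), channels=("nuclei",))
    assert densest_plane(blank, "nuclei", 0, prominence=1.0) == 0  # tie → lowest


def test_full_chain_on_painted_mask_is_exact():
    """match → threshold → median → area returns a painted area exactly.

    The painted shape is a full-width stripe: it has no interior corners, so
    the majority vote leaves it untouched and the chain is exact.
    """
    painted = np.full((40, 40), 10.0)
    painted[10:22, :] = 210.0
    series = np.stack([painted.copy() for _ in range(4)])
    matched = histogram_match(series, -1)
    bm = auto_threshold(matched[0])
    bm = median_filter_binary(bm)
    n, _ = signal_area(bm, 1.0)
    assert n == 12 * 40


def test_ome_tiff_round_trip(tmp_path, small_irradiated_stack):
    stack, _, _ = small_irradiated_stack
    path = tmp_path / "stack.ome.tif"
    stack.to_tiff(path)
    back = ImageStack.from_tiff(path)
    np.testing.assert_array_equal(back.data, stack.data)
    assert back.channel_names == stack.channel_names
    assert back.pixel_size == pytest.approx(stack.pixel_size)
    assert back.timestamps == stack.timestamps


def test_binary_mask_tiff_is_eight_bit(tmp_path):
    import tifffile

    mask = np.zeros((12, 12), bool)
    mask[3:7, 3:9] = True
    bm = BinaryMask(mask, ("auto_threshold[isodata,5]",))
    path = tmp_path / "mask.tif"
    bm.to_tiff(path)
    back = tifffile.imread(path)
    assert back.dtype == np.uint8
    np.testing.assert_array_equal(back > 0, mask)
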
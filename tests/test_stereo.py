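"""Rectification, semi-global disparity, WLS filtering, reprojection."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from stereofood import stereo as st
from stereofood.epipolar import CameraIntrinsics, RelativePose
from stereofood.errors import ParameterError, StereoFoodError, UsageError


def _flat_rect_pair(disparity, shape=(240, 320), seed=0, f=700.0):
    """Rectified pair of a frontoparallel textured plane at constant
    disparity (possibly fractional)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    tex = gaussian_filter(rng.random((h, w + 160)) * 255, 1.2)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    L = map_coordinates(tex, [yy, xx + 80.0], order=3)
    R = map_coordinates(tex, [yy, xx + 80.0 + disparity], order=3)
    K = np.array([[f, 0, w / 2 - 0.5], [0, f, h / 2 - 0.5], [0, 0, 1.0]])
    ones = np.ones(shape, bool)
    return st.RectifiedPair(np.clip(L, 0, 255).astype(np.uint8),
                            np.clip(R, 0, 255).astype(np.uint8),
                            np.eye(3), np.eye(3), K, 1.0, ones, ones)


# --------------------------------------------------------------------------
# rectification


def test_rectified_truth_correspondences_share_rows(default_scene,
                                                    estimated_pose):
    """Ground-truth correspondences land on equal rows within 0.5 px for
    at least 95% of sampled surface points."""
    from stereofood import synthetic as syn

    truth = default_scene
    rect = st.rectify_pair(*truth.images, truth.K, estimated_pose)
    pts = syn.food_surface_points(truth.spec, 400, seed=5)
    H1 = rect.K_new @ rect.R1 @ np.linalg.inv(truth.K.K)
    H2 = rect.K_new @ rect.R2 @ np.linalg.inv(truth.K.K)

    def remap(p, H):
        q = np.hstack([p, np.ones((len(p), 1))]) @ H.T
        return q[:, :2] / q[:, [2]]

    r1 = remap(truth.project(pts, 0), H1)
    r2 = remap(truth.project(pts, 1), H2)
    assert (np.abs(r1[:, 1] - r2[:, 1]) < 0.5).mean() >= 0.95


def test_pure_horizontal_translation_is_already_rectified():
    pose = RelativePose(np.eye(3), np.array([-1.0, 0.0, 0.0]))
    img = np.random.default_rng(0).integers(0, 255, (60, 80, 3),
                                            dtype=np.uint8)
    K = CameraIntrinsics(100.0, 100.0, 39.5, 29.5)
    rect = st.rectify_pair(img, img, K, pose)
    assert np.abs(rect.R1 - np.eye(3)).max() < 1e-9
    assert np.abs(rect.R2 - np.eye(3)).max() < 1e-9


def test_degenerate_baseline_raises_package_error():
    """A zero baseline cannot be rectified; the pose type itself already
    rejects a vanishing translation."""
    with pytest.raises(StereoFoodError):
        pose = RelativePose(np.eye(3), np.zeros(3))
        img = np.zeros((10, 10, 3), np.uint8)
        st.rectify_pair(img, img, CameraIntrinsics(10, 10, 5, 5), pose)


# --------------------------------------------------------------------------
# disparity


def test_identical_images_give_zero_disparity():
    rect = _flat_rect_pair(0.0)
    d = st.compute_disparity(rect, num_disparities=32)
    vals = d.values[~d.invalid_mask]
    assert np.nanmedian(vals) == pytest.approx(0.0, abs=0.05)
    assert (np.abs(vals) < 0.5).mean() > 0.98


def test_integer_shift_recovered_on_overlap():
    rect = _flat_rect_pair(8.0)
    d = st.compute_disparity(rect, num_disparities=32)
    vals = d.values[~d.invalid_mask]
    assert (np.abs(vals - 8.0) < 0.5).mean() > 0.98


def test_frontoparallel_plane_matches_pinhole_closed_form():
    """Median disparity within 0.5 px of f*b/z for a plane at depth z."""
    f, b, z = 700.0, 1.0, 50.0
    d_true = f * b / z  # 14 px
    rect = _flat_rect_pair(d_true)
    d = st.compute_disparity(rect, num_disparities=32)
    assert np.nanmedian(d.values[~d.invalid_mask]) == pytest.approx(
        d_true, abs=0.5)


def test_disparity_parameter_validation():
    rect = _flat_rect_pair(4.0)
    with pytest.raises(ParameterError):
        st.compute_disparity(rect, num_disparities=30)
    with pytest.raises(ParameterError):
        st.compute_disparity(rect, num_disparities=32, block_size=4)
    with pytest.raises(ParameterError):
        st.compute_disparity(rect, num_disparities=32, paths=3)


# --------------------------------------------------------------------------
# WLS filter


def test_wls_constant_disparity_fixed_point():
    rect = _flat_rect_pair(6.0)
    d = st.DisparityMap(np.full((240, 320), 6.0, np.float32),
                        np.zeros((240, 320), bool))
    out = st.filter_disparity_wls(d, rect.img1_rect)
    assert np.abs(out.values - 6.0).max() < 1e-6


def test_wls_preserves_guide_aligned_step_and_denoises():
    """A piecewise-constant disparity with an aligned guide edge keeps the
    edge within 1 px while the added noise variance drops >= 10x."""
    rng = np.random.default_rng(8)
    h, w = 200, 300
    guide = np.full((h, w), 60, np.uint8)
    guide[:, 150:] = 200
    step = np.where(np.arange(w) >= 150, 30.0, 10.0)[None, :]
    clean = np.repeat(step, h, axis=0)
    noisy = clean + rng.normal(0, 0.5, (h, w))
    d = st.DisparityMap(noisy.astype(np.float32), np.zeros((h, w), bool))
    out = st.filter_disparity_wls(d, guide, lam=300.0)
    interior = (slice(20, 180), slice(20, 130))
    var_in = np.var(noisy[interior] - clean[interior])
    var_out = np.var(out.values[interior] - clean[interior])
    assert var_out < var_in / 10.0
    # edge location: first column where the row crosses the midpoint
    mid = 20.0
    cross = (out.values[100] > mid).argmax()
    assert abs(int(cross) - 150) <= 1


def test_wls_fills_holes_from_surroundings():
    rng = np.random.default_rng(9)
    h, w = 120, 160
    guide = rng.integers(90, 110, (h, w)).astype(np.uint8)
    vals = np.full((h, w), 12.0, np.float32)
    invalid = np.zeros((h, w), bool)
    invalid[50:70, 60:90] = True
    vals[invalid] = np.nan
    out = st.filter_disparity_wls(st.DisparityMap(vals, invalid), guide)
    assert np.isfinite(out.values).all()
    assert np.abs(out.values[50:70, 60:90] - 12.0).max() < 0.5


def test_wls_shape_mismatch_rejected():
    d = st.DisparityMap(np.zeros((10, 10), np.float32),
                        np.zeros((10, 10), bool))
    with pytest.raises(ParameterError):
        st.filter_disparity_wls(d, np.zeros((20, 20), np.uint8))


# --------------------------------------------------------------------------
# reprojection


def test_reproject_requires_scale():
    rect = _flat_rect_pair(10.0)
    d = st.compute_disparity(rect, num_disparities=32)
    with pytest.raises(UsageError):
        st.reproject_to_cloud(d, rect, None)


def test_all_invalid_disparity_gives_empty_cloud():
    rect = _flat_rect_pair(10.0)
    vals = np.full(rect.shape, np.nan, np.float32)
    d = st.DisparityMap(vals, np.ones(rect.shape, bool))
    cloud = st.reproject_to_cloud(d, rect, 1.0)
    assert len(cloud) == 0


def test_frontoparallel_plane_reconstructs_coplanar():
    """RMS plane residual of the reconstructed frontoparallel plane is
    below 0.2 cm."""
    f, z_cm = 700.0, 40.0
    scale = 4.0  # cm per unit; depth in units = z_cm / scale
    d_true = f * 1.0 / (z_cm / scale)
    rect = _flat_rect_pair(d_true)
    d = st.compute_disparity(rect, num_disparities=96)
    d = st.refine_disparity_photometric(d, rect)
    # the left ~70 columns have no counterpart in the right view; the
    # example concerns the matchable overlap
    d.invalid_mask[:, :int(np.ceil(d_true)) + 8] = True
    cloud = st.reproject_to_cloud(d, rect, scale)
    z = cloud.points[:, 2]
    assert np.sqrt(np.mean((z - np.median(z)) ** 2)) < 0.2
    assert np.median(z) == pytest.approx(z_cm, rel=0.02)


def test_depth_monotonicity():
    """Within one reprojection, larger disparity means smaller depth."""
    rect = _flat_rect_pair(10.0)
    h, w = rect.shape
    vals = np.tile(np.linspace(8, 24, w, dtype=np.float32), (h, 1))
    d = st.DisparityMap(vals, np.zeros((h, w), bool))
    cloud = st.reproject_to_cloud(d, rect, 1.0, depth_range_cm=(0.1, 1e9))
    # reconstruct per-column depth: columns to the right have larger
    # disparity, hence smaller Z
    zs = cloud.points[:, 2].reshape(h, -1)
    col_depth = zs.mean(axis=0)
    assert (np.diff(col_depth) < 0).all()


def test_photometric_refinement_tightens_subpixel():
    """Refinement reduces the error against a known fractional shift."""
    rect = _flat_rect_pair(9.3)
    d0 = st.compute_disparity(rect, num_disparities=32)
    d1 = st.refine_disparity_photometric(d0, rect)
    m = ~d0.invalid_mask
    e0 = np.abs(d0.values[m] - 9.3)
    e1 = np.abs(d1.values[m] - 9.3)
    assert np.median(e1) <= np.median(e0)
    assert np.median(e1) < 0.15
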
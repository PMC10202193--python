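"""Epipolar geometry: RANSAC inlier filtering, fundamental/essential
estimation, optimal correction, pose recovery, triangulation."""

import numpy as np
import pytest

from conftest import (direction_angle_deg, exact_two_view,
                      rotation_angle_deg)
from stereofood import epipolar as ep
from stereofood.errors import (DegeneracyError, ParameterError,
                               StereoFoodError)
from stereofood.features import MatchSet


def _matchset(p1, p2):
    n = len(p1)
    pairs = np.stack([np.arange(n), np.arange(n), np.zeros(n)], 1)
    return MatchSet(pairs.astype(np.int64), np.asarray(p1, float),
                    np.asarray(p2, float))


# --------------------------------------------------------------------------
# RANSAC homography filtering


def test_ransac_threshold_is_fraction_of_largest_dimension():
    """0.6% of the largest dimension: 4.8 px for a 600x800 image."""
    assert ep.ransac_threshold_px((600, 800)) == pytest.approx(4.8)
    assert ep.ransac_threshold_px((1000, 400)) == pytest.approx(6.0)


def test_ransac_recovers_planted_inliers_exactly():
    """20 exact correspondences under a known homography plus 10 uniform
    outliers: the inlier mask recovers exactly the 20."""
    rng = np.random.default_rng(7)
    H = np.array([[1.02, 0.01, 5.0], [-0.015, 0.99, -3.0],
                  [1e-5, -2e-5, 1.0]])
    p1 = rng.uniform(50, 750, (20, 2))
    hom = np.hstack([p1, np.ones((20, 1))]) @ H.T
    p2 = hom[:, :2] / hom[:, [2]]
    o1 = rng.uniform(0, 800, (10, 2))
    o2 = rng.uniform(0, 800, (10, 2))
    m = _matchset(np.vstack([p1, o1]), np.vstack([p2, o2]))
    est = ep.filter_inliers_ransac(m, (600, 800), seed=3)
    assert est.inlier_mask[:20].all()
    assert not est.inlier_mask[20:].any()


def test_ransac_identity_homography_from_four_points():
    p = np.array([[10.0, 10.0], [700.0, 20.0], [650.0, 550.0],
                  [30.0, 500.0]])
    est = ep.filter_inliers_ransac(_matchset(p, p), (600, 800), seed=0)
    assert est.inlier_mask.all()
    assert np.allclose(est.H / est.H[2, 2], np.eye(3), atol=1e-6)


def test_ransac_needs_four_matches():
    p = np.random.default_rng(0).uniform(0, 500, (3, 2))
    with pytest.raises(DegeneracyError):
        ep.filter_inliers_ransac(_matchset(p, p), (600, 800))


def test_ransac_bit_reproducible_for_fixed_seed(matched_pair):
    a = ep.filter_inliers_ransac(matched_pair, (600, 800), seed=11)
    b = ep.filter_inliers_ransac(matched_pair, (600, 800), seed=11)
    assert np.array_equal(a.inlier_mask, b.inlier_mask)
    assert np.array_equal(a.H, b.H)


# --------------------------------------------------------------------------
# fundamental / essential


def test_fundamental_satisfies_epipolar_constraint_on_exact_data():
    _, _, _, _, x1, x2, F_true, _ = exact_two_view()
    F = ep.fundamental_8point(x1, x2)
    if np.sum(F * F_true) < 0:
        F = -F
    assert np.abs(F - F_true).max() < 1e-6
    res = ep.epipolar_residuals(F, x1, x2)
    # in normalized (unit-Frobenius) form the algebraic residual vanishes
    assert res.max() < 1e-6


def test_fundamental_rejects_collinear_points():
    t = np.linspace(0, 1, 8)
    p1 = np.stack([100 + 500 * t, 200 + 100 * t], 1)
    p2 = p1 + 3.0
    with pytest.raises(DegeneracyError):
        ep.fundamental_8point(p1, p2)
    with pytest.raises(DegeneracyError):
        ep.fundamental_8point(p1[:7], p2[:7])


def test_essential_from_fundamental_structure():
    """E = K2' F K1 with singular values projected to (s, s, 0); identity
    intrinsics reduce E to the projected F."""
    K, R, tn, _, x1, x2, F_true, E_true = exact_two_view()
    E = ep.essential_from_fundamental(F_true, K, K)
    En = E / np.linalg.norm(E)
    Et = E_true / np.linalg.norm(E_true)
    if np.sum(En * Et) < 0:
        En = -En
    assert np.abs(En - Et).max() < 1e-6
    s = np.linalg.svd(E, compute_uv=False)
    assert s[0] == pytest.approx(s[1])
    assert s[2] == pytest.approx(0.0, abs=1e-12)

    ident = ep.CameraIntrinsics(1.0, 1.0, 0.0, 0.0)
    F_rank2 = E_true  # already rank 2
    E2 = ep.essential_from_fundamental(F_rank2, ident, ident)
    s2 = np.linalg.svd(E2, compute_uv=False)
    assert s2[0] == pytest.approx(s2[1])


# --------------------------------------------------------------------------
# optimal (Hartley-Sturm) correction


def test_correction_leaves_satisfying_pairs_unchanged():
    _, _, _, _, x1, x2, F, _ = exact_two_view()
    inl = ep.correct_optimal(ep.InlierSet(x1, x2), F)
    assert np.abs(inl.corrected1 - x1).max() < 1e-6
    assert np.abs(inl.corrected2 - x2).max() < 1e-6


def test_correction_residual_below_1e9():
    _, _, _, _, x1, x2, F, _ = exact_two_view(noise=0.5, seed=2)
    inl = ep.correct_optimal(ep.InlierSet(x1, x2), F)
    res = ep.epipolar_residuals(F, inl.corrected1, inl.corrected2)
    assert res.max() < 1e-9


def test_correction_matches_grid_search_oracle():
    """The polynomial minimizer is at least as good as a brute-force 2-D
    grid search over displaced points on the epipolar pencil."""
    _, _, _, _, x1, x2, F, _ = exact_two_view(seed=5)
    rng = np.random.default_rng(6)
    for i in range(5):
        p1 = x1[i] + rng.uniform(-0.8, 0.8, 2)
        p2 = x2[i] + rng.uniform(-0.8, 0.8, 2)
        inl = ep.correct_optimal(ep.InlierSet(p1[None], p2[None]), F)
        d_hs = (np.sum((inl.corrected1[0] - p1) ** 2)
                + np.sum((inl.corrected2[0] - p2) ** 2))
        # oracle: grid over candidate x1' positions; x2' is the projection
        # of p2 onto the epipolar line of x1'
        best = np.inf
        for dx in np.linspace(-2, 2, 81):
            for dy in np.linspace(-2, 2, 81):
                q1 = p1 + (dx, dy)
                l2 = F @ np.array([q1[0], q1[1], 1.0])
                d2 = (l2[0] * p2[0] + l2[1] * p2[1] + l2[2]) ** 2 \
                    / (l2[0] ** 2 + l2[1] ** 2)
                best = min(best, dx * dx + dy * dy + d2)
        assert d_hs <= best + 1e-6


# --------------------------------------------------------------------------
# pose recovery and triangulation


def test_pose_recovery_noise_free_within_a_tenth_degree():
    K, R, tn, _, x1, x2, _, E = exact_two_view()
    inl = ep.InlierSet(x1, x2)
    pose, mask = ep.recover_pose(E, inl, K, K)
    assert rotation_angle_deg(pose.R, R) < 0.1
    assert direction_angle_deg(pose.t, tn) < 0.1
    assert mask.all()


def test_cheirality_count_matches_exhaustive_enumeration():
    K, R, tn, _, x1, x2, _, E = exact_two_view(seed=9)
    inl = ep.InlierSet(x1, x2)
    pose, mask = ep.recover_pose(E, inl, K, K)
    counts = []
    for Rc, tc in ep.decompose_essential(E):
        cand = ep.RelativePose(Rc, tc)
        _, front = ep.triangulate_points(inl, K, K, cand)
        counts.append(int(front.sum()))
    assert int(mask.sum()) == max(counts)


def test_pure_translation_pose():
    """E built from R = I, t = (1, 0, 0) recovers an identity rotation."""
    K = ep.CameraIntrinsics(700.0, 700.0, 399.5, 299.5)
    rng = np.random.default_rng(1)
    X = rng.uniform([-10, -10, 30], [10, 10, 50], (40, 3))
    t = np.array([1.0, 0.0, 0.0])
    x1 = ep.reproject(K, np.eye(3), np.zeros(3), X)
    x2 = ep.reproject(K, np.eye(3), -t * 0.1, X)  # camera moves right
    E = np.array([[0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])  # [t]_x for e_x
    pose, _ = ep.recover_pose(E, ep.InlierSet(x1, x2), K, K)
    assert rotation_angle_deg(pose.R, np.eye(3)) < 0.1


def test_triangulation_roundtrip_and_cheirality_flags():
    K, R, tn, Xs, x1, x2, _, _ = exact_two_view()
    pose = ep.RelativePose(R, tn)
    X, front = ep.triangulate_points(ep.InlierSet(x1, x2), K, K, pose)
    assert front.all()
    assert np.abs(X - Xs).max() < 1e-6
    # a correspondence crossing behind camera 2 is flagged
    X_behind = np.array([[0.0, 0.0, 30.0]])
    xb1 = ep.reproject(K, np.eye(3), np.zeros(3), X_behind)
    xb2 = xb1 + np.array([[800.0, 0.0]])  # implies negative parallax
    _, fb = ep.triangulate_points(ep.InlierSet(xb1, xb2), K, K, pose)
    assert not fb[0]


def test_triangulated_card_corners_remain_planar(default_scene,
                                                 estimated_pose):
    """Noise-free synthetic projections of the card corners triangulate to
    a near-perfect plane."""
    truth = default_scene
    c1 = truth.project(truth.card_corners_world, 0)
    c2 = truth.project(truth.card_corners_world, 1)
    pose = ep.RelativePose(truth.R_true.copy(),
                           truth.t_true / np.linalg.norm(truth.t_true))
    X, _ = ep.triangulate_points(ep.InlierSet(c1, c2), truth.K, truth.K,
                                 pose)
    centered = X - X.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    assert s[2] < 1e-4


def test_end_to_end_reprojection_consistency():
    """Recovered pose reprojects triangulated noise-free points onto both
    views within 0.01 px."""
    K, R, tn, _, x1, x2, _, E = exact_two_view(seed=12)
    inl = ep.correct_optimal(ep.InlierSet(x1, x2),
                             ep.fundamental_8point(x1, x2))
    pose, _ = ep.recover_pose(E, inl, K, K)
    X, _ = ep.triangulate_points(inl, K, K, pose)
    r1 = ep.reproject(K, np.eye(3), np.zeros(3), X)
    r2 = ep.reproject(K, pose.R, pose.t, X)
    assert np.abs(r1 - x1).max() < 0.01
    assert np.abs(r2 - x2).max() < 0.01


def test_rotation_recovery_degrades_gracefully_with_noise():
    """0.5 px Gaussian noise keeps the rotation within 1 degree."""
    K, R, tn, _, x1, x2, _, _ = exact_two_view(n_points=200, seed=3,
                                               noise=0.5)
    F = ep.fundamental_8point(x1, x2)
    E = ep.essential_from_fundamental(F, K, K)
    pose, _ = ep.recover_pose(E, ep.InlierSet(x1, x2), K, K)
    assert rotation_angle_deg(pose.R, R) < 1.0


def test_homography_decomposition_recovers_planted_plane_pose():
    """H = R + t n^T / d decomposes back to the planted (R, t, n)."""
    K = ep.CameraIntrinsics(700.0, 700.0, 399.5, 299.5)
    _, R, tn, *_ = exact_two_view()
    n = np.array([0.1, 0.65, 0.75])
    n /= np.linalg.norm(n)
    d = 40.0
    Hc = R + np.outer(tn * 4.0, n) / d
    H = K.K @ Hc @ np.linalg.inv(K.K)
    sols = ep.decompose_homography(H, K, K)
    best_r = min(rotation_angle_deg(Rs, R) for Rs, ts, ns in sols)
    best_t = min(direction_angle_deg(ts, tn) for Rs, ts, ns in sols)
    assert best_r < 0.01
    assert best_t < 0.01


def test_relative_pose_invariants():
    with pytest.raises(ParameterError):
        ep.RelativePose(np.eye(3) * 2.0, np.array([1.0, 0, 0]))
    with pytest.raises(ParameterError):
        ep.RelativePose(np.eye(3), np.zeros(3))
    p = ep.RelativePose(np.eye(3), np.array([3.0, 0, 0]))
    assert np.linalg.norm(p.t) == pytest.approx(1.0)


def test_calibration_json_roundtrip(tmp_path):
    K = ep.CameraIntrinsics(712.5, 698.0, 401.2, 300.8, 0.0, (600, 800))
    path = tmp_path / "calib.json"
    K.to_json(path)
    K2 = ep.CameraIntrinsics.from_json(path)
    assert K2.fx == K.fx and K2.image_shape == (600, 800)
    K_half = K.rescaled((300, 400))
    assert K_half.fx == pytest.approx(K.fx / 2)
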
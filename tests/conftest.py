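"""Shared fixtures: one rendered reference scene plus its sparse-geometry
chain, computed once per session — rendering and matching are the slow
parts of most integration tests."""

import numpy as np
import pytest

from stereofood import epipolar as ep
from stereofood import features as ft
from stereofood import synthetic as syn


@pytest.fixture(scope="session")
def default_scene():
    """Default hemisphere scene with full ground truth."""
    return syn.render_scene(syn.SceneSpec(), seed=1)


@pytest.fixture(scope="session")
def matched_pair(default_scene):
    """Cross-checked FAST+BRIEF matches between the two rendered views."""
    img1, img2 = default_scene.images
    kp1, d1 = ft.detect_and_describe(img1, 4000, method="fast-brief")
    kp2, d2 = ft.detect_and_describe(img2, 4000, method="fast-brief")
    return ft.match_bruteforce(kp1, d1, kp2, d2)


@pytest.fixture(scope="session")
def estimated_pose(default_scene, matched_pair):
    """Relative pose recovered from the rendered pair (full sparse chain)."""
    truth, m = default_scene, matched_pair
    est = ep.filter_inliers_ransac(m, truth.images[0].shape[:2], seed=0)
    terr = ep.symmetric_transfer_error(est.H, m.points1, m.points2)
    H_tight = ep.homography_dlt(m.points1[terr < 2.0], m.points2[terr < 2.0])
    inl = ep.inliers_from_estimate(m, est)
    F = ep.fundamental_plane_parallax(m.points1, m.points2, est.H)
    if F is None:
        F = ep.estimate_fundamental(inl)
    inl = ep.correct_optimal(inl, F)
    pose, _, _ = ep.recover_pose_planar(H_tight, m, inl, truth.K, truth.K)
    return pose


def exact_two_view(n_points=60, seed=0, noise=0.0):
    """Synthetic calibrated two-view geometry with exact correspondences.

    Returns (K, R, t_unit, X_cam1, pixels1, pixels2, F_true, E_true).
    """
    rng = np.random.default_rng(seed)
    K = ep.CameraIntrinsics(700.0, 700.0, 399.5, 299.5)

    def roty(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rotz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

    R = roty(0.02) @ rotz(0.01)
    t = np.array([-4.0, 0.2, 0.1])
    tn = t / np.linalg.norm(t)
    X = rng.uniform([-15, -10, 35], [15, 10, 55], (n_points, 3))
    x1 = ep.reproject(K, np.eye(3), np.zeros(3), X)
    x2 = ep.reproject(K, R, t, X)
    if noise:
        x1 = x1 + rng.normal(0, noise, x1.shape)
        x2 = x2 + rng.normal(0, noise, x2.shape)
    tx = np.array([[0, -tn[2], tn[1]], [tn[2], 0, -tn[0]],
                   [-tn[1], tn[0], 0.0]])
    E = tx @ R
    Kinv = np.linalg.inv(K.K)
    F = Kinv.T @ E @ Kinv
    return K, R, tn, X / np.linalg.norm(t), x1, x2, \
        F / np.linalg.norm(F), E


def rotation_angle_deg(Ra, Rb):
    c = (np.trace(Ra @ Rb.T) - 1.0) / 2.0
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def direction_angle_deg(a, b):
    c = abs(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
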
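"""Keypoint detection, binary descriptors, brute-force Hamming matching,
and the 50-match relevance gate."""

import numpy as np
import pytest

from stereofood import (MatchSet, detect_and_describe, is_relevant_pair,
                        match_bruteforce)
from stereofood.epipolar import sampson_distance
from stereofood.features import KeypointSet, hamming_distance_matrix


def _square_grid(n_sq=5, px=24, gap=24):
    """Grid of isolated dark squares plus their corner ground truth.

    Segment-test (FAST-family) detectors respond to L-shaped corners, not
    to the X-junctions of a classic checkerboard, so the localization
    oracle uses isolated squares whose 4 corners per square are known
    from construction.
    """
    step = px + gap
    n = n_sq * step + gap
    img = np.full((n, n), 220, np.uint8)
    corners = []
    for r in range(n_sq):
        for c in range(n_sq):
            y0, x0 = gap + r * step, gap + c * step
            img[y0:y0 + px, x0:x0 + px] = 20
            corners += [(x0 - 0.5, y0 - 0.5), (x0 + px - 0.5, y0 - 0.5),
                        (x0 - 0.5, y0 + px - 0.5),
                        (x0 + px - 0.5, y0 + px - 0.5)]
    return np.repeat(img[..., None], 3, axis=2), np.array(corners)


@pytest.mark.parametrize("method", ["orb", "fast-brief"])
def test_constant_image_yields_no_keypoints(method):
    img = np.full((120, 160, 3), 127, np.uint8)
    kp, desc = detect_and_describe(img, 500, method=method)
    assert len(kp) == 0
    assert desc.shape[1] == 256


def test_known_corners_localize_accurately():
    """At least 40 constructed corners are detected within 1.5 px."""
    img, true_corners = _square_grid()
    kp, _ = detect_and_describe(img, 2000, method="fast-brief")
    assert len(kp) > 0
    hits = 0
    for c in true_corners:
        d = np.linalg.norm(kp.xy - c, axis=1).min()
        hits += d < 1.5
    assert hits >= 40


@pytest.mark.parametrize("method", ["orb", "fast-brief"])
def test_detection_is_deterministic(method, default_scene):
    img = default_scene.images[0]
    kp_a, d_a = detect_and_describe(img, 1000, method=method)
    kp_b, d_b = detect_and_describe(img, 1000, method=method)
    assert np.array_equal(kp_a.xy, kp_b.xy)
    assert np.array_equal(d_a, d_b)


def test_self_match_is_identity():
    """Matching a distinct descriptor set against itself pairs each index
    with itself at Hamming distance 0."""
    rng = np.random.default_rng(3)
    desc = rng.random((30, 256)) > 0.5
    kp = KeypointSet(rng.random((30, 2)) * 100, np.ones(30), np.ones(30))
    m = match_bruteforce(kp, desc, kp, desc)
    assert len(m) == 30
    assert (m.pairs[:, 0] == m.pairs[:, 1]).all()
    assert (m.pairs[:, 2] == 0).all()


def test_matching_equals_mutual_nn_oracle():
    """Cross-checked matching reproduces the O(n^2) mutual-nearest-neighbor
    enumeration on small random descriptor sets."""
    rng = np.random.default_rng(4)
    d1 = rng.random((5, 256)) > 0.5
    d2 = rng.random((5, 256)) > 0.5
    kp1 = KeypointSet(rng.random((5, 2)), np.ones(5), np.ones(5))
    kp2 = KeypointSet(rng.random((5, 2)), np.ones(5), np.ones(5))
    dist = np.array([[np.sum(a ^ b) for b in d2] for a in d1])
    expected = {(i, int(np.argmin(dist[i])))
                for i in range(5)
                if int(np.argmin(dist[:, np.argmin(dist[i])])) == i}
    m = match_bruteforce(kp1, d1, kp2, d2)
    got = {(int(i), int(j)) for i, j, _ in m.pairs}
    assert got == expected
    assert np.array_equal(hamming_distance_matrix(d1, d2), dist)


def test_empty_descriptor_set_gives_empty_matchset():
    rng = np.random.default_rng(5)
    d = rng.random((4, 256)) > 0.5
    kp = KeypointSet(rng.random((4, 2)), np.ones(4), np.ones(4))
    empty_kp = KeypointSet(np.empty((0, 2)), np.empty(0), np.empty(0))
    m = match_bruteforce(kp, d, empty_kp, np.empty((0, 256), bool))
    assert len(m) == 0


def test_cross_check_symmetry(default_scene):
    """Swapping the image roles yields the same pairs with roles reversed."""
    img1, img2 = default_scene.images
    kp1, d1 = detect_and_describe(img1, 1500, method="fast-brief")
    kp2, d2 = detect_and_describe(img2, 1500, method="fast-brief")
    fwd = match_bruteforce(kp1, d1, kp2, d2)
    rev = match_bruteforce(kp2, d2, kp1, d1)
    pairs_fwd = {(int(i), int(j)) for i, j, _ in fwd.pairs}
    pairs_rev = {(int(j), int(i)) for i, j, _ in rev.pairs}
    assert pairs_fwd == pairs_rev


def test_relevance_gate_boundaries():
    """Exactly 50 matches is relevant; 49 and 0 are not."""
    def fake(n):
        pairs = np.zeros((n, 3), dtype=np.int64)
        pts = np.zeros((n, 2))
        return MatchSet(pairs, pts, pts)

    assert is_relevant_pair(fake(50)) is True
    assert is_relevant_pair(fake(49)) is False
    assert is_relevant_pair(fake(0)) is False


def test_matches_respect_ground_truth_epipolar_geometry(default_scene,
                                                        matched_pair):
    """On a rendered pair, at least 80% of retained matches lie within 2 px
    of the ground-truth epipolar transfer."""
    truth = default_scene
    K = truth.K.K
    tn = truth.t_true / np.linalg.norm(truth.t_true)
    tx = np.array([[0, -tn[2], tn[1]], [tn[2], 0, -tn[0]],
                   [-tn[1], tn[0], 0.0]])
    F = np.linalg.inv(K).T @ tx @ truth.R_true @ np.linalg.inv(K)
    F /= np.linalg.norm(F)
    sd = sampson_distance(F, matched_pair.points1, matched_pair.points2)
    assert (sd < 2.0).mean() >= 0.8
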
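"""Keypoint detection, binary description, and brute-force Hamming matching.

The pipeline needs repeatable corner-like features on both views and a
binary descriptor matched exhaustively with a mutual cross-check; any
binary descriptor fulfilling that contract works.  Two backends are
provided, both 256-bit:

``orb``
    skimage's ORB (oriented FAST + rotated BRIEF, image pyramid) — robust
    to the scale/rotation change between a fronto-parallel card template
    and its foreshortened in-scene appearance.  The default.
``fast-brief``
    single-scale FAST corners + BRIEF — several times faster, adequate for
    the near-pure-translation stereo pair itself.

A pair of food images is considered *relevant* only if matching produces
at least :data:`RELEVANCE_MIN_MATCHES` matches; irrelevant pairs abort the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import BRIEF, ORB, corner_fast, corner_peaks

from .errors import ParameterError
from .imaging import to_gray

#: Minimum number of brute-force matches for a pair to count as relevant.
RELEVANCE_MIN_MATCHES = 50


@dataclass
class KeypointSet:
    """Detected keypoints: positions ``xy`` (n, 2) in x-right/y-down pixel
    coordinates, detector ``response`` (n,), and ``scale`` (n,) in pixels."""

    xy: np.ndarray
    response: np.ndarray
    scale: np.ndarray

    def __len__(self) -> int:
        return len(self.xy)


@dataclass
class MatchSet:
    """Cross-checked matches between two keypoint sets.

    ``pairs`` holds (index1, index2, hamming_distance) triples; ``points1``
    and ``points2`` are the corresponding pixel coordinates, row i of one
    matching row i of the other.
    """

    pairs: np.ndarray  # (m, 3) int: i1, i2, hamming distance in bits
    points1: np.ndarray  # (m, 2) float
    points2: np.ndarray  # (m, 2) float

    def __len__(self) -> int:
        return len(self.pairs)

    def swapped(self) -> "MatchSet":
        """The same matches with the two image roles exchanged."""
        p = self.pairs[:, [1, 0, 2]]
        return MatchSet(p, self.points2.copy(), self.points1.copy())


def _pack(descriptors: np.ndarray) -> np.ndarray:
    """Pack a (n, nbits) boolean descriptor matrix into uint8 words."""
    return np.packbits(descriptors.astype(np.uint8), axis=1)


def detect_and_describe(img: np.ndarray, max_keypoints: int = 2000,
                        method: str = "orb") -> tuple[KeypointSet, np.ndarray]:
    """Detect keypoints and compute 256-bit binary descriptors.

    Returns at most ``max_keypoints`` keypoints sorted by decreasing
    detector response, with a (n, 256) boolean descriptor matrix.
    Deterministic for a fixed input; a textureless image yields an empty
    set (not an error).
    """
    if max_keypoints < 1:
        raise ParameterError(f"max_keypoints must be >= 1, got {max_keypoints}")
    gray = to_gray(img).astype(np.float64) / 255.0

    if method == "orb":
        det = ORB(n_keypoints=max_keypoints)
        try:
            det.detect_and_extract(gray)
        except RuntimeError:  # skimage raises when no keypoints survive
            return _empty()
        if len(det.keypoints) == 0:
            return _empty()
        xy = det.keypoints[:, ::-1].astype(np.float64)  # (row, col) -> (x, y)
        resp = det.responses.astype(np.float64)
        scale = det.scales.astype(np.float64)
        desc = det.descriptors.astype(bool)
    elif method == "fast-brief":
        response_img = corner_fast(gray, n=9, threshold=0.015)
        rc = corner_peaks(response_img, min_distance=3, threshold_rel=0.001)
        if len(rc) == 0:
            return _empty()
        resp = response_img[rc[:, 0], rc[:, 1]]
        extractor = BRIEF(descriptor_size=256, sigma=1.0)
        extractor.extract(gray, rc)
        offsets = _subpixel_peak(response_img, rc)
        rc, resp = rc[extractor.mask], resp[extractor.mask]
        offsets = offsets[extractor.mask]
        desc = extractor.descriptors.astype(bool)
        if len(rc) > max_keypoints:
            keep = np.argsort(-resp, kind="stable")[:max_keypoints]
            rc, resp, desc = rc[keep], resp[keep], desc[keep]
            offsets = offsets[keep]
        xy = rc[:, ::-1].astype(np.float64) + offsets[:, ::-1]
        scale = np.full(len(xy), 1.0)
    else:
        raise ParameterError(f"unknown detector/descriptor method {method!r}")

    order = np.argsort(-resp, kind="stable")
    return KeypointSet(xy[order], resp[order], scale[order]), desc[order]


def _subpixel_peak(response: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Per-axis parabolic sub-pixel refinement of detector response peaks.

    Returns (n, 2) offsets in (row, col), each clipped to [-0.5, 0.5]."""
    r, c = rc[:, 0], rc[:, 1]
    h, w = response.shape
    inside = (r > 0) & (r < h - 1) & (c > 0) & (c < w - 1)
    out = np.zeros((len(rc), 2))

    def axis_offset(minus, center, plus):
        den = minus - 2 * center + plus
        with np.errstate(divide="ignore", invalid="ignore"):
            off = 0.5 * (minus - plus) / den
        return np.clip(np.where(np.abs(den) > 1e-12, off, 0.0), -0.5, 0.5)

    ri, ci = r[inside], c[inside]
    out[inside, 0] = axis_offset(response[ri - 1, ci], response[ri, ci],
                                 response[ri + 1, ci])
    out[inside, 1] = axis_offset(response[ri, ci - 1], response[ri, ci],
                                 response[ri, ci + 1])
    return out


def _empty() -> tuple[KeypointSet, np.ndarray]:
    return (KeypointSet(np.empty((0, 2)), np.empty(0), np.empty(0)),
            np.empty((0, 256), dtype=bool))


def hamming_distance_matrix(desc1: np.ndarray, desc2: np.ndarray,
                            chunk: int = 512) -> np.ndarray:
    """(n1, n2) matrix of Hamming distances between boolean descriptor rows."""
    if desc1.shape[1] != desc2.shape[1]:
        raise ParameterError(
            f"descriptor lengths differ: {desc1.shape[1]} vs {desc2.shape[1]}")
    p1, p2 = _pack(desc1), _pack(desc2)
    out = np.empty((len(p1), len(p2)), dtype=np.int32)
    for lo in range(0, len(p1), chunk):
        hi = min(lo + chunk, len(p1))
        xor = p1[lo:hi, None, :] ^ p2[None, :, :]
        out[lo:hi] = np.bitwise_count(xor).sum(axis=2, dtype=np.int32)
    return out


def match_bruteforce(kp1: KeypointSet, desc1: np.ndarray,
                     kp2: KeypointSet, desc2: np.ndarray,
                     max_distance: int = 256) -> MatchSet:
    """Exhaustive Hamming matching with a mutual cross-check.

    A pair (i, j) is retained iff j is i's nearest neighbor in image 2 and
    i is j's nearest neighbor in image 1, so no index appears twice on
    either side.  ``max_distance`` optionally discards pairs above a
    Hamming distance (off by default — downstream robust estimation
    benefits from the full cross-checked set, while the relevance gate
    applies its own confidence cut).  Nearest-neighbor ties resolve to
    the lowest index, making the result deterministic.
    """
    if len(desc1) == 0 or len(desc2) == 0:
        return MatchSet(np.empty((0, 3), dtype=np.int64),
                        np.empty((0, 2)), np.empty((0, 2)))
    dist = hamming_distance_matrix(desc1, desc2)
    nn12 = np.argmin(dist, axis=1)
    nn21 = np.argmin(dist, axis=0)
    i1 = np.arange(len(desc1))
    mutual = nn21[nn12] == i1
    i1, i2 = i1[mutual], nn12[mutual]
    d = dist[i1, i2]
    close = d <= max_distance
    i1, i2, d = i1[close], i2[close], d[close]
    order = np.argsort(i1, kind="stable")
    i1, i2, d = i1[order], i2[order], d[order]
    pairs = np.stack([i1, i2, d], axis=1).astype(np.int64)
    return MatchSet(pairs, kp1.xy[i1].copy(), kp2.xy[i2].copy())


def is_relevant_pair(matches: MatchSet,
                     min_matches: int = RELEVANCE_MIN_MATCHES,
                     max_distance: int = 64) -> bool:
    """True iff the pair produced at least ``min_matches`` confident
    matches.

    Only matches below ``max_distance`` Hamming bits count: chance mutual
    nearest neighbors between unrelated images cluster near the random
    level of 128 bits, genuine correspondences far below it, so counting
    raw pairs would let any two busy images pass the gate.
    """
    if len(matches) == 0:
        return False
    confident = int((matches.pairs[:, 2] <= max_distance).sum())
    return confident >= min_matches
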
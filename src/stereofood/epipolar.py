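"""Two-view epipolar geometry: robust inlier filtering, fundamental/essential
matrix estimation, optimal correspondence correction, and relative pose
recovery with the cheirality check.

Conventions
-----------
A world point ``X`` expressed in camera-1 coordinates maps into camera 2 as
``x2 = R @ x1 + t``; ``t`` is recovered with unit norm (the metric scale is
fixed later by the reference card).  Pixel coordinates are homogeneous
``(x, y, 1)`` with x right / y down.  The epipolar constraint is
``x2^T F x1 = 0`` and ``E = K2^T F K1``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (AmbiguousPoseError, DegeneracyError,
                     EstimationFailureError, InputError, ParameterError)
from .features import MatchSet

# --------------------------------------------------------------------------
# data types


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics in pixels; ``image_shape`` is the (rows, cols)
    geometry the parameters refer to."""

    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0
    image_shape: tuple[int, int] | None = None

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ParameterError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, self.skew, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    def rescaled(self, new_shape: tuple[int, int]) -> "CameraIntrinsics":
        """Intrinsics for the same camera after resizing the image to
        ``new_shape`` (rows, cols).  Requires ``image_shape`` to be set."""
        if self.image_shape is None:
            raise ParameterError("image_shape unknown; cannot rescale K")
        sy = new_shape[0] / self.image_shape[0]
        sx = new_shape[1] / self.image_shape[1]
        return CameraIntrinsics(self.fx * sx, self.fy * sy,
                                (self.cx + 0.5) * sx - 0.5,
                                (self.cy + 0.5) * sy - 0.5,
                                self.skew * sx, tuple(new_shape))

    @classmethod
    def from_json(cls, path) -> "CameraIntrinsics":
        """Load from a JSON calibration file with keys fx, fy, cx, cy and
        optional skew, image_height, image_width."""
        try:
            with open(path) as fh:
                d = json.load(fh)
            shape = None
            if "image_height" in d and "image_width" in d:
                shape = (int(d["image_height"]), int(d["image_width"]))
            return cls(float(d["fx"]), float(d["fy"]), float(d["cx"]),
                       float(d["cy"]), float(d.get("skew", 0.0)), shape)
        except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
            raise InputError(f"cannot read calibration {path!r}: {exc}") from exc

    def to_json(self, path) -> None:
        d = {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
             "skew": self.skew}
        if self.image_shape is not None:
            d["image_height"], d["image_width"] = int(self.image_shape[0]), \
                int(self.image_shape[1])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class HomographyEstimate:
    """RANSAC homography (image 1 -> image 2) with its per-match inlier mask
    and the pixel threshold that defined an inlier."""

    H: np.ndarray
    inlier_mask: np.ndarray
    threshold_px: float


@dataclass
class InlierSet:
    """Inlier correspondences, optionally with optimally corrected
    coordinates satisfying the epipolar constraint exactly."""

    points1: np.ndarray
    points2: np.ndarray
    corrected1: np.ndarray | None = None
    corrected2: np.ndarray | None = None
    uncorrectable: np.ndarray | None = None  # epipole-coincident pairs

    def __len__(self) -> int:
        return len(self.points1)

    @property
    def best1(self) -> np.ndarray:
        return self.points1 if self.corrected1 is None else self.corrected1

    @property
    def best2(self) -> np.ndarray:
        return self.points2 if self.corrected2 is None else self.corrected2


@dataclass
class RelativePose:
    """Rotation and unit translation of camera 2 w.r.t. camera 1, plus the
    metric scale factor (cm per reconstruction unit) once determined."""

    R: np.ndarray
    t: np.ndarray
    scale: float | None = None

    def __post_init__(self):
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8) or \
                not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-8):
            raise ParameterError("R must be a proper rotation")
        n = np.linalg.norm(self.t)
        if not np.isfinite(n) or n == 0:
            raise ParameterError("t must be a nonzero vector")
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3) / n


# --------------------------------------------------------------------------
# helpers


def _homog(pts: np.ndarray) -> np.ndarray:
    return np.hstack([pts, np.ones((len(pts), 1))])


def _hartley_normalization(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform taking the points to centroid 0, RMS distance
    sqrt(2); returns (T, transformed homogeneous points)."""
    c = pts.mean(axis=0)
    d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    return T, _homog(pts) @ T.T


def homography_dlt(pts1: np.ndarray, pts2: np.ndarray) -> np.ndarray:
    """Normalized DLT homography from >= 4 correspondences."""
    if len(pts1) < 4:
        raise DegeneracyError("homography needs >= 4 correspondences")
    T1, x1 = _hartley_normalization(pts1)
    T2, x2 = _hartley_normalization(pts2)
    n = len(pts1)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = x1
    A[0::2, 6:9] = -x2[:, [0]] * x1
    A[1::2, 3:6] = x1
    A[1::2, 6:9] = -x2[:, [1]] * x1
    if len(A) < 9:  # keep the null space under the economy SVD
        A = np.vstack([A, np.zeros((9 - len(A), 9))])
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    if s[7] < 1e-12 * s[0]:
        raise DegeneracyError("degenerate configuration for homography")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(T2) @ Hn @ T1
    if abs(H[2, 2]) > 1e-12:
        H = H / H[2, 2]
    return H


def symmetric_transfer_error(H: np.ndarray, pts1: np.ndarray,
                             pts2: np.ndarray) -> np.ndarray:
    """Per-pair max of forward and backward reprojection distances (px)."""
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(len(pts1), np.inf)
    f = _homog(pts1) @ H.T
    b = _homog(pts2) @ Hinv.T
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = np.linalg.norm(f[:, :2] / f[:, [2]] - pts2, axis=1)
        be = np.linalg.norm(b[:, :2] / b[:, [2]] - pts1, axis=1)
    err = np.maximum(fe, be)
    return np.where(np.isfinite(err), err, np.inf)


def sampson_distance(F: np.ndarray, pts1: np.ndarray,
                     pts2: np.ndarray) -> np.ndarray:
    """First-order geometric (Sampson) distance to the epipolar constraint."""
    x1, x2 = _homog(pts1), _homog(pts2)
    Fx1 = x1 @ F.T
    Ftx2 = x2 @ F
    num = np.einsum("ij,ij->i", x2, Fx1) ** 2
    den = Fx1[:, 0] ** 2 + Fx1[:, 1] ** 2 + Ftx2[:, 0] ** 2 + Ftx2[:, 1] ** 2
    return np.sqrt(num / np.maximum(den, 1e-300))


def ransac_threshold_px(image_dims: tuple[int, int],
                        fraction: float = 0.006) -> float:
    """Inlier threshold: the stated fraction (0.6%) of the largest image
    dimension, in pixels (4.8 px at 600 x 800)."""
    return fraction * max(image_dims)


# --------------------------------------------------------------------------
# robust inlier filtering


def filter_inliers_ransac(matches: MatchSet, image_dims: tuple[int, int],
                          confidence: float = 0.99, seed: int = 0,
                          max_iters: int = 5000,
                          threshold_fraction: float = 0.006,
                          model: str = "homography") -> HomographyEstimate:
    """Separate inlier from outlier matches with seeded RANSAC.

    The default model is a plane-projective homography, with threshold
    0.6% of the largest image dimension (symmetric reprojection error) and
    99% confidence.  ``model="fundamental"`` switches to a fundamental-
    matrix model with the Sampson distance at the same threshold — useful
    on strongly non-planar scenes where homography filtering would bias
    the inliers toward the dominant plane.

    Deterministic for a fixed seed; the model is refit to all inliers by
    least squares before returning.
    """
    if model == "homography":
        min_samples, fit, err = 4, homography_dlt, symmetric_transfer_error
    elif model == "fundamental":
        min_samples = 8
        fit, err = fundamental_8point, sampson_distance
    else:
        raise ParameterError(f"unknown RANSAC model {model!r}")
    pts1, pts2 = matches.points1, matches.points2
    n = len(pts1)
    if n < min_samples:
        raise DegeneracyError(
            f"RANSAC needs >= {min_samples} matches, got {n}")
    if not 0 < confidence < 1:
        raise ParameterError(f"confidence must be in (0, 1), got {confidence}")
    thr = ransac_threshold_px(image_dims, threshold_fraction)
    rng = np.random.default_rng(seed)

    best_mask = None
    best_count = 0
    iters_needed = max_iters
    it = 0
    while it < min(iters_needed, max_iters):
        it += 1
        idx = rng.choice(n, size=min_samples, replace=False)
        try:
            M = fit(pts1[idx], pts2[idx])
        except DegeneracyError:
            continue
        mask = err(M, pts1, pts2) < thr
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
            w = count / n
            if w > 0:
                denom = np.log1p(-min(w ** min_samples, 1 - 1e-12))
                iters_needed = int(np.ceil(np.log(1 - confidence) / denom)) \
                    if denom < 0 else max_iters
    if best_mask is None or best_count < min_samples:
        raise EstimationFailureError(
            "RANSAC found no model with sufficient support")
    M = fit(pts1[best_mask], pts2[best_mask])
    best_mask = err(M, pts1, pts2) < thr
    if best_mask.sum() >= min_samples:  # refit once on consolidated inliers
        M = fit(pts1[best_mask], pts2[best_mask])
        best_mask = err(M, pts1, pts2) < thr
    return HomographyEstimate(M, best_mask, thr)


def inliers_from_estimate(matches: MatchSet,
                          est: HomographyEstimate) -> InlierSet:
    m = est.inlier_mask
    return InlierSet(matches.points1[m].copy(), matches.points2[m].copy())


# --------------------------------------------------------------------------
# fundamental / essential matrices


def fundamental_8point(pts1: np.ndarray, pts2: np.ndarray) -> np.ndarray:
    """Normalized 8-point fundamental matrix with rank-2 enforcement.

    Returns F with unit Frobenius norm; ``x2^T F x1 = 0``.  Raises
    :class:`DegeneracyError` for < 8 pairs or a rank-deficient (e.g. all
    collinear) configuration.
    """
    if len(pts1) < 8:
        raise DegeneracyError(f"8-point method needs >= 8 pairs, got {len(pts1)}")
    T1, x1 = _hartley_normalization(pts1)
    T2, x2 = _hartley_normalization(pts2)
    A = (x2[:, :, None] * x1[:, None, :]).reshape(len(pts1), 9)
    if len(A) < 9:  # keep the null space under the economy SVD
        A = np.vstack([A, np.zeros((9 - len(A), 9))])
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    if s[7] < 1e-10 * s[0]:
        raise DegeneracyError("degenerate point configuration for F")
    Fn = vt[-1].reshape(3, 3)
    U, sv, Vt = np.linalg.svd(Fn)
    Fn = U @ np.diag([sv[0], sv[1], 0.0]) @ Vt
    F = T2.T @ Fn @ T1
    return F / np.linalg.norm(F)


def estimate_fundamental(inl: InlierSet) -> np.ndarray:
    """Fundamental matrix from the inlier correspondences (normalized
    8-point on all pairs)."""
    return fundamental_8point(inl.points1, inl.points2)


def _epipole_from_parallax(a: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    """Maximum-likelihood epipole from parallax segments a_i -> b_i.

    Each residual is the pixel deviation of b_i from the ray cast from a_i
    toward the epipole, so the objective stays meaningful for an epipole
    at or near infinity (near-parallel segments) and is not attracted to
    finite points inside the segment cluster the way the algebraic
    line-through-epipole formulation is.  Solved over the homogeneous
    epipole on the unit sphere with a robust (soft-L1) loss.
    """
    from scipy.optimize import least_squares

    seg = b - a
    # initial guess: dominant segment direction, epipole at infinity
    M = seg.T @ seg
    _, vec = np.linalg.eigh(M)
    d0 = vec[:, -1]
    e0 = np.array([d0[0], d0[1], 0.0])

    def residuals(e):
        e = e / np.linalg.norm(e)
        u = np.stack([e[0] - a[:, 0] * e[2], e[1] - a[:, 1] * e[2]], axis=1)
        un = np.linalg.norm(u, axis=1)
        un = np.maximum(un, 1e-12)
        return (seg[:, 0] * u[:, 1] - seg[:, 1] * u[:, 0]) / un

    # both epipole signs describe the same geometry; pick the better start
    if np.abs(residuals(e0)).sum() > np.abs(residuals(-e0)).sum():
        e0 = -e0
    try:
        sol = least_squares(residuals, e0, loss="soft_l1", f_scale=0.75,
                            max_nfev=200)
    except Exception:
        return None
    e = sol.x
    n = np.linalg.norm(e)
    if not np.isfinite(n) or n == 0:
        return None
    return e / n


def fundamental_plane_parallax(matches_pts1: np.ndarray,
                               matches_pts2: np.ndarray,
                               H: np.ndarray,
                               min_parallax_px: float = 1.2,
                               max_parallax_px: float = 25.0,
                               min_offplane: int = 10) -> np.ndarray | None:
    """Fundamental matrix via plane + parallax, for plane-dominated scenes.

    A tabletop food scene is mostly one plane; the unstructured 8-point
    method is then near-degenerate, because every F in the pencil
    ``[e]_x H`` fits the planar points.  Given the dominant-plane
    homography ``H``, each off-plane correspondence constrains the epipole
    instead: the residual segment from ``H x1`` to ``x2`` lies on an
    epipolar line, so all such segments meet in the epipole ``e2``; then
    ``F = [e2]_x H``.

    Robustness: the plane homography is first refit tightly (2 px) so the
    residuals measure true off-plane parallax; residual segments are kept
    only in a parallax band (below ``min_parallax_px`` is detection noise,
    above ``max_parallax_px`` is a mismatch — genuine food parallax in the
    capture protocol is a few pixels); the epipole is solved by IRLS with
    a Cauchy weight, so stray mismatched lines are downweighted.

    Returns None when fewer than ``min_offplane`` usable off-plane
    correspondences exist — the caller should fall back to 8-point.
    """
    err = symmetric_transfer_error(H, matches_pts1, matches_pts2)
    tight = err < 2.0
    if tight.sum() >= 8:
        try:
            H = homography_dlt(matches_pts1[tight], matches_pts2[tight])
        except DegeneracyError:
            pass
    a = _homog(matches_pts1) @ H.T
    with np.errstate(divide="ignore", invalid="ignore"):
        a = a / a[:, [2]]
    b = _homog(matches_pts2)
    par = np.linalg.norm(a[:, :2] - b[:, :2], axis=1)
    sel = np.isfinite(par) & (par > min_parallax_px) & (par < max_parallax_px)
    if sel.sum() < min_offplane:
        return None
    e2 = _epipole_from_parallax(a[sel, :2], b[sel, :2])
    if e2 is None:
        return None
    ex = np.array([[0, -e2[2], e2[1]],
                   [e2[2], 0, -e2[0]],
                   [-e2[1], e2[0], 0.0]])
    F = ex @ H
    n = np.linalg.norm(F)
    if not np.isfinite(n) or n == 0:
        return None
    return F / n


def essential_from_fundamental(F: np.ndarray, K1: CameraIntrinsics,
                               K2: CameraIntrinsics) -> np.ndarray:
    """E = K2^T F K1, with singular values projected to (s, s, 0)."""
    E = K2.K.T @ F @ K1.K
    U, s, Vt = np.linalg.svd(E)
    sigma = 0.5 * (s[0] + s[1])
    return U @ np.diag([sigma, sigma, 0.0]) @ Vt


# --------------------------------------------------------------------------
# optimal (Hartley–Sturm) correction


def _closest_point_on_line(line: np.ndarray) -> np.ndarray:
    a, b, c = line
    return np.array([-a * c, -b * c, a * a + b * b])


def _correct_single(x1: np.ndarray, x2: np.ndarray,
                    F: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Hartley–Sturm optimal correction of one correspondence.

    Minimizes d(x1, x1')^2 + d(x2, x2')^2 subject to x2'^T F x1' = 0 by
    parametrizing the epipolar-line pencil and solving the 6th-degree
    polynomial in the line parameter; the minimizing root gives the pair
    of epipolar lines onto which the points are orthogonally projected.
    Returns (corrected1, corrected2, ok); ``ok`` is False when the point
    coincides with an epipole and the pair is passed through unchanged.
    """
    T1 = np.array([[1, 0, -x1[0]], [0, 1, -x1[1]], [0, 0, 1.0]])
    T2 = np.array([[1, 0, -x2[0]], [0, 1, -x2[1]], [0, 0, 1.0]])
    # F in the translated frames: constraint (T2 x2)^T Ft (T1 x1) = 0
    Ft = np.linalg.inv(T2).T @ F @ np.linalg.inv(T1)
    # epipoles: Ft e1 = 0, Ft^T e2 = 0, normalized to e_x^2 + e_y^2 = 1
    _, _, Vt = np.linalg.svd(Ft)
    e1 = Vt[-1]
    U, _, _ = np.linalg.svd(Ft)
    e2 = U[:, -1]
    n1 = np.hypot(e1[0], e1[1])
    n2 = np.hypot(e2[0], e2[1])
    if n1 < 1e-12 or n2 < 1e-12:
        return x1.copy(), x2.copy(), False  # point at an epipole
    e1, e2 = e1 / n1, e2 / n2
    R1 = np.array([[e1[0], e1[1], 0], [-e1[1], e1[0], 0], [0, 0, 1.0]])
    R2 = np.array([[e2[0], e2[1], 0], [-e2[1], e2[0], 0], [0, 0, 1.0]])
    Fr = R2 @ Ft @ R1.T
    f1, f2 = e1[2], e2[2]
    a, b, c, d = Fr[1, 1], Fr[1, 2], Fr[2, 1], Fr[2, 2]

    # g(t) = t((at+b)^2 + f2^2 (ct+d)^2)^2 - (ad-bc)(1+f1^2 t^2)^2 (at+b)(ct+d)
    p1 = np.polynomial.polynomial.polymul(np.array([b, a]), np.array([b, a]))
    p2 = np.polynomial.polynomial.polymul(np.array([d, c]), np.array([d, c]))
    q = np.polynomial.polynomial.polyadd(p1, f2 * f2 * p2)
    lhs = np.polynomial.polynomial.polymul(
        np.array([0.0, 1.0]), np.polynomial.polynomial.polymul(q, q))
    r = np.array([1.0, 0.0, f1 * f1])
    rhs = (a * d - b * c) * np.polynomial.polynomial.polymul(
        np.polynomial.polynomial.polymul(r, r),
        np.polynomial.polynomial.polymul(np.array([b, a]), np.array([d, c])))
    g = np.polynomial.polynomial.polysub(lhs, rhs)
    if np.allclose(g, 0.0):
        roots = np.array([0.0])
    else:
        roots = np.polynomial.polynomial.polyroots(g)
        roots = np.real(roots[np.abs(roots.imag) < 1e-8])

    def cost(t):
        return (t * t / (1 + f1 * f1 * t * t)
                + (c * t + d) ** 2 / ((a * t + b) ** 2 + f2 * f2 * (c * t + d) ** 2))

    candidates = [(cost(t), t) for t in roots]
    # the t -> infinity asymptote can be the minimizer
    inf_cost = 1.0 / (f1 * f1) + c * c / (a * a + f2 * f2 * c * c) \
        if f1 != 0 else np.inf
    use_inf = bool(candidates) is False or inf_cost < min(c0 for c0, _ in candidates)
    if use_inf:
        l1 = np.array([f1, 0.0, -1.0])
        l2 = Fr @ np.array([0.0, 1.0, 0.0])
    else:
        _, t = min(candidates, key=lambda ct: ct[0])
        l1 = np.array([t * f1, 1.0, -t])
        l2 = Fr @ np.array([0.0, t, 1.0])
    xh1 = _closest_point_on_line(l1)
    xh2 = _closest_point_on_line(l2)
    xh1 = np.linalg.inv(T1) @ R1.T @ xh1
    xh2 = np.linalg.inv(T2) @ R2.T @ xh2
    return xh1[:2] / xh1[2], xh2[:2] / xh2[2], True


def correct_optimal(inl: InlierSet, F: np.ndarray) -> InlierSet:
    """Optimal-triangulation correction of every inlier pair.

    Fills ``corrected1``/``corrected2`` with the coordinates minimizing the
    summed squared displacement subject to the epipolar constraint; pairs
    coinciding with an epipole are flagged in ``uncorrectable`` and passed
    through with a warning.
    """
    c1 = np.empty_like(inl.points1)
    c2 = np.empty_like(inl.points2)
    bad = np.zeros(len(inl), dtype=bool)
    for i in range(len(inl)):
        c1[i], c2[i], ok = _correct_single(inl.points1[i], inl.points2[i], F)
        bad[i] = not ok
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pair(s) coincide with an epipole; "
                      "passed through uncorrected", stacklevel=2)
    return InlierSet(inl.points1, inl.points2, c1, c2, bad)


def epipolar_residuals(F: np.ndarray, pts1: np.ndarray,
                       pts2: np.ndarray) -> np.ndarray:
    """|x2^T F x1| per pair, with F scaled to unit Frobenius norm."""
    Fn = F / np.linalg.norm(F)
    return np.abs(np.einsum("ij,ij->i", _homog(pts2), _homog(pts1) @ Fn.T))


# --------------------------------------------------------------------------
# triangulation and pose


def triangulate_linear(pts1: np.ndarray, pts2: np.ndarray,
                       P1: np.ndarray, P2: np.ndarray) -> np.ndarray:
    """Batched DLT triangulation; returns (n, 3) points in camera-1 units."""
    n = len(pts1)
    A = np.empty((n, 4, 4))
    A[:, 0] = pts1[:, [0]] * P1[2] - P1[0]
    A[:, 1] = pts1[:, [1]] * P1[2] - P1[1]
    A[:, 2] = pts2[:, [0]] * P2[2] - P2[0]
    A[:, 3] = pts2[:, [1]] * P2[2] - P2[1]
    _, _, Vt = np.linalg.svd(A, full_matrices=False)
    X = Vt[:, -1, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        return X[:, :3] / X[:, [3]]


def projection_matrices(K1: CameraIntrinsics, K2: CameraIntrinsics,
                        R: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P1 = K1.K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    P2 = K2.K @ np.hstack([R, np.asarray(t).reshape(3, 1)])
    return P1, P2


def triangulate_points(inl: InlierSet, K1: CameraIntrinsics,
                       K2: CameraIntrinsics, pose: RelativePose
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the (corrected, if available) correspondences.

    Returns (points (n, 3) in reconstruction units, in_front mask); points
    with non-positive depth in either camera are flagged False.
    """
    P1, P2 = projection_matrices(K1, K2, pose.R, pose.t)
    X = triangulate_linear(inl.best1, inl.best2, P1, P2)
    z1 = X[:, 2]
    z2 = (X @ pose.R.T + pose.t)[:, 2]
    in_front = np.isfinite(X).all(axis=1) & (z1 > 0) & (z2 > 0)
    return X, in_front


def decompose_essential(E: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """The four (R, t) candidates of an essential matrix, ||t|| = 1."""
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    Ra, Rb = U @ W @ Vt, U @ W.T @ Vt
    t = U[:, 2] / np.linalg.norm(U[:, 2])
    return [(Ra, t), (Ra, -t), (Rb, t), (Rb, -t)]


def recover_pose(E: np.ndarray, inl: InlierSet, K1: CameraIntrinsics,
                 K2: CameraIntrinsics) -> tuple[RelativePose, np.ndarray]:
    """Select the (R, t) decomposition passing the cheirality check.

    All four candidates triangulate every correspondence; the candidate
    with the most points of positive depth in both cameras wins.  A tie or
    a winner with under half the points in front raises
    :class:`AmbiguousPoseError` with diagnostics.
    """
    if len(inl) < 5:
        raise DegeneracyError(f"pose recovery needs >= 5 inliers, got {len(inl)}")
    counts, masks, poses = [], [], []
    for R, t in decompose_essential(E):
        pose = RelativePose(R, t)
        _, in_front = triangulate_points(inl, K1, K2, pose)
        counts.append(int(in_front.sum()))
        masks.append(in_front)
        poses.append(pose)
    order = np.argsort(counts)[::-1]
    best, second = order[0], order[1]
    if counts[best] == counts[second]:
        raise AmbiguousPoseError(
            f"cheirality tie between candidates: counts={counts}")
    if counts[best] < 0.5 * len(inl):
        raise AmbiguousPoseError(
            f"best candidate has only {counts[best]}/{len(inl)} points in "
            f"front; counts={counts}")
    return poses[best], masks[best]


def decompose_homography(H: np.ndarray, K1: CameraIntrinsics,
                         K2: CameraIntrinsics
                         ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Decompose a plane homography into (R, unit t, plane normal) triples.

    Faugeras-Lustman SVD decomposition of the calibrated homography
    ``Hc = K2^-1 H K1``: for a scene plane with unit normal ``n`` (camera-1
    frame) at distance d, ``Hc ~ R + t n^T / d``.  Up to eight algebraic
    solutions exist; those with the plane behind camera 1 are dropped and
    duplicates merged.  The caller disambiguates the remainder with
    off-plane correspondences and the cheirality check (see
    :func:`recover_pose_planar`).
    """
    Hc = np.linalg.inv(K2.K) @ H @ K1.K
    _, sv, _ = np.linalg.svd(Hc)
    Hn = Hc / sv[1]
    U, d, Vt = np.linalg.svd(Hn)
    V = Vt.T
    s = np.linalg.det(U) * np.linalg.det(V)
    d1, d2, d3 = d
    if d1 - d3 < 1e-9:  # pure rotation: plane at infinity / zero baseline
        R = s * U @ Vt
        return [(R, np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 1.0]))]
    x1 = np.sqrt(max((d1 * d1 - d2 * d2) / (d1 * d1 - d3 * d3), 0.0))
    x3 = np.sqrt(max((d2 * d2 - d3 * d3) / (d1 * d1 - d3 * d3), 0.0))
    sols = []
    for e1 in (1.0, -1.0):
        for e3 in (1.0, -1.0):
            a, c = e1 * x1, e3 * x3
            sin_t = (d1 - d3) * a * c / d2
            cos_t = (d1 * c * c + d3 * a * a) / d2
            Rp = np.array([[cos_t, 0, -sin_t], [0, 1, 0], [sin_t, 0, cos_t]])
            tp = (d1 - d3) * np.array([a, 0.0, -c])
            sols.append((s * U @ Rp @ Vt, U @ tp, V @ np.array([a, 0.0, c])))
            sin_p = (d1 + d3) * a * c / d2
            cos_p = (d3 * a * a - d1 * c * c) / d2
            Rp2 = np.array([[cos_p, 0, sin_p], [0, -1, 0],
                            [sin_p, 0, -cos_p]])
            tp2 = (d1 + d3) * np.array([a, 0.0, c])
            sols.append((s * U @ Rp2 @ Vt, U @ tp2, V @ np.array([a, 0.0, c])))
    out = []
    for R, t, n in sols:
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            continue
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            continue
        if n[2] <= 0:  # plane must face camera 1 (points along +z rays)
            n, t = -n, -t
        t = t / nt
        dup = False
        for R0, t0, n0 in out:
            if np.abs(R - R0).max() < 1e-9 and np.abs(t - t0).max() < 1e-9:
                dup = True
                break
        if not dup:
            out.append((R, t, n))
    return out


def recover_pose_planar(H: np.ndarray, matches: MatchSet, inl: InlierSet,
                        K1: CameraIntrinsics, K2: CameraIntrinsics
                        ) -> tuple[RelativePose, np.ndarray, np.ndarray]:
    """Relative pose for a plane-dominated scene via homography
    decomposition, disambiguated by off-plane parallax and cheirality.

    The tabletop protocol makes the table the dominant plane, so the
    RANSAC homography is far better conditioned than any fundamental-
    matrix estimate; its decomposition candidates are scored by the median
    Sampson distance of the off-plane (high-parallax) matches, and the
    survivors are put through the cheirality check on the inliers.

    Returns (pose, in-front mask over the inliers, plane normal in the
    camera-1 frame).  Raises :class:`AmbiguousPoseError` when no candidate
    passes.
    """
    err = symmetric_transfer_error(H, matches.points1, matches.points2)
    off = err > 2.5
    cands = decompose_homography(H, K1, K2)
    if not cands:
        raise AmbiguousPoseError("homography decomposition produced no "
                                 "valid candidate")
    scores = []
    for R, t, n in cands:
        tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]],
                       [-t[1], t[0], 0.0]])
        F = np.linalg.inv(K2.K).T @ (tx @ R) @ np.linalg.inv(K1.K)
        nrm = np.linalg.norm(F)
        if nrm == 0 or not np.isfinite(nrm):
            scores.append(np.inf)
            continue
        sd = sampson_distance(F / nrm, matches.points1, matches.points2)
        scores.append(float(np.median(sd[off])) if off.sum() >= 10
                      else float(np.median(sd)))
    best_score = min(scores)
    keep = [c for c, sc in zip(cands, scores)
            if sc <= max(1.25 * best_score, best_score + 0.05)]
    best_pose, best_mask, best_normal, best_count = None, None, None, -1
    for R, t, n in keep:
        pose = RelativePose(R, t)
        _, in_front = triangulate_points(inl, K1, K2, pose)
        if int(in_front.sum()) > best_count:
            best_count = int(in_front.sum())
            best_pose, best_mask, best_normal = pose, in_front, n
    if best_pose is None or best_count < 0.5 * len(inl):
        raise AmbiguousPoseError(
            f"no homography-decomposition candidate passed cheirality "
            f"(best {best_count}/{len(inl)} in front)")
    return best_pose, best_mask, best_normal


def reproject(K: CameraIntrinsics, R: np.ndarray, t: np.ndarray,
              X: np.ndarray) -> np.ndarray:
    """Project 3D points (camera-1 frame) into a camera with pose (R, t)."""
    x = (X @ R.T + np.asarray(t).reshape(1, 3)) @ K.K.T
    return x[:, :2] / x[:, [2]]
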
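"""Metric scale from the reference card.

Two-view reconstruction fixes geometry only up to a global scale.  The
capture protocol resolves it with a card of known physical size
(8.5 x 5.5 cm) lying on the table: the card is located in each image by
matching a template of its printed pattern and fitting a homography, its
four corners are triangulated, and the scale factor is the ratio
d_ref / d_est between the card's real long-edge length and the
reconstructed one.  Multiplying the reconstruction by that factor puts
every coordinate in centimeters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synthetic
from .epipolar import (CameraIntrinsics, InlierSet, RelativePose,
                       filter_inliers_ransac, triangulate_points)
from .errors import CardNotFoundError, EstimationFailureError, UsageError
from .features import MatchSet, detect_and_describe, match_bruteforce
from .imaging import to_gray


@dataclass
class ReferenceCardSpec:
    """Physical card dimensions plus the template image of its pattern."""

    long_edge_cm: float = 8.5
    short_edge_cm: float = 5.5
    template: np.ndarray = field(
        default_factory=lambda: synthetic.make_card_template())

    def __post_init__(self):
        if not self.long_edge_cm > self.short_edge_cm > 0:
            raise EstimationFailureError(
                "card spec requires long_edge_cm > short_edge_cm > 0")

    @property
    def template_corners_px(self) -> np.ndarray:
        """Template corner pixels in convex order (TL, TR, BR, BL)."""
        h, w = self.template.shape[:2]
        return np.array([[0.0, 0.0], [w - 1.0, 0.0],
                         [w - 1.0, h - 1.0], [0.0, h - 1.0]])


@dataclass
class CardDetection:
    """Card corners in one image and the template-to-image homography."""

    corners_px: np.ndarray  # (4, 2), convex image order
    H_card: np.ndarray  # 3 x 3
    n_matches: int


def _is_convex_quad(corners: np.ndarray) -> bool:
    d = np.roll(corners, -1, axis=0) - corners
    cross = d[:, 0] * np.roll(d, -1, axis=0)[:, 1] \
        - d[:, 1] * np.roll(d, -1, axis=0)[:, 0]
    return bool((cross > 0).all() or (cross < 0).all())


def _card_region_mask(img: np.ndarray) -> np.ndarray | None:
    """Footprint mask of the card: the largest connected region made of
    near-black and achromatic near-white pixels that contains a healthy
    share of both (the printed pattern is a black/white mixture; the dish
    rim is bright but has no black, dark food has no achromatic white)."""
    from scipy import ndimage as ndi
    g = to_gray(img).astype(np.int16)
    if img.ndim == 3:
        f = img.astype(np.int16)
        chroma = f.max(axis=2) - f.min(axis=2)
    else:
        chroma = np.zeros_like(g)
    black = g < 50
    white = (g > 140) & (chroma < 30)
    cand = ndi.binary_closing(black | white, iterations=2)
    cand = ndi.binary_fill_holes(cand)
    lab, n = ndi.label(cand)
    if n == 0:
        return None
    best, best_size = None, 0
    for i in range(1, n + 1):
        region = lab == i
        size = int(region.sum())
        if size < 400 or size < best_size:
            continue
        nb = int((region & black).sum())
        nw = int((region & white).sum())
        # the print is a dense black/white mixture filling the card; a
        # bright dish rim closed into a disk has a mostly-textured interior
        if nb > 0.08 * size and nw > 0.15 * size and \
                nb + nw > 0.55 * size:
            best, best_size = region, size
    return best


def _quad_from_mask(region: np.ndarray) -> np.ndarray | None:
    """Coarse corner estimate: the four convex-hull points spanning the
    region (diagonal extremes plus the extremes on either side of that
    diagonal), ordered clockwise in image coordinates."""
    from scipy.spatial import ConvexHull, QhullError
    ys, xs = np.nonzero(region)
    pts = np.stack([xs, ys], axis=1).astype(np.float64)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except (QhullError, IndexError):
        return None
    c0 = hull[np.argmax(((hull - hull.mean(0)) ** 2).sum(1))]
    c1 = hull[np.argmax(((hull - c0) ** 2).sum(1))]
    d = c1 - c0
    signed = (hull[:, 0] - c0[0]) * d[1] - (hull[:, 1] - c0[1]) * d[0]
    if signed.max() <= 0 or signed.min() >= 0:
        return None  # degenerate: all hull points on one side
    c2 = hull[np.argmax(signed)]
    c3 = hull[np.argmin(signed)]
    quad = np.stack([c0, c1, c2, c3])
    ctr = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 1] - ctr[1], quad[:, 0] - ctr[0])
    return quad[np.argsort(ang)]


def _refine_quad_lines(region: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Sub-pixel corner refinement: assign mask boundary pixels to the
    nearest quad edge, fit a total-least-squares line per edge, and
    intersect adjacent lines.  Falls back to the input quad if any edge is
    under-supported."""
    from scipy import ndimage as ndi
    boundary = region & ~ndi.binary_erosion(region)
    ys, xs = np.nonzero(boundary)
    pts = np.stack([xs, ys], axis=1).astype(np.float64)
    lines = []
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        ab = b - a
        L = np.linalg.norm(ab)
        u = ab / L
        rel = pts - a
        along = rel @ u
        perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
        sel = (perp < 3.0) & (along > 0.1 * L) & (along < 0.9 * L)
        if sel.sum() < 8:
            return quad
        p = pts[sel]
        c = p.mean(axis=0)
        _, _, vt = np.linalg.svd(p - c, full_matrices=False)
        d = vt[0]  # line direction
        lines.append((c, d))
    out = np.empty((4, 2))
    for i in range(4):
        (c1, d1), (c2, d2) = lines[(i - 1) % 4], lines[i]
        A = np.stack([d1, -d2], axis=1)
        if abs(np.linalg.det(A)) < 1e-9:
            return quad
        s = np.linalg.solve(A, c2 - c1)
        out[i] = c1 + s[0] * d1
    return out


def _orientation_score(gray: np.ndarray, H0: np.ndarray,
                       template: np.ndarray) -> float:
    """Normalized correlation between the unwarped card and the template,
    both blurred and downsampled — used to resolve the 180-degree flip."""
    from scipy.ndimage import gaussian_filter
    h, w = template.shape[:2]
    rect = _warp_to_template_frame(gray, H0, (h, w)).astype(np.float64)
    tpl = template[..., 0].astype(np.float64) if template.ndim == 3 \
        else template.astype(np.float64)
    a = gaussian_filter(rect, 4.0)[::8, ::8].ravel()
    b = gaussian_filter(tpl, 4.0)[::8, ::8].ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else -1.0


def _warp_to_template_frame(gray: np.ndarray, H0: np.ndarray,
                            shape: tuple[int, int]) -> np.ndarray:
    from scipy.ndimage import map_coordinates
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    src = H0 @ np.stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
    src = src[:2] / src[2]
    out = map_coordinates(gray.astype(np.float64),
                          [src[1].reshape(h, w), src[0].reshape(h, w)],
                          order=1, mode="constant", cval=0.0)
    return np.clip(out, 0, 255).astype(np.uint8)


def detect_card(img: np.ndarray, spec: ReferenceCardSpec | None = None,
                seed: int = 0, max_keypoints: int = 1200,
                method: str = "orb", refine_with_features: bool = True
                ) -> CardDetection:
    """Locate the reference card and the template-to-image homography.

    The card's small, foreshortened appearance makes direct binary-
    descriptor matching against the fronto-parallel template unreliable,
    so detection proceeds geometrically first: the card footprint is
    segmented from its high-contrast black/white print, its border lines
    are fit to sub-pixel precision and intersected for corners, and the
    180-degree orientation ambiguity is resolved by correlating the
    unwarped card with the template.  The homography is then the DLT fit
    of template corners to the detected corners; if feature matching in
    the unwarped (template-frame) card finds enough RANSAC support, it
    refines the homography further.

    Raises :class:`CardNotFoundError` if no card-like region exists or the
    detected corners are not a convex quadrilateral.
    """
    from .epipolar import homography_dlt

    spec = spec or ReferenceCardSpec()
    gray = to_gray(img)
    region = _card_region_mask(img)
    if region is None:
        raise CardNotFoundError(
            "no card-like region found — is the card fully in frame and "
            "unoccluded?")
    quad = _quad_from_mask(region)
    if quad is None:
        raise CardNotFoundError("card region has no quadrilateral outline")
    quad = _refine_quad_lines(region, quad)
    if not _is_convex_quad(quad):
        raise CardNotFoundError(
            "detected card corners are not a convex quadrilateral")
    # map the template's long side onto the quad's long edges; resolve the
    # remaining 180-degree flip by template correlation
    e = np.linalg.norm(np.roll(quad, -1, axis=0) - quad, axis=1)
    if e[0] + e[2] < e[1] + e[3]:
        quad = np.roll(quad, -1, axis=0)
    tc = spec.template_corners_px
    candidates = []
    for order in (quad, np.roll(quad, 2, axis=0)):
        try:
            H0 = homography_dlt(tc, order)
        except Exception:
            continue
        candidates.append((_orientation_score(gray, H0, spec.template),
                           H0, order))
    if not candidates:
        raise CardNotFoundError("card homography could not be fit")
    score, H0, corners = max(candidates, key=lambda c: c[0])
    support = int(region.sum())

    if refine_with_features:
        # optional refinement: match features between the template and the
        # perspectively unwarped card; only adopted with clear support
        rect = _warp_to_template_frame(gray, H0, spec.template.shape[:2])
        kp_t, d_t = detect_and_describe(spec.template, max_keypoints, method)
        kp_r, d_r = detect_and_describe(
            np.repeat(rect[..., None], 3, axis=2), max_keypoints, method)
        matches = match_bruteforce(kp_t, d_t, kp_r, d_r)
        if len(matches) >= 12:
            try:
                est = filter_inliers_ransac(
                    matches, spec.template.shape[:2], seed=seed)
                if int(est.inlier_mask.sum()) >= 12:
                    H_ref = H0 @ est.H
                    proj = np.hstack([tc, np.ones((4, 1))]) @ H_ref.T
                    refined = proj[:, :2] / proj[:, [2]]
                    if np.isfinite(refined).all() and _is_convex_quad(refined):
                        H0, corners = H_ref, refined
            except Exception:
                pass

    H0 = H0 / H0[2, 2]
    return CardDetection(np.asarray(corners, dtype=np.float64), H0, support)


def triangulate_card(det1: CardDetection, det2: CardDetection,
                     K1: CameraIntrinsics, K2: CameraIntrinsics,
                     pose: RelativePose) -> np.ndarray:
    """Triangulate the four card corners into reconstruction units."""
    inl = InlierSet(det1.corners_px, det2.corners_px)
    X, _ = triangulate_points(inl, K1, K2, pose)
    return X


def compute_scale(corners_3d: np.ndarray, spec: ReferenceCardSpec | None = None,
                  edge: str = "long") -> float:
    """Scale factor (cm per reconstruction unit) from triangulated corners.

    d_est is the mean of the two reconstructed long-edge lengths (corner
    order TL, TR, BR, BL: edges 0-1 and 3-2); the factor is
    d_ref / d_est with d_ref the card's physical long edge.  ``edge`` may
    be set to ``"diagonal"`` to use the mean diagonal instead.
    """
    spec = spec or ReferenceCardSpec()
    c = np.asarray(corners_3d, dtype=np.float64)
    if edge == "long":
        d_est = 0.5 * (np.linalg.norm(c[1] - c[0]) + np.linalg.norm(c[2] - c[3]))
        d_ref = spec.long_edge_cm
    elif edge == "diagonal":
        d_est = 0.5 * (np.linalg.norm(c[2] - c[0]) + np.linalg.norm(c[3] - c[1]))
        d_ref = float(np.hypot(spec.long_edge_cm, spec.short_edge_cm))
    else:
        raise EstimationFailureError(f"unknown edge choice {edge!r}")
    if not np.isfinite(d_est) or d_est <= 0:
        raise EstimationFailureError(
            f"degenerate reconstructed card size d_est={d_est}")
    return d_ref / d_est


def apply_scale(points: np.ndarray, pose: RelativePose,
                scale: float) -> tuple[np.ndarray, RelativePose]:
    """Convert a reconstruction to centimeters.

    Multiplies every coordinate by ``scale`` and records it on the pose.
    May be applied once per pose; a second call raises :class:`UsageError`.
    """
    if scale <= 0 or not np.isfinite(scale):
        raise EstimationFailureError(f"scale must be positive, got {scale}")
    if pose.scale is not None:
        raise UsageError("metric scale already applied to this pose")
    scaled = np.asarray(points, dtype=np.float64) * scale
    new_pose = RelativePose(pose.R.copy(), pose.t.copy(), float(scale))
    return scaled, new_pose
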
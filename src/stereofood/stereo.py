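"""Dense two-view stereo: rectification, semi-global matching, WLS
filtering, and reprojection to a metric point cloud.

The rectified pair shares a common image plane parallel to the baseline,
so correspondences lie on equal rows and the search is one-dimensional.
Matching cost is the Hamming distance between census transforms,
aggregated semi-globally along scanline paths with the usual P1/P2
smoothness penalties; a winner-take-all disparity with parabolic sub-pixel
refinement follows, validated by a left-right consistency check.  The
weighted-least-squares filter is a fast global smoother guided by the
rectified source image: it aligns disparity edges with image edges and
propagates values from high- to low-confidence regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
from scipy.ndimage import map_coordinates

from .epipolar import CameraIntrinsics, RelativePose
from .errors import ParameterError, RectificationError, UsageError
from .imaging import to_gray

# --------------------------------------------------------------------------
# rectification


@dataclass
class RectifiedPair:
    """Row-aligned image pair plus the geometry to undo the mapping."""

    img1_rect: np.ndarray  # uint8 gray
    img2_rect: np.ndarray
    R1: np.ndarray  # camera-1 -> rectified-1 rotation
    R2: np.ndarray
    K_new: np.ndarray  # shared rectified intrinsics
    baseline: float  # reconstruction units (1 for a unit-norm pose)
    valid_mask1: np.ndarray
    valid_mask2: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.img1_rect.shape[:2]


def _warp_rotation(img: np.ndarray, H: np.ndarray,
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Warp ``img`` by the inverse of homography ``H`` onto ``shape``."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    pts = np.stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
    src = np.linalg.inv(H) @ pts
    sx = (src[0] / src[2]).reshape(h, w)
    sy = (src[1] / src[2]).reshape(h, w)
    out = map_coordinates(img.astype(np.float64), [sy, sx], order=1,
                          mode="constant", cval=0.0)
    valid = (sx >= 0) & (sx <= img.shape[1] - 1) & \
        (sy >= 0) & (sy <= img.shape[0] - 1)
    return np.clip(out, 0, 255).astype(np.uint8), valid


def rectify_pair(img1: np.ndarray, img2: np.ndarray, K: CameraIntrinsics,
                 pose: RelativePose) -> RectifiedPair:
    """Rotate both views onto a common plane parallel to the baseline.

    Uses the calibrated (Fusiello-style) construction: the new x-axis is
    the baseline direction, the new y/z axes are built from the mean
    optical axis.  Scale-free — the pose's translation may be unit-norm.
    Raises :class:`RectificationError` when the baseline is numerically
    degenerate or parallel to the optical axis.
    """
    t = np.asarray(pose.t, dtype=np.float64)
    if not np.isfinite(t).all() or np.linalg.norm(t) < 1e-9:
        raise RectificationError("degenerate (near-zero) baseline")
    C2 = -pose.R.T @ t  # camera-2 center in camera-1 coordinates
    b = np.linalg.norm(C2)
    e1 = C2 / b
    z_mean = np.array([0.0, 0.0, 1.0]) + pose.R.T @ np.array([0.0, 0.0, 1.0])
    e2 = np.cross(z_mean, e1)
    n = np.linalg.norm(e2)
    if n < 1e-9:
        raise RectificationError("baseline parallel to the optical axis")
    e2 = e2 / n
    e3 = np.cross(e1, e2)
    R1 = np.stack([e1, e2, e3])
    R2 = R1 @ pose.R.T
    f = 0.5 * (K.fx + K.fy)
    h, w = to_gray(img1).shape
    K_new = np.array([[f, 0.0, K.cx], [0.0, f, K.cy], [0.0, 0.0, 1.0]])
    H1 = K_new @ R1 @ np.linalg.inv(K.K)
    H2 = K_new @ R2 @ np.linalg.inv(K.K)
    g1, g2 = to_gray(img1), to_gray(img2)
    r1, m1 = _warp_rotation(g1, H1, (h, w))
    r2, m2 = _warp_rotation(g2, H2, (h, w))
    return RectifiedPair(r1, r2, R1, R2, K_new, b, m1, m2)


# --------------------------------------------------------------------------
# disparity (census + semi-global aggregation)


@dataclass
class DisparityMap:
    """Sub-pixel disparity per rectified-left pixel; ``invalid_mask`` marks
    occlusions and matching failures."""

    values: np.ndarray  # float32, disparity in pixels (left x - right x)
    invalid_mask: np.ndarray  # bool
    min_disparity: int = 0


@numba.njit(cache=True)
def _census(img, radius):
    """Census transform with a (2r+1)^2 window (<= 7x7 fits in 64 bits)."""
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint64)
    for y in range(radius, h - radius):
        for x in range(radius, w - radius):
            c = img[y, x]
            code = np.uint64(0)
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if dy == 0 and dx == 0:
                        continue
                    code = code << np.uint64(1)
                    if img[y + dy, x + dx] < c:
                        code |= np.uint64(1)
            out[y, x] = code
    return out


@numba.njit(cache=True)
def _popcount64(v):
    v = v - ((v >> np.uint64(1)) & np.uint64(0x5555555555555555))
    v = (v & np.uint64(0x3333333333333333)) + \
        ((v >> np.uint64(2)) & np.uint64(0x3333333333333333))
    v = (v + (v >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (v * np.uint64(0x0101010101010101)) >> np.uint64(56)


@numba.njit(cache=True)
def _cost_volume(cen1, cen2, min_disp, num_disp, max_cost):
    h, w = cen1.shape
    cost = np.full((h, w, num_disp), np.uint8(max_cost), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            c1 = cen1[y, x]
            for di in range(num_disp):
                xr = x - (min_disp + di)
                if 0 <= xr < w:
                    cost[y, x, di] = np.uint8(_popcount64(c1 ^ cen2[y, xr]))
    return cost


@numba.njit(cache=True)
def _aggregate_horizontal(cost, agg, P1, P2, dx):
    """Add the left-to-right (dx=1) or right-to-left (dx=-1) path."""
    h, w, D = cost.shape
    INF = np.float32(1e9)
    Lprev = np.empty(D, dtype=np.float32)
    Lcur = np.empty(D, dtype=np.float32)
    for y in range(h):
        xs = range(w) if dx > 0 else range(w - 1, -1, -1)
        first = True
        for x in xs:
            if first:
                for d in range(D):
                    Lcur[d] = cost[y, x, d]
                first = False
            else:
                minprev = INF
                for d in range(D):
                    if Lprev[d] < minprev:
                        minprev = Lprev[d]
                for d in range(D):
                    best = Lprev[d]
                    if d > 0 and Lprev[d - 1] + P1 < best:
                        best = Lprev[d - 1] + P1
                    if d < D - 1 and Lprev[d + 1] + P1 < best:
                        best = Lprev[d + 1] + P1
                    if minprev + P2 < best:
                        best = minprev + P2
                    Lcur[d] = cost[y, x, d] + best - minprev
            for d in range(D):
                agg[y, x, d] += Lcur[d]
                Lprev[d] = Lcur[d]
    return agg


@numba.njit(cache=True)
def _aggregate_diag(cost, agg, P1, P2, dy, dx):
    """Add one diagonal path (dy = +/-1, dx = +/-1)."""
    h, w, D = cost.shape
    INF = np.float32(1e9)
    Lprev = np.empty((w, D), dtype=np.float32)
    Lcur = np.empty((w, D), dtype=np.float32)
    ys = range(h) if dy > 0 else range(h - 1, -1, -1)
    first = True
    for y in ys:
        for x in range(w):
            px = x - dx
            if first or px < 0 or px >= w:
                for d in range(D):
                    Lcur[x, d] = cost[y, x, d]
            else:
                minprev = INF
                for d in range(D):
                    if Lprev[px, d] < minprev:
                        minprev = Lprev[px, d]
                for d in range(D):
                    best = Lprev[px, d]
                    if d > 0 and Lprev[px, d - 1] + P1 < best:
                        best = Lprev[px, d - 1] + P1
                    if d < D - 1 and Lprev[px, d + 1] + P1 < best:
                        best = Lprev[px, d + 1] + P1
                    if minprev + P2 < best:
                        best = minprev + P2
                    Lcur[x, d] = cost[y, x, d] + best - minprev
            for d in range(D):
                agg[y, x, d] += Lcur[x, d]
        for x in range(w):
            for d in range(D):
                Lprev[x, d] = Lcur[x, d]
        first = False
    return agg


@numba.njit(cache=True)
def _aggregate_vertical(cost, agg, P1, P2, dy):
    """Vertical path aggregation (whole-row vectorized recursion)."""
    h, w, D = cost.shape
    INF = np.float32(1e9)
    Lprev = np.empty((w, D), dtype=np.float32)
    ys = range(h) if dy > 0 else range(h - 1, -1, -1)
    first = True
    for y in ys:
        for x in range(w):
            if first:
                for d in range(D):
                    v = np.float32(cost[y, x, d])
                    Lprev[x, d] = v
                    agg[y, x, d] += v
            else:
                minprev = INF
                for d in range(D):
                    if Lprev[x, d] < minprev:
                        minprev = Lprev[x, d]
                for d in range(D):
                    best = Lprev[x, d]
                    if d > 0 and Lprev[x, d - 1] + P1 < best:
                        best = Lprev[x, d - 1] + P1
                    if d < D - 1 and Lprev[x, d + 1] + P1 < best:
                        best = Lprev[x, d + 1] + P1
                    if minprev + P2 < best:
                        best = minprev + P2
                    v = cost[y, x, d] + best - minprev
                    Lprev[x, d] = v
                    agg[y, x, d] += v
        first = False
    return agg


@numba.njit(cache=True)
def _wta_subpixel(agg, cost, min_disp):
    h, w, D = agg.shape
    disp = np.empty((h, w), dtype=np.float32)
    match_cost = np.empty((h, w), dtype=np.float32)
    for y in range(h):
        for x in range(w):
            best_d = 0
            best_v = agg[y, x, 0]
            for d in range(1, D):
                if agg[y, x, d] < best_v:
                    best_v = agg[y, x, d]
                    best_d = d
            off = 0.0
            if 0 < best_d < D - 1:
                cm = agg[y, x, best_d - 1]
                cp = agg[y, x, best_d + 1]
                den = cm - 2.0 * best_v + cp
                if den > 1e-9:
                    off = 0.5 * (cm - cp) / den
                    if off > 0.5:
                        off = 0.5
                    elif off < -0.5:
                        off = -0.5
            disp[y, x] = min_disp + best_d + off
            match_cost[y, x] = cost[y, x, best_d]
    return disp, match_cost


@numba.njit(cache=True)
def _cost_right_reference(cost, min_disp, max_cost):
    """Re-index the shared matching costs with the right image as
    reference: costR(y, xr, d) = costL(y, xr + d, d)."""
    h, w, D = cost.shape
    out = np.full((h, w, D), np.uint8(max_cost), dtype=np.uint8)
    for y in range(h):
        for xr in range(w):
            for d in range(D):
                xl = xr + min_disp + d
                if 0 <= xl < w:
                    out[y, xr, d] = cost[y, xl, d]
    return out


@numba.njit(cache=True)
def _wta_plain(agg, min_disp):
    h, w, D = agg.shape
    disp = np.empty((h, w), dtype=np.float32)
    for y in range(h):
        for x in range(w):
            best_d = 0
            best_v = agg[y, x, 0]
            for d in range(1, D):
                if agg[y, x, d] < best_v:
                    best_v = agg[y, x, d]
                    best_d = d
            disp[y, x] = min_disp + best_d
    return disp


@numba.njit(cache=True)
def _right_from_left_agg(agg, min_disp):
    """Right-reference WTA read directly off the left-aggregated volume
    (cheap, but shares the aggregation with the left map)."""
    h, w, D = agg.shape
    disp = np.full((h, w), -1.0, dtype=np.float32)
    for y in range(h):
        for xr in range(w):
            best_d = -1
            best_v = np.float32(1e18)
            for d in range(D):
                xl = xr + min_disp + d
                if xl < w:
                    v = agg[y, xl, d]
                    if v < best_v:
                        best_v = v
                        best_d = d
            if best_d >= 0:
                disp[y, xr] = min_disp + best_d
    return disp


def compute_disparity(rect: RectifiedPair, num_disparities: int = 128,
                      block_size: int = 5, min_disparity: int = 0,
                      p1: float | None = None, p2: float | None = None,
                      paths: int = 4, lr_threshold: float = 1.5,
                      max_cost_fraction: float = 1.0,
                      lr_independent: bool = True) -> DisparityMap:
    """Semi-global census disparity with sub-pixel refinement.

    ``num_disparities`` must be a positive multiple of 16 and
    ``block_size`` an odd number >= 3 (it scales the default smoothness
    penalties, in the customary P1 = 8*3*block^2, P2 = 32*3*block^2 way).
    Occlusions and ambiguous regions fail the left-right consistency
    check and are flagged in the invalid mask.
    """
    if num_disparities <= 0 or num_disparities % 16:
        raise ParameterError(
            f"num_disparities must be a positive multiple of 16, got "
            f"{num_disparities}")
    if block_size < 3 or block_size % 2 == 0:
        raise ParameterError(
            f"block_size must be odd and >= 3, got {block_size}")
    if paths not in (2, 4, 8):
        raise ParameterError(f"paths must be 2, 4 or 8, got {paths}")
    radius = min(block_size // 2, 3)  # 64-bit census caps the window at 7x7
    bits = (2 * radius + 1) ** 2 - 1
    if p1 is None:
        p1 = bits / 3.0  # smoothness penalties on the census-cost scale
    if p2 is None:
        p2 = 1.5 * bits
    g1 = rect.img1_rect.astype(np.uint8)
    g2 = rect.img2_rect.astype(np.uint8)
    cen1 = _census(g1, radius)
    cen2 = _census(g2, radius)
    cost = _cost_volume(cen1, cen2, min_disparity, num_disparities, bits)
    agg = np.zeros(cost.shape, dtype=np.float32)
    P1, P2 = np.float32(p1), np.float32(p2)
    _aggregate_horizontal(cost, agg, P1, P2, 1)
    _aggregate_horizontal(cost, agg, P1, P2, -1)
    if paths >= 4:
        _aggregate_vertical(cost, agg, P1, P2, 1)
        _aggregate_vertical(cost, agg, P1, P2, -1)
    if paths == 8:
        _aggregate_diag(cost, agg, P1, P2, 1, 1)
        _aggregate_diag(cost, agg, P1, P2, 1, -1)
        _aggregate_diag(cost, agg, P1, P2, -1, 1)
        _aggregate_diag(cost, agg, P1, P2, -1, -1)
    disp, match_cost = _wta_subpixel(agg, cost, min_disparity)
    if lr_independent:
        # independent right-reference aggregation: raw costs are shared,
        # but scanline aggregation is reference-dependent, so object-edge
        # fattening lands on opposite sides in the two maps and the
        # left-right check can actually catch it
        cost_r = _cost_right_reference(cost, min_disparity, bits)
        agg_r = np.zeros(cost_r.shape, dtype=np.float32)
        _aggregate_horizontal(cost_r, agg_r, P1, P2, 1)
        _aggregate_horizontal(cost_r, agg_r, P1, P2, -1)
        if paths >= 4:
            _aggregate_vertical(cost_r, agg_r, P1, P2, 1)
            _aggregate_vertical(cost_r, agg_r, P1, P2, -1)
        if paths == 8:
            _aggregate_diag(cost_r, agg_r, P1, P2, 1, 1)
            _aggregate_diag(cost_r, agg_r, P1, P2, 1, -1)
            _aggregate_diag(cost_r, agg_r, P1, P2, -1, 1)
            _aggregate_diag(cost_r, agg_r, P1, P2, -1, -1)
        dr = _wta_plain(agg_r, min_disparity)
    else:
        dr = _right_from_left_agg(agg, min_disparity)
    h, w = disp.shape
    xs = np.arange(w)[None, :].repeat(h, axis=0)
    xr = np.rint(xs - disp).astype(np.int64)
    in_range = (xr >= 0) & (xr < w)
    lr = np.full((h, w), np.inf, dtype=np.float32)
    yy = np.arange(h)[:, None].repeat(w, axis=1)
    lr[in_range] = np.abs(disp[in_range] - dr[yy[in_range], xr[in_range]])
    # optionally reject pixels whose winning raw cost is near the random-
    # match level (their own content does not support the disparity);
    # disabled by default — it also trims steeply slanted true surfaces
    invalid = ~in_range | (lr > lr_threshold) | ~rect.valid_mask1 | \
        (match_cost > max_cost_fraction * bits)
    border = 3  # census support margin
    invalid[:border] = invalid[-border:] = True
    invalid[:, :border] = invalid[:, -border:] = True
    disp = disp.copy()
    disp[invalid] = np.nan
    return DisparityMap(disp, invalid, min_disparity)


@numba.njit(cache=True)
def _photometric_refine(dispv, invalid, L, R, radius, iters, max_step):
    """Per-pixel 1-D photometric (Lucas-Kanade) disparity refinement.

    Starting from the SGM estimate, each valid pixel's disparity is
    adjusted by Gauss-Newton on the SSD between the left patch and the
    bilinearly sampled right patch — removing the staircase/pixel-locking
    bias of discrete matching on slanted and gently curved surfaces.
    """
    h, w = dispv.shape
    out = dispv.copy()
    for y in range(radius, h - radius):
        for x in range(radius, w - radius):
            if invalid[y, x]:
                continue
            d = dispv[y, x]
            if not np.isfinite(d):
                continue
            total_step = 0.0
            for _ in range(iters):
                num = 0.0
                den = 0.0
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        xs = x + dx - d
                        x0 = int(np.floor(xs))
                        if x0 < 1 or x0 >= w - 2:
                            continue
                        f = xs - x0
                        yv = y + dy
                        r0 = R[yv, x0]
                        r1 = R[yv, x0 + 1]
                        rv = r0 * (1.0 - f) + r1 * f
                        # horizontal gradient of the sampled right image
                        gm = R[yv, x0 - 1] * (1.0 - f) + r0 * f
                        gp = r1 * (1.0 - f) + R[yv, x0 + 2] * f
                        grad = 0.5 * (gp - gm)
                        e = L[yv, x + dx] - rv
                        # d increases -> sample moves left -> rv changes by -grad
                        num += e * (-grad)
                        den += grad * grad
                if den < 1e-6:
                    break
                # Gauss-Newton: e = L - R(x-d), de/dd = +grad, so
                # delta = -sum(e*grad)/sum(grad^2) = num/den
                step = num / den
                if step > 0.5:
                    step = 0.5
                elif step < -0.5:
                    step = -0.5
                d += step
                total_step += step
                if abs(total_step) > max_step:
                    d = dispv[y, x]
                    break
                if abs(step) < 0.01:
                    break
            out[y, x] = d
    return out


def refine_disparity_photometric(disp: DisparityMap, rect: RectifiedPair,
                                 radius: int = 3, iters: int = 4,
                                 max_step: float = 1.5) -> DisparityMap:
    """Photometric sub-pixel refinement of an SGM disparity map."""
    L = rect.img1_rect.astype(np.float64)
    R = rect.img2_rect.astype(np.float64)
    vals = _photometric_refine(disp.values.astype(np.float64),
                               disp.invalid_mask, L, R, radius, iters,
                               max_step)
    return DisparityMap(vals.astype(np.float32), disp.invalid_mask.copy(),
                        disp.min_disparity)


# --------------------------------------------------------------------------
# WLS (fast global smoother) filtering


@numba.njit(cache=True)
def _fgs_horizontal(data, conf, guide, dguide, lam, sigma, sigma_d):
    h, w = data.shape
    out = np.empty_like(data)
    a = np.empty(w, dtype=np.float64)
    b = np.empty(w, dtype=np.float64)
    c = np.empty(w, dtype=np.float64)
    r = np.empty(w, dtype=np.float64)
    for y in range(h):
        for x in range(w):
            if x > 0:
                wl = np.exp(-abs(guide[y, x] - guide[y, x - 1]) / sigma
                            - abs(dguide[y, x] - dguide[y, x - 1]) / sigma_d)
            else:
                wl = 0.0
            if x < w - 1:
                wr = np.exp(-abs(guide[y, x] - guide[y, x + 1]) / sigma
                            - abs(dguide[y, x] - dguide[y, x + 1]) / sigma_d)
            else:
                wr = 0.0
            a[x] = -lam * wl
            c[x] = -lam * wr
            b[x] = conf[y, x] + lam * (wl + wr)
            r[x] = conf[y, x] * data[y, x]
        # Thomas algorithm
        for x in range(1, w):
            m = a[x] / b[x - 1]
            b[x] -= m * c[x - 1]
            r[x] -= m * r[x - 1]
        out[y, w - 1] = r[w - 1] / b[w - 1]
        for x in range(w - 2, -1, -1):
            out[y, x] = (r[x] - c[x] * out[y, x + 1]) / b[x]
    return out


@numba.njit(cache=True)
def _fgs_vertical(data, conf, guide, dguide, lam, sigma, sigma_d):
    h, w = data.shape
    out = np.empty_like(data)
    a = np.empty(h, dtype=np.float64)
    b = np.empty(h, dtype=np.float64)
    c = np.empty(h, dtype=np.float64)
    r = np.empty(h, dtype=np.float64)
    for x in range(w):
        for y in range(h):
            if y > 0:
                wu = np.exp(-abs(guide[y, x] - guide[y - 1, x]) / sigma
                            - abs(dguide[y, x] - dguide[y - 1, x]) / sigma_d)
            else:
                wu = 0.0
            if y < h - 1:
                wd = np.exp(-abs(guide[y, x] - guide[y + 1, x]) / sigma
                            - abs(dguide[y, x] - dguide[y + 1, x]) / sigma_d)
            else:
                wd = 0.0
            a[y] = -lam * wu
            c[y] = -lam * wd
            b[y] = conf[y, x] + lam * (wu + wd)
            r[y] = conf[y, x] * data[y, x]
        for y in range(1, h):
            m = a[y] / b[y - 1]
            b[y] -= m * c[y - 1]
            r[y] -= m * r[y - 1]
        out[h - 1, x] = r[h - 1] / b[h - 1]
        for y in range(h - 2, -1, -1):
            out[y, x] = (r[y] - c[y] * out[y + 1, x]) / b[y]
    return out


def prefill_background(values: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Horizontal background fill: each invalid pixel takes the smaller of
    the nearest valid disparities to its left and right (occluded regions
    belong to the background), with a vertical nearest fallback."""
    h, w = values.shape
    out = values.copy()
    x = np.arange(w)
    # left scan
    idx = np.where(~invalid, x[None, :], -1)
    left = np.maximum.accumulate(idx, axis=1)
    # right scan
    idxr = np.where(~invalid, x[None, :], w)
    right = np.minimum.accumulate(idxr[:, ::-1], axis=1)[:, ::-1]
    rows = np.arange(h)[:, None].repeat(w, axis=1)
    lv = np.where(left >= 0, values[rows, np.clip(left, 0, w - 1)], np.nan)
    rv = np.where(right < w, values[rows, np.clip(right, 0, w - 1)], np.nan)
    fill = np.fmin(lv, rv)  # background (smaller disparity) wins
    out[invalid] = fill[invalid]
    # any rows with no valid pixel at all: column-wise nearest by ffill
    still = ~np.isfinite(out)
    if still.any():
        col_med = np.nanmedian(out, axis=0)
        out[still] = np.take(col_med, np.nonzero(still)[1])
        out[~np.isfinite(out)] = np.nanmedian(values)
    return out


def filter_disparity_wls(disp: DisparityMap, guide: np.ndarray,
                         lam: float = 8000.0, sigma: float = 1.5,
                         iterations: int = 3,
                         roi_mask: np.ndarray | None = None,
                         sigma_disparity: float = 1.0) -> DisparityMap:
    """Edge-aware weighted-least-squares smoothing of the disparity map.

    Implemented as a fast global smoother: ``iterations`` alternating
    1-D horizontal/vertical WLS solves guided jointly by the rectified
    source image and by the (pre-filled) disparity map itself, with the
    per-iteration regularization schedule that makes the separable passes
    approximate the 2-D solution.  ``sigma`` follows the familiar
    disparity-WLS convention (unitless edge sensitivity, ~1.5);
    internally it scales intensity differences by ``16*sigma`` gray
    levels.  ``sigma_disparity`` (px) stops propagation across genuine
    depth discontinuities — sub-pixel matching noise is far below it, a
    food/table step far above — so the surface is smoothed without
    bleeding object edges.  Invalid pixels are pre-filled from the
    background side and re-estimated with low confidence, so holes inside
    the valid region receive propagated values.
    """
    g = to_gray(guide).astype(np.float64)
    if g.shape != disp.values.shape:
        raise ParameterError(
            f"guide shape {g.shape} != disparity shape {disp.values.shape}")
    if lam <= 0 or sigma <= 0 or sigma_disparity <= 0:
        raise ParameterError("lam, sigma and sigma_disparity must be positive")
    sigma_gray = 16.0 * sigma
    data = prefill_background(disp.values, disp.invalid_mask)
    conf = np.where(disp.invalid_mask, 0.05, 1.0)
    # the discontinuity guide: lightly smoothed pre-filled disparity, so
    # isolated spikes do not wall off their neighborhoods
    from scipy.ndimage import median_filter
    dguide = median_filter(data, size=3)
    u = data.copy()
    T = iterations
    for it in range(1, T + 1):
        lam_t = 1.5 * lam * 4.0 ** (T - it) / (4.0 ** T - 1.0)
        u = _fgs_horizontal(u, conf, g, dguide, lam_t, sigma_gray,
                            sigma_disparity)
        u = _fgs_vertical(u, conf, g, dguide, lam_t, sigma_gray,
                          sigma_disparity)
    # holes inside the usable region are now filled; pixels outside it
    # (rectification border, image margin) stay invalid
    if roi_mask is not None:
        still_invalid = ~np.asarray(roi_mask, dtype=bool)
    else:
        still_invalid = np.zeros_like(disp.invalid_mask)
    border = 3
    still_invalid[:border] = still_invalid[-border:] = True
    still_invalid[:, :border] = still_invalid[:, -border:] = True
    return DisparityMap(u.astype(np.float32), still_invalid,
                        disp.min_disparity)


# --------------------------------------------------------------------------
# reprojection


def reproject_to_cloud(disp: DisparityMap, rect: RectifiedPair, scale: float,
                       guide: np.ndarray | None = None,
                       depth_range_cm: tuple[float, float] = (20.0, 100.0),
                       stride: int = 1):
    """Back-project the disparity map to a metric point cloud (cm).

    Depth in reconstruction units is ``f * baseline / d``; every
    coordinate is multiplied by the metric ``scale`` (cm per unit) fixed
    by the reference card.  Points outside ``depth_range_cm`` — the
    capture protocol keeps the dish a few tens of cm away — are dropped
    as disparity failures.  Returns a :class:`PointCloud` in the
    rectified camera-1 frame.
    """
    from .volume import PointCloud

    if scale is None or not np.isfinite(scale) or scale <= 0:
        raise UsageError("metric scale must be set before reprojection")
    v = disp.values[::stride, ::stride]
    inv = disp.invalid_mask[::stride, ::stride]
    h, w = disp.values.shape
    yy, xx = np.mgrid[0:h:stride, 0:w:stride].astype(np.float64)
    f = rect.K_new[0, 0]
    cx, cy = rect.K_new[0, 2], rect.K_new[1, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = f * rect.baseline / v.astype(np.float64)
    ok = np.isfinite(Z) & (Z > 0) & ~inv
    Zc = Z * scale
    ok &= (Zc >= depth_range_cm[0]) & (Zc <= depth_range_cm[1])
    X = (xx - cx) / f * Zc
    Y = (yy - cy) / f * Zc
    pts = np.stack([X[ok], Y[ok], Zc[ok]], axis=1)
    colors = None
    if guide is not None:
        gg = np.asarray(guide)
        if gg.ndim == 2:
            gg = np.repeat(gg[..., None], 3, axis=2)
        colors = gg[::stride, ::stride][ok]
    return PointCloud(pts, colors)
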
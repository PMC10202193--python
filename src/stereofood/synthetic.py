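"""Synthetic ground-truthed stereo food scenes.

Every stage of the pipeline is validated against scenes rendered by this
module: a textured table plane at z = 0 carrying a reference card
(8.5 x 5.5 cm), a shallow dish rim, and a food item of analytically known
volume (hemisphere, spherical cap, or box), imaged by two pinhole cameras
that emulate the capture protocol — roughly 40-50 cm from the dish at
about 45 degrees from the vertical, the second camera shifted a few cm to
the right.  Rendering is ray casting against the analytic primitives with
procedural value-noise textures and Lambertian shading, so the geometry in
the images is exact and deterministic for a fixed (spec, seed).

The generated truth includes the metric relative pose, the card corners in
every frame, and a world-to-pixel correspondence oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .epipolar import CameraIntrinsics
from .errors import ParameterError, SceneGenerationError

# --------------------------------------------------------------------------
# food shapes


@dataclass(frozen=True)
class Hemisphere:
    radius: float  # cm


@dataclass(frozen=True)
class SphericalCap:
    radius: float  # sphere radius, cm
    height: float  # cap height above the table, cm


@dataclass(frozen=True)
class Box:
    a: float  # cm, x extent
    b: float  # cm, y extent
    c: float  # cm, height


FoodShape = Hemisphere | SphericalCap | Box


def analytic_volume(shape: FoodShape) -> float:
    """Closed-form volume in cm^3 of a supported food shape."""
    if isinstance(shape, Hemisphere):
        if shape.radius <= 0:
            raise ParameterError("hemisphere radius must be positive")
        return 2.0 / 3.0 * np.pi * shape.radius ** 3
    if isinstance(shape, SphericalCap):
        r, h = shape.radius, shape.height
        if r <= 0 or h <= 0 or h > 2 * r:
            raise ParameterError(f"invalid spherical cap r={r}, h={h}")
        return np.pi * h * h * (3 * r - h) / 3.0
    if isinstance(shape, Box):
        if min(shape.a, shape.b, shape.c) <= 0:
            raise ParameterError("box dimensions must be positive")
        return shape.a * shape.b * shape.c
    raise ParameterError(f"unsupported shape {shape!r}")


# --------------------------------------------------------------------------
# scene specification

#: Physical card dimensions of the capture protocol, cm.
CARD_LONG_CM = 8.5
CARD_SHORT_CM = 5.5

#: Height of the shallow dish rim above the table, cm.  The protocol calls
#: for shallow dishes; the rim stays below the food-extraction floor.
DISH_RIM_CM = 0.2

_DEFAULT_K = CameraIntrinsics(700.0, 700.0, 399.5, 299.5,
                              image_shape=(600, 800))


@dataclass
class SceneSpec:
    """Full description of one synthetic capture."""

    food_shape: FoodShape = field(default_factory=lambda: Hemisphere(3.0))
    food_center: tuple[float, float] = (0.0, 0.0)  # on the table, cm
    card_center: tuple[float, float] = (0.0, -13.5)
    card_angle_deg: float = 0.0  # in-plane rotation of the card
    dish_radius: float = 8.0  # cm
    texture_seed: int = 0
    camera_distance: float = 45.0  # cm from the look-at point
    elevation_deg: float = 45.0  # angle from the vertical axis
    azimuth_deg: float = 90.0  # direction the camera sits in, on the table
    baseline_cm: float = 4.0  # rightward shift of the second camera
    tilt_jitter_deg: float = 0.3  # hand-held orientation change, view 2
    intrinsics: CameraIntrinsics = field(default_factory=lambda: _DEFAULT_K)

    def __post_init__(self):
        analytic_volume(self.food_shape)  # validates dimensions
        if not 20.0 <= self.camera_distance <= 100.0:
            raise ParameterError("camera_distance must be within [20, 100] cm")
        if self.baseline_cm <= 0:
            raise ParameterError("baseline must be positive")


@dataclass
class SceneTruth:
    """Rendered pair plus everything needed to check any pipeline stage."""

    spec: SceneSpec
    images: tuple[np.ndarray, np.ndarray]  # uint8 RGB, (600, 800, 3)
    K: CameraIntrinsics
    R_true: np.ndarray  # camera-2 w.r.t. camera-1
    t_true: np.ndarray  # metric, cm (norm = true baseline length)
    v_true: float  # cm^3
    card_corners_world: np.ndarray  # (4, 3) cm, convex order
    card_corners_px: tuple[np.ndarray, np.ndarray]  # projections per view
    cam_rotations: tuple[np.ndarray, np.ndarray]  # world->camera
    cam_centers: tuple[np.ndarray, np.ndarray]  # world, cm

    def project(self, world_points: np.ndarray, view: int) -> np.ndarray:
        """Correspondence oracle: world points (n, 3) -> pixels in a view."""
        R, C = self.cam_rotations[view], self.cam_centers[view]
        x = (np.atleast_2d(world_points) - C) @ R.T @ self.K.K.T
        return x[:, :2] / x[:, [2]]

    def depth(self, world_points: np.ndarray, view: int) -> np.ndarray:
        R, C = self.cam_rotations[view], self.cam_centers[view]
        return ((np.atleast_2d(world_points) - C) @ R.T)[:, 2]


# --------------------------------------------------------------------------
# procedural textures


def _hash01(ix: np.ndarray, iy: np.ndarray, seed: float) -> np.ndarray:
    """Deterministic pseudo-random lattice values in [0, 1)."""
    v = np.sin(ix * 127.1 + iy * 311.7 + seed * 74.7) * 43758.5453123
    return v - np.floor(v)


def value_noise(x: np.ndarray, y: np.ndarray, scale: float,
                seed: float) -> np.ndarray:
    """Bilinear value noise at wavelength ``scale`` (cm), in [0, 1)."""
    u, v = x / scale, y / scale
    iu, iv = np.floor(u), np.floor(v)
    fu, fv = u - iu, v - iv
    fu = fu * fu * (3 - 2 * fu)  # smoothstep
    fv = fv * fv * (3 - 2 * fv)
    a = _hash01(iu, iv, seed)
    b = _hash01(iu + 1, iv, seed)
    c = _hash01(iu, iv + 1, seed)
    d = _hash01(iu + 1, iv + 1, seed)
    return (a * (1 - fu) + b * fu) * (1 - fv) + (c * (1 - fu) + d * fu) * fv


def fractal_noise(x: np.ndarray, y: np.ndarray, base_scale: float,
                  seed: float, octaves: int = 3) -> np.ndarray:
    """Multi-octave value noise, normalized to [0, 1]."""
    out = np.zeros_like(x, dtype=np.float64)
    amp, norm = 1.0, 0.0
    for o in range(octaves):
        out += amp * value_noise(x, y, base_scale / (2 ** o), seed + 13.7 * o)
        norm += amp
        amp *= 0.55
    return out / norm


def make_card_template(width_px: int = 340, height_px: int = 220,
                       seed: int = 0) -> np.ndarray:
    """Printable high-contrast fiducial pattern for the reference card.

    Asymmetric, corner-rich: thresholded value noise blocks inside a thick
    black border with a solid corner marker breaking every symmetry.  The
    aspect ratio matches the physical card (8.5 x 5.5 cm).  Returned as an
    RGB uint8 image; deterministic for a fixed seed.
    """
    yy, xx = np.mgrid[0:height_px, 0:width_px].astype(np.float64)
    u = xx / width_px * 8.5  # cm across the card
    v = yy / height_px * 5.5
    blocks = value_noise(u, v, 0.9, seed + 0.5) > 0.5
    fine = value_noise(u, v, 0.45, seed + 7.25) > 0.62
    img = np.where(blocks ^ fine, 235, 20).astype(np.float64)
    border = (u < 0.4) | (u > 8.1) | (v < 0.4) | (v > 5.1)
    img[border] = 20
    img[(u > 0.55) & (u < 1.45) & (v > 0.55) & (v < 1.45)] = 235  # TL window
    img[(u > 0.75) & (u < 1.25) & (v > 0.75) & (v < 1.25)] = 20   # TL dot
    return np.repeat(np.clip(img, 0, 255).astype(np.uint8)[..., None], 3, axis=2)


# --------------------------------------------------------------------------
# cameras


def _look_at(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation for a camera at ``center`` looking at
    ``target``, x right / y down / z forward."""
    z = target - center
    z = z / np.linalg.norm(z)
    x = np.cross(z, np.array([0.0, 0.0, 1.0]))
    n = np.linalg.norm(x)
    if n < 1e-9:
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / n
    y = np.cross(z, x)
    return np.stack([x, y, z])  # rows


def _small_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_deg, max_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K


# --------------------------------------------------------------------------
# rendering


def _card_corners_world(spec: SceneSpec) -> np.ndarray:
    """World positions of the template's TL, TR, BR, BL corners.

    The template's u axis maps to the card-frame +x direction and its v
    (downward) axis to card-frame -y, so that a camera looking down at the
    table sees the pattern unmirrored."""
    th = np.radians(spec.card_angle_deg)
    Rc = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    half = np.array([[-CARD_LONG_CM / 2, CARD_SHORT_CM / 2],
                     [CARD_LONG_CM / 2, CARD_SHORT_CM / 2],
                     [CARD_LONG_CM / 2, -CARD_SHORT_CM / 2],
                     [-CARD_LONG_CM / 2, -CARD_SHORT_CM / 2]])
    xy = half @ Rc.T + np.asarray(spec.card_center)
    return np.hstack([xy, np.zeros((4, 1))])


def _render_view(spec: SceneSpec, Rw2c: np.ndarray, C: np.ndarray,
                 template: np.ndarray) -> np.ndarray:
    K = spec.intrinsics
    h, w = K.image_shape
    vv, uu = np.mgrid[0:h, 0:w].astype(np.float64)
    d_cam = np.stack([(uu - K.cx) / K.fx, (vv - K.cy) / K.fy,
                      np.ones_like(uu)], axis=-1)
    d = d_cam @ Rw2c  # rows of Rw2c are camera axes -> transpose multiply
    depth = np.full((h, w), np.inf)
    albedo = np.zeros((h, w, 3))
    normal = np.zeros((h, w, 3))
    seed = float(spec.texture_seed)

    def shade_plane(z_plane):
        dz = d[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (z_plane - C[2]) / dz
        return np.where((dz < 0) & (s > 0), s, np.inf)

    # table plane z = 0
    s = shade_plane(0.0)
    hit = s < depth
    px = C[0] + s * d[..., 0]
    py = C[1] + s * d[..., 1]
    # high-frequency wood-like texture: octaves down to ~2 px at the
    # working resolution so dense matching has signal everywhere
    tex = 0.25 + 0.65 * fractal_noise(px * 0.6, py, 3.0, seed + 1.0, 5)
    col = np.stack([tex * 0.95, tex * 0.80, tex * 0.62], axis=-1)
    depth = np.where(hit, s, depth)
    albedo = np.where(hit[..., None], col, albedo)
    normal = np.where(hit[..., None], np.array([0.0, 0.0, 1.0]), normal)

    # reference card on the table plane (overwrites the table texture)
    th = np.radians(spec.card_angle_deg)
    ca, sa = np.cos(th), np.sin(th)
    rx = (px - spec.card_center[0]) * ca + (py - spec.card_center[1]) * sa
    ry = -(px - spec.card_center[0]) * sa + (py - spec.card_center[1]) * ca
    on_card = hit & (np.abs(rx) <= CARD_LONG_CM / 2) & \
        (np.abs(ry) <= CARD_SHORT_CM / 2)
    tu = (rx + CARD_LONG_CM / 2) / CARD_LONG_CM * (template.shape[1] - 1)
    # template v runs opposite to card-frame y so the print is unmirrored
    # when viewed from above
    tv = (CARD_SHORT_CM / 2 - ry) / CARD_SHORT_CM * (template.shape[0] - 1)
    tu = np.clip(tu, 0, template.shape[1] - 1.001)
    tv = np.clip(tv, 0, template.shape[0] - 1.001)
    iu, ivv = tu.astype(int), tv.astype(int)
    fu, fv = tu - iu, tv - ivv
    tpl = template[..., 0].astype(np.float64) / 255.0
    card_val = (tpl[ivv, iu] * (1 - fu) * (1 - fv)
                + tpl[ivv, np.minimum(iu + 1, template.shape[1] - 1)] * fu * (1 - fv)
                + tpl[np.minimum(ivv + 1, template.shape[0] - 1), iu] * (1 - fu) * fv
                + tpl[np.minimum(ivv + 1, template.shape[0] - 1),
                      np.minimum(iu + 1, template.shape[1] - 1)] * fu * fv)
    card_col = np.stack([card_val, card_val, card_val * 0.97], axis=-1)
    albedo = np.where(on_card[..., None], card_col, albedo)

    # shallow dish rim: flat annulus at z = DISH_RIM_CM
    s = shade_plane(DISH_RIM_CM)
    px2 = C[0] + s * d[..., 0]
    py2 = C[1] + s * d[..., 1]
    rad = np.hypot(px2 - spec.food_center[0], py2 - spec.food_center[1])
    ring = (s < depth) & (rad >= spec.dish_radius - 0.7) & \
        (rad <= spec.dish_radius)
    rim_tex = 0.80 + 0.15 * fractal_noise(px2, py2, 0.8, seed + 3.0, 2)
    rim_col = np.stack([rim_tex, rim_tex, rim_tex], axis=-1)
    depth = np.where(ring, s, depth)
    albedo = np.where(ring[..., None], rim_col, albedo)
    normal = np.where(ring[..., None], np.array([0.0, 0.0, 1.0]), normal)

    # food shape
    shape = spec.food_shape
    fc = np.array([spec.food_center[0], spec.food_center[1], 0.0])
    if isinstance(shape, (Hemisphere, SphericalCap)):
        r = shape.radius
        zc = 0.0 if isinstance(shape, Hemisphere) else shape.height - r
        ctr = fc + np.array([0.0, 0.0, zc])
        oc = C - ctr
        b = np.einsum("ijk,k->ij", d, oc)
        cq = oc @ oc - r * r
        a2 = np.einsum("ijk,ijk->ij", d, d)  # ray dirs are not unit length
        disc = b * b - a2 * cq
        ok = disc > 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        s1 = (-b - sq) / a2  # near intersection
        pz = C[2] + s1 * d[..., 2]
        ok = ok & (s1 > 0) & (pz >= -1e-9)
        hit = ok & (s1 < depth)
        hx = C[0] + s1 * d[..., 0]
        hy = C[1] + s1 * d[..., 1]
        hz = pz
        nrm = np.stack([(hx - ctr[0]) / r, (hy - ctr[1]) / r,
                        (hz - ctr[2]) / r], axis=-1)
        tex = 0.25 + 0.70 * fractal_noise(hx + 2.7 * hz, hy - 1.3 * hz,
                                          1.1, seed + 5.0, 4)
        col = np.stack([tex * 0.9, tex * 0.65, tex * 0.45], axis=-1)
        depth = np.where(hit, s1, depth)
        albedo = np.where(hit[..., None], col, albedo)
        normal = np.where(hit[..., None], nrm, normal)
    else:  # Box
        lo = fc + np.array([-shape.a / 2, -shape.b / 2, 0.0])
        hi = fc + np.array([shape.a / 2, shape.b / 2, shape.c])
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - C) / d
            t2 = (hi - C) / d
        tmin = np.minimum(t1, t2).max(axis=-1)
        tmax = np.maximum(t1, t2).min(axis=-1)
        ok = (tmax > np.maximum(tmin, 0.0))
        s1 = np.where(tmin > 0, tmin, tmax)
        hit = ok & (s1 > 0) & (s1 < depth)
        hx = C[0] + s1 * d[..., 0]
        hy = C[1] + s1 * d[..., 1]
        hz = C[2] + s1 * d[..., 2]
        # face normal: the axis on which the hit point touches a slab bound
        eps = 1e-6
        nrm = np.zeros(hx.shape + (3,))
        nrm[..., 0] = np.where(np.abs(hx - lo[0]) < eps, -1,
                               np.where(np.abs(hx - hi[0]) < eps, 1, 0))
        nrm[..., 1] = np.where(np.abs(hy - lo[1]) < eps, -1,
                               np.where(np.abs(hy - hi[1]) < eps, 1, 0))
        nrm[..., 2] = np.where(np.abs(hz - hi[2]) < eps, 1, 0)
        nn = np.linalg.norm(nrm, axis=-1, keepdims=True)
        nrm = np.where(nn > 0, nrm / np.maximum(nn, 1e-12), nrm)
        tex = 0.25 + 0.70 * fractal_noise(hx + hz, hy - hz, 1.0,
                                          seed + 5.0, 4)
        col = np.stack([tex * 0.9, tex * 0.65, tex * 0.45], axis=-1)
        depth = np.where(hit, s1, depth)
        albedo = np.where(hit[..., None], col, albedo)
        normal = np.where(hit[..., None], nrm, normal)

    light = np.array([0.30, -0.45, 0.84])
    light = light / np.linalg.norm(light)
    lam = np.clip(np.einsum("ijk,k->ij", normal, light), 0.0, 1.0)
    shade = (0.35 + 0.65 * lam)[..., None]
    img = np.clip(albedo * shade * 255.0, 0, 255)
    img[~np.isfinite(depth)] = 40.0  # background outside the table (none)
    return np.rint(img).astype(np.uint8)


def render_scene(spec: SceneSpec, seed: int = 0) -> SceneTruth:
    """Ray-cast the two views of a scene and return the full ground truth.

    Deterministic for a fixed (spec, seed); ``seed`` drives only the
    hand-held orientation jitter of the second camera.  Raises
    :class:`SceneGenerationError` if the card or the food falls outside
    either view.
    """
    rng = np.random.default_rng(seed)
    K = spec.intrinsics
    h, w = K.image_shape
    el = np.radians(spec.elevation_deg)
    az = np.radians(spec.azimuth_deg)
    card_c = np.array([spec.card_center[0], spec.card_center[1], 0.0])
    food_c = np.array([spec.food_center[0], spec.food_center[1], 0.0])
    target = 0.5 * (card_c + food_c)
    direction = np.array([np.sin(el) * np.cos(az), np.sin(el) * np.sin(az),
                          np.cos(el)])
    C1 = target + spec.camera_distance * direction
    R1 = _look_at(C1, target)
    C2 = C1 + spec.baseline_cm * R1[0]  # shift along camera-1's x (right)
    R2 = _small_rotation(rng, spec.tilt_jitter_deg) @ R1

    # prefilter the card texture to the expected minification (mip level):
    # the template has ~40 px/cm, the image about fx/distance px/cm, and
    # sampling without the matching low-pass would alias the pattern.
    template = make_card_template(seed=spec.texture_seed)
    tpl_px_per_cm = template.shape[1] / CARD_LONG_CM
    img_px_per_cm = K.fx / spec.camera_distance
    footprint = tpl_px_per_cm / max(img_px_per_cm, 1e-6)
    if footprint > 1.0:
        from scipy.ndimage import gaussian_filter
        template = gaussian_filter(
            template.astype(np.float64), sigma=(0.5 * footprint,) * 2 + (0.0,)
        ).astype(np.uint8)
    img1 = _render_view(spec, R1, C1, template)
    img2 = _render_view(spec, R2, C2, template)

    R_rel = R2 @ R1.T
    t_rel = R2 @ (C1 - C2)
    corners = _card_corners_world(spec)
    truth = SceneTruth(spec, (img1, img2), K, R_rel, t_rel,
                       analytic_volume(spec.food_shape), corners,
                       (np.empty(0),) * 2, (R1, R2), (C1, C2))
    cpx1 = truth.project(corners, 0)
    cpx2 = truth.project(corners, 1)
    truth.card_corners_px = (cpx1, cpx2)
    for cpx in (cpx1, cpx2):
        if (cpx[:, 0] < 0).any() or (cpx[:, 0] >= w).any() or \
                (cpx[:, 1] < 0).any() or (cpx[:, 1] >= h).any():
            raise SceneGenerationError("reference card outside a view")
    fpx1 = truth.project(food_c[None], 0)[0]
    fpx2 = truth.project(food_c[None], 1)[0]
    for fpx in (fpx1, fpx2):
        if not (0 <= fpx[0] < w and 0 <= fpx[1] < h):
            raise SceneGenerationError("food outside a view")
    return truth


def food_surface_points(spec: SceneSpec, n: int = 2000,
                        seed: int = 0) -> np.ndarray:
    """Quasi-uniform sample of the food's exposed surface (world cm), for
    point-to-surface oracles."""
    rng = np.random.default_rng(seed)
    fc = np.array([spec.food_center[0], spec.food_center[1], 0.0])
    shape = spec.food_shape
    if isinstance(shape, (Hemisphere, SphericalCap)):
        r = shape.radius
        zc = 0.0 if isinstance(shape, Hemisphere) else shape.height - r
        zmin = -zc / r  # cos(theta) at the table plane
        u = rng.uniform(max(zmin, -1.0), 1.0, n)
        ph = rng.uniform(0, 2 * np.pi, n)
        s = np.sqrt(1 - u * u)
        pts = np.stack([r * s * np.cos(ph), r * s * np.sin(ph),
                        zc + r * u], axis=1)
        return pts[pts[:, 2] >= 0] + fc
    # box: top face + four sides, area-weighted
    areas = np.array([shape.a * shape.b, shape.a * shape.c, shape.a * shape.c,
                      shape.b * shape.c, shape.b * shape.c], dtype=float)
    face = rng.choice(5, size=n, p=areas / areas.sum())
    u = rng.uniform(-0.5, 0.5, n)
    v = rng.uniform(0.0, 1.0, n)
    pts = np.empty((n, 3))
    top = face == 0
    pts[top] = np.stack([u[top] * shape.a, (v[top] - 0.5) * shape.b,
                         np.full(top.sum(), shape.c)], axis=1)
    for f, sign, along_x in ((1, -1, True), (2, 1, True),
                             (3, -1, False), (4, 1, False)):
        m = face == f
        if along_x:  # walls at y = +/- b/2
            pts[m] = np.stack([u[m] * shape.a,
                               np.full(m.sum(), sign * shape.b / 2),
                               v[m] * shape.c], axis=1)
        else:  # walls at x = +/- a/2
            pts[m] = np.stack([np.full(m.sum(), sign * shape.a / 2),
                               u[m] * shape.b, v[m] * shape.c], axis=1)
    return pts + fc


# --------------------------------------------------------------------------
# scene suites


def make_scene_suite(n: int, seed: int = 0) -> list[SceneSpec]:
    """Randomized scene specs spanning the three shape families within the
    capture-protocol bounds (distance 40-50 cm, elevation 45 +/- 5 deg).

    Deterministic for fixed (n, seed).  Five capture-pose perturbations per
    scene are derivable with :func:`perturb_capture` and sub-seeds 0-4.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        fam = i % 3
        if fam == 0:
            shape: FoodShape = Hemisphere(rng.uniform(2.5, 4.0))
        elif fam == 1:
            r = rng.uniform(4.0, 6.0)
            shape = SphericalCap(r, rng.uniform(1.5, min(2.6, r)))
        else:
            shape = Box(rng.uniform(4.0, 7.0), rng.uniform(4.0, 7.0),
                        rng.uniform(2.0, 3.2))
        dish = rng.uniform(7.0, 9.0)
        specs.append(SceneSpec(
            food_shape=shape,
            food_center=(0.0, 0.0),
            card_center=(rng.uniform(-2.0, 2.0), -(dish + 5.0)),
            card_angle_deg=rng.uniform(-12.0, 12.0),
            dish_radius=dish,
            texture_seed=int(rng.integers(0, 2 ** 20)),
            camera_distance=rng.uniform(40.0, 50.0),
            elevation_deg=rng.uniform(40.0, 50.0),
            azimuth_deg=90.0 + rng.uniform(-10.0, 10.0),
            baseline_cm=rng.uniform(3.5, 4.5),
        ))
    return specs


def perturb_capture(spec: SceneSpec, sub_seed: int) -> SceneSpec:
    """One of the five perturbed capture poses used for repeated estimates
    of the same dish: jittered distance, elevation, azimuth and baseline,
    within protocol bounds.  Deterministic for (spec, sub_seed)."""
    rng = np.random.default_rng((spec.texture_seed * 31 + sub_seed) % (2 ** 31))
    return replace(
        spec,
        camera_distance=float(np.clip(
            spec.camera_distance + rng.uniform(-2.0, 2.0), 40.0, 50.0)),
        elevation_deg=spec.elevation_deg + rng.uniform(-2.0, 2.0),
        azimuth_deg=spec.azimuth_deg + rng.uniform(-4.0, 4.0),
        baseline_cm=float(np.clip(
            spec.baseline_cm + rng.uniform(-0.4, 0.4), 3.0, 5.0)),
    )
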
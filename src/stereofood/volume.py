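"""Food volume from the metric point cloud, and nutrition from the volume.

The table (which the reference card and the bottom of the shallow dish
define) is recovered as the RANSAC plane with the largest support in the
cloud; points above it are the food.  The volume is the convex hull of the
food points together with their orthogonal projections onto the plane —
the projections close the unseen base, without which the hull would
underestimate any shape whose silhouette does not already touch the
table.  Weight follows from a reference weight/volume pair (a density
surrogate): W_est = V_est * W_ref / V_ref, and each macronutrient scales
per 100 g: Macro_est = Macro_per100g * W_est / 100.

The convex hull overestimates concave foods; that bias is inherent to the
method and documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import (DegeneracyError, DegenerateGeometryError, EmptyFoodError,
                     InputError, ParameterError)

# --------------------------------------------------------------------------
# data types


@dataclass
class PointCloud:
    """Metric 3D points (cm) with optional per-point RGB colors."""

    points: np.ndarray  # (n, 3) float
    colors: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Plane:
    """Plane {p : normal . p = offset}, unit normal oriented so the camera
    side is positive."""

    normal: np.ndarray
    offset: float
    inlier_count: int = 0

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0 or not np.isfinite(norm):
            raise ParameterError("plane normal must be nonzero")
        self.normal = n / norm
        self.offset = float(self.offset) / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.normal - self.offset


@dataclass
class TriangleMesh:
    """Triangle surface over the food points (vertices in cm)."""

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int


@dataclass
class VolumeEstimate:
    v_est: float  # cm^3
    n_food_points: int
    plane: Plane


@dataclass
class FoodCompositionRecord:
    """Per-food reference data: a weight/volume pair from a food-composition
    database plus per-100 g macronutrients."""

    food_id: str
    w_usda: float  # g
    v_usda: float  # cm^3
    carbs_per100g: float
    protein_per100g: float
    fat_per100g: float
    kcal_per100g: float

    def __post_init__(self):
        if self.w_usda <= 0 or self.v_usda <= 0:
            raise ParameterError(
                f"{self.food_id}: reference weight and volume must be > 0")
        for name in ("carbs_per100g", "protein_per100g", "fat_per100g",
                     "kcal_per100g"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{self.food_id}: {name} must be >= 0")


@dataclass
class NutritionEstimate:
    w_est: float  # g
    macros_est: dict[str, float]  # macro name -> amount (g or kcal)


@dataclass
class DishEvaluation:
    """One dish's truth, its five repeated volume estimates, and MAPE."""

    v_real: float
    v_estimates: list[float]
    mape_i: float


# --------------------------------------------------------------------------
# plane fitting and food extraction


def _plane_from_points(p: np.ndarray) -> tuple[np.ndarray, float] | None:
    c = p.mean(axis=0)
    _, s, vt = np.linalg.svd(p - c, full_matrices=False)
    n = vt[-1]
    if not np.isfinite(n).all():
        return None
    return n, float(n @ c)


def fit_plane_ransac(cloud: PointCloud, dist_threshold: float = 0.4,
                     seed: int = 0, max_iters: int = 2000,
                     confidence: float = 0.999,
                     camera_center=(0.0, 0.0, 0.0)) -> Plane:
    """RANSAC plane with the largest support, refined by least squares.

    The inlier threshold is a distance in cm (default 0.4).  The normal is
    oriented so the camera center has positive signed distance, making
    "above the plane" mean "toward the camera".  Deterministic for a
    fixed seed.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise DegeneracyError(f"plane fit needs >= 3 points, got {len(pts)}")
    rng = np.random.default_rng(seed)
    n_pts = len(pts)
    best_count, best_mask = 0, None
    iters_needed = max_iters
    it = 0
    while it < min(iters_needed, max_iters):
        it += 1
        idx = rng.choice(n_pts, size=3, replace=False)
        a, b, c = pts[idx]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        d = pts @ n - n @ a
        mask = np.abs(d) < dist_threshold
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
            wfrac = count / n_pts
            denom = np.log1p(-min(wfrac ** 3, 1 - 1e-12))
            if denom < 0:
                iters_needed = int(np.ceil(np.log(1 - confidence) / denom))
    if best_mask is None:
        raise DegeneracyError("all RANSAC samples were collinear")
    fit = _plane_from_points(pts[best_mask])
    if fit is None:
        raise DegeneracyError("plane refinement failed")
    normal, offset = fit
    mask = np.abs(pts @ normal - offset) < dist_threshold
    if mask.sum() >= 3:  # consolidate once on the refined inliers
        refit = _plane_from_points(pts[mask])
        if refit is not None:
            normal, offset = refit
            mask = np.abs(pts @ normal - offset) < dist_threshold
    cam = np.asarray(camera_center, dtype=np.float64)
    if cam @ normal - offset < 0:
        normal, offset = -normal, -offset
    return Plane(normal, offset, int(mask.sum()))


def extract_food_points(cloud: PointCloud, plane: Plane,
                        min_height: float = 0.3) -> PointCloud:
    """Points strictly above the plane by more than ``min_height`` cm.

    The margin removes table, card and shallow-dish-rim points along with
    plane-fit noise.  Point order is preserved.  Raises
    :class:`EmptyFoodError` when nothing remains (reconstruction failed
    or the dish is empty).
    """
    d = plane.signed_distance(cloud.points)
    keep = d > min_height
    if not keep.any():
        raise EmptyFoodError(
            f"no points more than {min_height} cm above the table plane")
    colors = cloud.colors[keep] if cloud.colors is not None else None
    return PointCloud(cloud.points[keep], colors)


def _plane_basis(plane: Plane) -> np.ndarray:
    """Two orthonormal in-plane axes (rows) for projecting onto a plane."""
    n = plane.normal
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    return np.stack([u, np.cross(n, u)])


def select_food_cluster(food: PointCloud, plane: Plane,
                        cell_cm: float = 0.5,
                        min_cell_points: int = 2) -> PointCloud:
    """Keep the connected blob of above-plane points that is the food.

    Reconstruction noise leaves scattered table points above the
    extraction threshold; a convex hull over them would dwarf the real
    food volume.  The above-plane points are binned on a 2-D grid in
    plane coordinates, connected components are found, and the component
    containing the highest points (95th-percentile height) is returned —
    the food stands taller than any noise sheet or dish-rim leak.
    """
    from scipy import ndimage as ndi

    pts = food.points
    if len(pts) < 4:
        return food
    B = _plane_basis(plane)
    uv = (pts - plane.offset * plane.normal) @ B.T
    h = plane.signed_distance(pts)
    ij = np.floor((uv - uv.min(axis=0)) / cell_cm).astype(np.int64)
    shape = ij.max(axis=0) + 1
    counts2d = np.zeros(shape, dtype=np.int32)
    np.add.at(counts2d, (ij[:, 0], ij[:, 1]), 1)
    grid = counts2d >= min_cell_points  # sparse noise cells do not connect
    lab, n = ndi.label(grid, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return food
    point_label = lab[ij[:, 0], ij[:, 1]]
    tall = h >= np.percentile(h, 95.0)
    counts = np.bincount(point_label[tall], minlength=n + 1)
    if counts[1:].max() == 0:
        tall = np.ones(len(h), dtype=bool)
        counts = np.bincount(point_label[tall], minlength=n + 1)
    target = int(np.argmax(counts[1:])) + 1
    keep = point_label == target

    # second stage: noise can bridge the food to nearby raised structure
    # (typically the shallow dish rim); keep only points within reach of
    # the cluster's tall core
    core_height = max(0.5, 0.25 * float(np.percentile(h[keep], 98.0)))
    core = keep & (h > core_height)
    if core.sum() >= 4:
        from scipy.spatial import cKDTree

        tree = cKDTree(uv[core])
        d_core, _ = tree.query(uv[keep], k=1)
        sel = np.zeros(len(pts), dtype=bool)
        sel[np.nonzero(keep)[0][d_core <= 1.5]] = True
        if sel.sum() >= 4:
            keep = sel
    colors = food.colors[keep] if food.colors is not None else None
    return PointCloud(pts[keep], colors)


def rasterize_food_surface(food: PointCloud, plane: Plane,
                           cell_cm: float = 0.4,
                           min_points: int = 3,
                           max_spread_cm: float = 1.0) -> PointCloud:
    """Robust resampling of the food surface on a plane-aligned grid.

    The convex hull is an extreme-point statistic, so a handful of noise
    spikes inflate the volume arbitrarily.  The food points are binned on
    a 2-D grid in plane coordinates and each cell with at least
    ``min_points`` points is replaced by its center at the *median*
    height of its points — a surface sample that preserves the shape
    while being immune to isolated outliers.

    Cells whose height spread (p90 - p10) exceeds ``max_spread_cm`` are
    dropped: they are either near-vertical walls — which the hull covers
    anyway via the top edge and the base closure — or matching-noise
    spray around such walls, which would otherwise push hull facets
    outward.
    """
    pts = food.points
    if len(pts) < 4:
        return food
    B = _plane_basis(plane)
    uv = (pts - plane.offset * plane.normal) @ B.T
    h = plane.signed_distance(pts)
    origin = uv.min(axis=0)
    ij = np.floor((uv - origin) / cell_cm).astype(np.int64)
    shape = ij.max(axis=0) + 1
    flat = ij[:, 0] * shape[1] + ij[:, 1]
    order = np.argsort(flat, kind="stable")
    flat_s, h_s = flat[order], h[order]
    bounds = np.flatnonzero(np.diff(flat_s)) + 1
    groups = np.split(h_s, bounds)
    cells = np.concatenate([[flat_s[0]], flat_s[bounds]])
    out = []
    for cell, hh in zip(cells, groups):
        if len(hh) < min_points:
            continue
        if np.percentile(hh, 90) - np.percentile(hh, 10) > max_spread_cm:
            continue
        i, j = divmod(int(cell), int(shape[1]))
        center = origin + (np.array([i, j]) + 0.5) * cell_cm
        hmed = float(np.median(hh))
        out.append(center[0] * B[0] + center[1] * B[1]
                   + (plane.offset + hmed) * plane.normal)
    if len(out) < 4:
        return food
    return PointCloud(np.asarray(out))


def keep_tall_components(surface: PointCloud, plane: Plane,
                         cell_cm: float = 0.3,
                         height_fraction: float = 0.6) -> PointCloud:
    """Drop low-lying satellite components of a rasterized food surface.

    Matting and half-occlusion artifacts form arcs and patches around the
    silhouette that disconnect from the food at raster resolution and
    stay well below its height.  Components whose peak height reaches
    ``height_fraction`` of the global 98th-percentile height are kept —
    so a genuinely fragmented food surface survives — and everything
    lower goes.
    """
    from scipy import ndimage as ndi

    pts = surface.points
    if len(pts) < 8:
        return surface
    B = _plane_basis(plane)
    uv = (pts - plane.offset * plane.normal) @ B.T
    h = plane.signed_distance(pts)
    ij = np.floor((uv - uv.min(axis=0)) / cell_cm + 0.5).astype(np.int64)
    shape = ij.max(axis=0) + 1
    grid = np.zeros(shape, dtype=bool)
    grid[ij[:, 0], ij[:, 1]] = True
    lab, n = ndi.label(grid, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return surface
    point_label = lab[ij[:, 0], ij[:, 1]]
    h_bar = height_fraction * float(np.percentile(h, 98.0))
    keep_labels = {int(l) for l in np.unique(point_label[h >= h_bar])
                   if l > 0}
    keep = np.isin(point_label, sorted(keep_labels))
    if keep.sum() < 4:
        return surface
    return PointCloud(pts[keep])


def despeckle_surface(surface: PointCloud, plane: Plane,
                      cell_cm: float = 0.3, max_step_cm: float = 0.5,
                      iterations: int = 2) -> PointCloud:
    """Remove local spike cells from a rasterized food surface.

    A cell is dropped when its height exceeds the maximum of its existing
    8-neighbors by more than ``max_step_cm``, or when it has no neighbor
    at all — isolated floaters and one-cell towers that would become hull
    vertices.  Smooth dome tops rise only gradually above their ring of
    neighbors and are untouched.
    """
    pts = surface.points
    if len(pts) < 8:
        return surface
    B = _plane_basis(plane)
    for _ in range(iterations):
        uv = (pts - plane.offset * plane.normal) @ B.T
        h = plane.signed_distance(pts)
        origin = uv.min(axis=0)
        ij = np.floor((uv - origin) / cell_cm + 0.5).astype(np.int64)
        shape = ij.max(axis=0) + 1
        grid = np.full(shape, -np.inf)
        grid[ij[:, 0], ij[:, 1]] = h
        pad = np.pad(grid, 1, constant_values=-np.inf)
        nbmax = np.full(shape, -np.inf)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                nbmax = np.maximum(
                    nbmax, pad[1 + dy:shape[0] + 1 + dy,
                               1 + dx:shape[1] + 1 + dx])
        nb = nbmax[ij[:, 0], ij[:, 1]]
        keep = np.isfinite(nb) & (h - nb <= max_step_cm)
        if keep.all() or keep.sum() < 8:
            break
        pts = pts[keep]
    return PointCloud(pts)


def refine_plane_local(cloud: PointCloud, plane: Plane, food: PointCloud,
                       dist_threshold: float = 0.4,
                       ring_cm: tuple[float, float] = (1.0, 8.0)
                       ) -> Plane:
    """Refit the table plane on the annulus of table points around the food.

    A globally fitted plane absorbs any smooth low-frequency warp of the
    reconstruction, tilting it relative to the table immediately under
    the dish; the food height is what matters, so the plane is re-
    estimated by least squares from the global-plane inliers whose
    in-plane distance to the food footprint lies within ``ring_cm``.
    Falls back to the input plane when the ring is under-populated.
    """
    B = _plane_basis(plane)
    fuv = (food.points - plane.offset * plane.normal) @ B.T
    c = fuv.mean(axis=0)
    r_food = np.percentile(np.linalg.norm(fuv - c, axis=1), 98.0)
    uv = (cloud.points - plane.offset * plane.normal) @ B.T
    rad = np.linalg.norm(uv - c, axis=1)
    d = plane.signed_distance(cloud.points)
    ring = (np.abs(d) < dist_threshold) & \
        (rad > r_food + ring_cm[0]) & (rad < r_food + ring_cm[1])
    if ring.sum() < 50:
        return plane
    fit = _plane_from_points(cloud.points[ring])
    if fit is None:
        return plane
    normal, offset = fit
    if normal @ plane.normal < 0:
        normal, offset = -normal, -offset
    # the refit corrects sub-degree low-frequency warp; a large swing
    # means the ring was contaminated (dish rim, noise sheet) — keep the
    # global plane instead
    if np.degrees(np.arccos(np.clip(normal @ plane.normal, -1, 1))) > 2.0:
        return plane
    return Plane(normal, offset, int(ring.sum()))


# --------------------------------------------------------------------------
# surface and volume


def mesh_surface(points: PointCloud | np.ndarray) -> TriangleMesh:
    """Delaunay triangle mesh over the food points.

    The points are projected onto their best-fit plane, triangulated in
    2D, and the triangles lifted back to 3D — the standard terrain-style
    surface for a cloud seen from one side.  Raises
    :class:`DegenerateGeometryError` for < 4 or coplanar-degenerate
    input.
    """
    pts = points.points if isinstance(points, PointCloud) else \
        np.asarray(points, dtype=np.float64)
    if len(pts) < 4:
        raise DegenerateGeometryError(
            f"surface meshing needs >= 4 points, got {len(pts)}")
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    if s[1] < 1e-9:
        raise DegenerateGeometryError("points are collinear")
    uv = (pts - c) @ vt[:2].T
    try:
        tri = Delaunay(uv)
    except QhullError as exc:
        raise DegenerateGeometryError(f"triangulation failed: {exc}") from exc
    # drop degenerate (zero-area) triangles
    t = tri.simplices
    a = pts[t[:, 1]] - pts[t[:, 0]]
    b = pts[t[:, 2]] - pts[t[:, 0]]
    area = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    return TriangleMesh(pts.copy(), t[area > 1e-12])


def estimate_volume(food: PointCloud, plane: Plane) -> VolumeEstimate:
    """Convex-hull volume of the food above the table plane, in cm^3.

    The hull is taken over the food points together with their orthogonal
    projections onto the plane, which closes the unseen base on the
    table; without it the hull would slice away everything below the
    lowest reconstructed point.
    """
    pts = food.points
    if len(pts) < 4:
        raise DegenerateGeometryError(
            f"volume needs >= 4 points above the plane, got {len(pts)}")
    d = plane.signed_distance(pts)
    base = pts - d[:, None] * plane.normal
    try:
        hull = ConvexHull(np.vstack([pts, base]))
    except QhullError as exc:
        raise DegenerateGeometryError(f"hull construction failed: {exc}") \
            from exc
    return VolumeEstimate(float(hull.volume), len(pts), plane)


# --------------------------------------------------------------------------
# nutrition (reference-database scaling)


def estimate_weight(v_est: float, rec: FoodCompositionRecord) -> float:
    """Weight in grams: W_est = V_est * W_ref / V_ref."""
    if v_est < 0:
        raise ParameterError(f"v_est must be >= 0, got {v_est}")
    return v_est * rec.w_usda / rec.v_usda


def estimate_macros(w_est: float, rec: FoodCompositionRecord
                    ) -> NutritionEstimate:
    """Per-macronutrient amounts: Macro_est = Macro_per100g * W_est / 100."""
    if w_est < 0:
        raise ParameterError(f"w_est must be >= 0, got {w_est}")
    macros = {
        "carbs_g": rec.carbs_per100g * w_est / 100.0,
        "protein_g": rec.protein_per100g * w_est / 100.0,
        "fat_g": rec.fat_per100g * w_est / 100.0,
        "kcal": rec.kcal_per100g * w_est / 100.0,
    }
    return NutritionEstimate(float(w_est), macros)


# --------------------------------------------------------------------------
# evaluation metrics


def mape_dish(v_real: float, v_estimates) -> float:
    """Mean absolute percentage error of one dish's five repeated volume
    estimates: mean of |v_real - v_est| / v_real."""
    v = np.asarray(v_estimates, dtype=np.float64)
    if v_real <= 0:
        raise ParameterError(f"v_real must be > 0, got {v_real}")
    if v.shape != (5,):
        raise ParameterError(f"exactly 5 estimates required, got {v.shape}")
    return float(np.mean(np.abs((v_real - v) / v_real)))


def mape_overall(dish_mapes) -> float:
    """Arithmetic mean of per-dish MAPEs."""
    m = np.asarray(dish_mapes, dtype=np.float64)
    if m.size == 0:
        raise ParameterError("dish_mapes must be non-empty")
    return float(m.mean())


# --------------------------------------------------------------------------
# composition table I/O

_REQUIRED_COLUMNS = ("food_id", "w_usda_g", "v_usda_cm3", "carbs_per100g",
                     "protein_per100g", "fat_per100g", "kcal_per100g")


def load_composition_table(path) -> dict[str, FoodCompositionRecord]:
    """Read a food-composition CSV into records keyed by food_id.

    Expected columns: food_id, w_usda_g, v_usda_cm3, carbs_per100g,
    protein_per100g, fat_per100g, kcal_per100g.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read composition table {path!r}: {exc}") \
            from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(
            f"composition table {path!r} lacks columns: {missing}")
    records = {}
    for _, row in df.iterrows():
        rec = FoodCompositionRecord(
            str(row["food_id"]), float(row["w_usda_g"]),
            float(row["v_usda_cm3"]), float(row["carbs_per100g"]),
            float(row["protein_per100g"]), float(row["fat_per100g"]),
            float(row["kcal_per100g"]))
        records[rec.food_id] = rec
    if not records:
        raise InputError(f"composition table {path!r} is empty")
    return records


def default_composition_path():
    """Path of the packaged illustrative composition table."""
    from importlib.resources import files
    return files("stereofood.data") / "composition.csv"
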
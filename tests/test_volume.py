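"""Plane fitting, food extraction, hull volume, nutrition arithmetic,
and the MAPE evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stereofood import volume as vol
from stereofood.errors import (DegeneracyError, DegenerateGeometryError,
                               EmptyFoodError, InputError, ParameterError)


def _hemisphere_cloud(r=3.0, n=4000, seed=0, table=True):
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 1, n)
    ph = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - u * u)
    pts = np.stack([r * s * np.cos(ph), r * s * np.sin(ph), r * u], axis=1)
    if table:
        t = np.hstack([rng.uniform(-12, 12, (3000, 2)), np.zeros((3000, 1))])
        t = t[np.hypot(t[:, 0], t[:, 1]) > r + 0.2]
        pts = np.vstack([pts, t])
    return vol.PointCloud(pts)


REC = vol.FoodCompositionRecord("test", 200.0, 250.0, 30.0, 8.0, 12.0, 180.0)


# --------------------------------------------------------------------------
# plane fitting


def test_exact_plane_is_recovered_and_oriented_to_camera():
    rng = np.random.default_rng(0)
    pts = np.hstack([rng.uniform(-10, 10, (500, 2)), np.zeros((500, 1))])
    # camera sits above the plane at negative z in this frame? place it at
    # +z: the normal must give the camera positive signed distance
    plane = vol.fit_plane_ransac(vol.PointCloud(pts), seed=0,
                                 camera_center=(0, 0, 10.0))
    assert abs(plane.offset) < 1e-9
    assert plane.normal[2] == pytest.approx(1.0)
    assert plane.signed_distance(np.array([[0, 0, 10.0]]))[0] > 0


def test_plane_inlier_count_matches_brute_force_recount():
    cloud = _hemisphere_cloud()
    plane = vol.fit_plane_ransac(cloud, dist_threshold=0.4, seed=1)
    recount = int((np.abs(plane.signed_distance(cloud.points)) < 0.4).sum())
    assert plane.inlier_count == recount


def test_noisy_table_plane_within_tolerance():
    """Dominant table at z=0 with 0.05 cm noise: normal within 2 degrees,
    offset within 0.2 cm."""
    rng = np.random.default_rng(2)
    pts = np.hstack([rng.uniform(-12, 12, (4000, 2)),
                     rng.normal(0, 0.05, (4000, 1))])
    blob = rng.uniform(0, 3, (400, 3))
    plane = vol.fit_plane_ransac(vol.PointCloud(np.vstack([pts, blob])),
                                 seed=3, camera_center=(0, 0, 40.0))
    ang = np.degrees(np.arccos(abs(plane.normal[2])))
    assert ang < 2.0
    assert abs(plane.offset) < 0.2


def test_plane_needs_three_points():
    with pytest.raises(DegeneracyError):
        vol.fit_plane_ransac(vol.PointCloud(np.zeros((2, 3))))


# --------------------------------------------------------------------------
# food extraction


def test_extraction_matches_signed_distance_recount():
    cloud = _hemisphere_cloud()
    plane = vol.Plane(np.array([0, 0, 1.0]), 0.0)
    food = vol.extract_food_points(cloud, plane, 0.3)
    expected = cloud.points[cloud.points[:, 2] > 0.3]
    assert np.array_equal(food.points, expected)


def test_extraction_empty_raises():
    pts = np.hstack([np.random.default_rng(0).uniform(-5, 5, (100, 2)),
                     np.zeros((100, 1))])
    plane = vol.Plane(np.array([0, 0, 1.0]), 0.0)
    with pytest.raises(EmptyFoodError):
        vol.extract_food_points(vol.PointCloud(pts), plane, 0.3)


def test_extraction_boundary_epsilon_retained():
    pts = np.array([[0, 0, 1e-9], [1, 1, 0.0]])
    plane = vol.Plane(np.array([0, 0, 1.0]), 0.0)
    food = vol.extract_food_points(vol.PointCloud(pts), plane, 0.0)
    assert len(food) == 1


# --------------------------------------------------------------------------
# surface meshing


def test_tetrahedron_meshes():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.3, 1.0]])
    mesh = vol.mesh_surface(vol.PointCloud(pts))
    assert len(mesh.triangles) >= 1
    assert mesh.triangles.max() < 4


def test_hemisphere_mesh_covers_all_vertices():
    cloud = _hemisphere_cloud(n=500, table=False)
    mesh = vol.mesh_surface(cloud)
    used = np.unique(mesh.triangles)
    # every input vertex appears in at least one triangle (Delaunay of the
    # planar projection covers the convex footprint)
    assert len(used) >= 0.99 * len(cloud)


def test_mesh_rejects_insufficient_points():
    with pytest.raises(DegenerateGeometryError):
        vol.mesh_surface(vol.PointCloud(np.zeros((3, 3))))
    line = np.stack([np.linspace(0, 1, 10)] * 3, axis=1)
    with pytest.raises(DegenerateGeometryError):
        vol.mesh_surface(vol.PointCloud(line))


# --------------------------------------------------------------------------
# hull volume


def test_unit_cube_volume_exact():
    cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                     for z in (0, 1)], dtype=float)
    plane = vol.Plane(np.array([0, 0, 1.0]), 0.0)
    est = vol.estimate_volume(vol.PointCloud(cube[cube[:, 2] > 0]), plane)
    assert est.v_est == pytest.approx(1.0, abs=1e-9)


def test_hemisphere_volume_within_three_percent():
    r = 3.0
    est = vol.estimate_volume(_hemisphere_cloud(r, 6000, table=False),
                              vol.Plane(np.array([0, 0, 1.0]), 0.0))
    assert est.v_est == pytest.approx(2 / 3 * np.pi * r ** 3, rel=0.03)


def test_spherical_cap_volume_within_three_percent():
    r, h = 5.0, 2.0
    rng = np.random.default_rng(4)
    zc = h - r
    u = rng.uniform(-zc / r, 1, 8000)
    ph = rng.uniform(0, 2 * np.pi, 8000)
    s = np.sqrt(1 - u * u)
    pts = np.stack([r * s * np.cos(ph), r * s * np.sin(ph), zc + r * u], 1)
    pts = pts[pts[:, 2] > 0]
    est = vol.estimate_volume(vol.PointCloud(pts),
                              vol.Plane(np.array([0, 0, 1.0]), 0.0))
    assert est.v_est == pytest.approx(np.pi * h * h * (3 * r - h) / 3,
                                      rel=0.03)


def test_volume_similarity_law_k_cubed():
    """Scaling points by k about a point on the plane scales volume k^3."""
    cloud = _hemisphere_cloud(2.0, 3000, table=False)
    plane = vol.Plane(np.array([0, 0, 1.0]), 0.0)
    v1 = vol.estimate_volume(cloud, plane).v_est
    for k in (0.5, 2.0, 3.0):
        vk = vol.estimate_volume(vol.PointCloud(cloud.points * k),
                                 plane).v_est
        assert vk == pytest.approx(v1 * k ** 3, rel=1e-9)


def test_hull_ignores_interior_points():
    cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                     for z in (0.001, 1)], dtype=float)
    plane = vol.Plane(np.array([0, 0, 1.0]), 0.0)
    v1 = vol.estimate_volume(vol.PointCloud(cube), plane).v_est
    with_inner = np.vstack([cube, [[0.5, 0.5, 0.5]]])
    v2 = vol.estimate_volume(vol.PointCloud(with_inner), plane).v_est
    assert v2 == pytest.approx(v1, abs=1e-12)


def test_degenerate_hull_raises():
    with pytest.raises(DegenerateGeometryError):
        vol.estimate_volume(vol.PointCloud(np.zeros((3, 3))),
                            vol.Plane(np.array([0, 0, 1.0]), 0.0))


# --------------------------------------------------------------------------
# nutrition arithmetic


def test_weight_identity_and_linearity():
    assert vol.estimate_weight(REC.v_usda, REC) == pytest.approx(REC.w_usda)
    assert vol.estimate_weight(2 * REC.v_usda, REC) == pytest.approx(
        2 * REC.w_usda)
    assert vol.estimate_weight(0.0, REC) == 0.0


def test_macros_at_100g_equal_reference_values():
    nut = vol.estimate_macros(100.0, REC)
    assert nut.macros_est["carbs_g"] == pytest.approx(REC.carbs_per100g)
    assert nut.macros_est["protein_g"] == pytest.approx(REC.protein_per100g)
    assert nut.macros_est["fat_g"] == pytest.approx(REC.fat_per100g)
    assert nut.macros_est["kcal"] == pytest.approx(REC.kcal_per100g)


def test_macros_arithmetic_and_zero():
    nut = vol.estimate_macros(50.0, vol.FoodCompositionRecord(
        "x", 100, 100, 30.0, 0.0, 0.0, 0.0))
    assert nut.macros_est["carbs_g"] == pytest.approx(15.0)
    zero = vol.estimate_macros(0.0, REC)
    assert all(v == 0.0 for v in zero.macros_est.values())
    with pytest.raises(ParameterError):
        vol.estimate_macros(-1.0, REC)


@given(v=hst.floats(0.0, 1e4))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_weight_macro_composition_is_linear_in_volume(v):
    w = vol.estimate_weight(v, REC)
    nut = vol.estimate_macros(w, REC)
    expect = REC.carbs_per100g * (v * REC.w_usda / REC.v_usda) / 100.0
    assert nut.macros_est["carbs_g"] == pytest.approx(expect, rel=1e-12,
                                                      abs=1e-12)


def test_composition_record_invariants():
    with pytest.raises(ParameterError):
        vol.FoodCompositionRecord("bad", 0.0, 100, 1, 1, 1, 1)
    with pytest.raises(ParameterError):
        vol.FoodCompositionRecord("bad", 100, 100, -1, 1, 1, 1)


# --------------------------------------------------------------------------
# MAPE metrics


def test_mape_dish_hand_arithmetic():
    assert vol.mape_dish(100.0, [90, 110, 100, 95, 105]) == pytest.approx(
        0.06)
    assert vol.mape_dish(50.0, [50] * 5) == 0.0
    assert vol.mape_dish(50.0, [0] * 5) == 1.0


def test_mape_dish_validation():
    with pytest.raises(ParameterError):
        vol.mape_dish(0.0, [1] * 5)
    with pytest.raises(ParameterError):
        vol.mape_dish(10.0, [1] * 4)


@given(k=hst.floats(0.01, 100.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_mape_dish_scale_invariance(k):
    v = [90.0, 110.0, 100.0, 95.0, 105.0]
    a = vol.mape_dish(100.0, v)
    b = vol.mape_dish(100.0 * k, [x * k for x in v])
    assert a == pytest.approx(b, rel=1e-9)


def test_mape_overall_mean():
    assert vol.mape_overall([0.1]) == pytest.approx(0.1)
    assert vol.mape_overall([0.0, 0.2]) == pytest.approx(0.1)
    assert vol.mape_overall([0.105] * 148) == pytest.approx(0.105)
    with pytest.raises(ParameterError):
        vol.mape_overall([])


# --------------------------------------------------------------------------
# composition table I/O


def test_packaged_composition_table_loads():
    recs = vol.load_composition_table(vol.default_composition_path())
    assert len(recs) >= 5
    assert all(r.v_usda > 0 for r in recs.values())


def test_composition_table_missing_column(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("food_id,w_usda_g\nx,1\n")
    with pytest.raises(InputError):
        vol.load_composition_table(p)
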
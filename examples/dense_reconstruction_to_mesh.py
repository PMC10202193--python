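"""Dense reconstruction of a rendered dish, exported as PLY + OBJ.

Rectifies the pair, computes the filtered disparity, reprojects to a
metric cloud, extracts the food above the table plane, and writes the
cloud and the Delaunay surface mesh into ./scene_export/.
"""

from pathlib import Path

import numpy as np

from stereofood import epipolar as ep
from stereofood import features as ft
from stereofood import stereo as st
from stereofood import synthetic as syn
from stereofood import volume as vol
from stereofood.io import write_obj_mesh, write_ply_cloud

truth = syn.render_scene(syn.SceneSpec(food_shape=syn.SphericalCap(5, 2)),
                         seed=3)
img1, img2 = truth.images

# sparse chain for pose (the pipeline wraps all of this; shown expanded)
kp1, d1 = ft.detect_and_describe(img1, 4000, method="fast-brief")
kp2, d2 = ft.detect_and_describe(img2, 4000, method="fast-brief")
m = ft.match_bruteforce(kp1, d1, kp2, d2)
est = ep.filter_inliers_ransac(m, img1.shape[:2], seed=0)
terr = ep.symmetric_transfer_error(est.H, m.points1, m.points2)
H_tight = ep.homography_dlt(m.points1[terr < 2], m.points2[terr < 2])
F = ep.fundamental_plane_parallax(m.points1, m.points2, est.H)
inl = ep.correct_optimal(ep.inliers_from_estimate(m, est), F)
pose, _, _ = ep.recover_pose_planar(H_tight, m, inl, truth.K, truth.K)

from stereofood import scale as sc
cspec = sc.ReferenceCardSpec(
    template=syn.make_card_template(seed=truth.spec.texture_seed))
s = sc.compute_scale(sc.triangulate_card(
    sc.detect_card(img1, cspec), sc.detect_card(img2, cspec),
    truth.K, truth.K, pose), cspec)

rect = st.rectify_pair(img1, img2, truth.K, pose)
disp = st.compute_disparity(rect, num_disparities=128)
disp = st.refine_disparity_photometric(disp, rect)
disp = st.filter_disparity_wls(disp, rect.img1_rect, lam=300, sigma=3.0,
                               roi_mask=rect.valid_mask1 & rect.valid_mask2)
cloud = st.reproject_to_cloud(disp, rect, s, rect.img1_rect, stride=2)
print(f"{len(cloud)} metric points, scale {s:.3f} cm/unit")

plane = vol.fit_plane_ransac(vol.PointCloud(cloud.points[::3]), seed=0)
food = vol.select_food_cluster(
    vol.extract_food_points(cloud, plane, 0.3), plane)
mesh = vol.mesh_surface(food)
vest = vol.estimate_volume(
    vol.rasterize_food_surface(food, plane, 0.3), plane)
print(f"food points {len(food)}, surface triangles {len(mesh.triangles)}")
print(f"V_est {vest.v_est:.1f} cm^3 (true {truth.v_true:.1f})")

out = Path("scene_export")
out.mkdir(exist_ok=True)
write_ply_cloud(cloud, out / "cloud.ply")
write_ply_cloud(food, out / "food.ply")
write_obj_mesh(mesh, out / "food_mesh.obj")
print(f"wrote {out}/cloud.ply, food.ply, food_mesh.obj")
# open the PLY/OBJ in any 3D viewer; the cloud is in cm, camera-1
# rectified frame, table plane visible as the dominant flat region
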
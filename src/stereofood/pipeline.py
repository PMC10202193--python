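"""End-to-end pipeline: two food photos -> volume, weight, macronutrients.

Stage order: preprocess (CLAHE + resize) -> keypoints & brute-force
matching -> relevance gate (>= 50 matches) -> RANSAC homography inlier
filter -> fundamental matrix & optimal correspondence correction ->
relative pose -> reference-card scale -> rectification -> semi-global
disparity -> WLS filtering -> point cloud -> table plane -> convex-hull
volume -> weight and macros from the food-composition record.  Each stage
failure raises a distinct, named error.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import epipolar as ep
from . import features as ft
from . import imaging, scale, stereo, synthetic, volume
from .errors import InputError, ParameterError, RelevanceGateError

log = logging.getLogger("stereofood")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the defaults used throughout.

    Angles of attack for a misbehaving dataset are noted per field; all
    values are validated on load and unknown keys are rejected.
    """

    # preprocessing (CLAHE is for real captures; synthetic renders are
    # already contrast-normalized and are evaluated with enhance=False)
    enhance: bool = True
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    resize_shape: tuple[int, int] = (600, 800)  # (rows, cols)
    # features & matching
    descriptor: str = "fast-brief"  # stereo pair; "orb" also accepted
    card_descriptor: str = "orb"
    max_keypoints: int = 4000
    min_matches: int = 50  # relevance gate
    # robust estimation
    ransac_threshold_fraction: float = 0.006  # of the largest image dim
    ransac_confidence: float = 0.99
    ransac_max_iters: int = 5000
    inlier_model: str = "homography"  # or "fundamental"
    pose_method: str = "homography"  # or "essential"
    seed: int = 0
    # reference card
    card_long_cm: float = 8.5
    card_short_cm: float = 5.5
    card_edge: str = "long"  # or "diagonal"
    # dense stereo
    num_disparities: int = 128
    block_size: int = 5
    sgm_paths: int = 4
    photometric_refine: bool = True
    wls_lambda: float = 300.0
    wls_sigma: float = 3.0
    wls_sigma_disparity: float = 0.7
    preserve_measured_disparity: bool = True
    occlusion_clamp_px: float = 0.5
    cloud_stride: int = 2
    depth_range_cm: tuple[float, float] = (20.0, 100.0)
    # plane & food extraction
    plane_threshold_cm: float = 0.4
    plane_max_points: int = 40000
    min_food_height_cm: float = 0.3
    food_cluster_cell_cm: float = 0.4
    food_raster_cell_cm: float = 0.3
    refine_plane_locally: bool = True
    # composition table
    composition_path: str | None = None

    def __post_init__(self):
        if self.min_matches < 1:
            raise ParameterError("min_matches must be >= 1")
        if self.descriptor not in ("fast-brief", "orb") or \
                self.card_descriptor not in ("fast-brief", "orb"):
            raise ParameterError("descriptor must be 'fast-brief' or 'orb'")
        if self.inlier_model not in ("homography", "fundamental"):
            raise ParameterError(
                "inlier_model must be 'homography' or 'fundamental'")
        if self.pose_method not in ("homography", "essential"):
            raise ParameterError(
                "pose_method must be 'homography' or 'essential'")
        if not 0 < self.ransac_confidence < 1:
            raise ParameterError("ransac_confidence must be in (0, 1)")
        if self.cloud_stride < 1:
            raise ParameterError("cloud_stride must be >= 1")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise InputError(f"cannot read config {path!r}: {exc}") from exc
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("clahe_tile_grid", "resize_shape", "depth_range_cm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class PipelineResult:
    """Final output of one estimate plus per-stage diagnostics."""

    food_id: str
    v_est_cm3: float
    w_est_g: float
    macros: dict[str, float]
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"food_id": self.food_id, "v_est_cm3": self.v_est_cm3,
                       "w_est_g": self.w_est_g, "macros": self.macros,
                       "diagnostics": self.diagnostics}, fh, indent=1)


def _stage(diag, name, t0):
    dt = time.perf_counter() - t0
    log.info("stage %-16s %6.2f s", name, dt)
    diag.setdefault("timings_s", {})[name] = round(dt, 3)
    return time.perf_counter()


def reconstruct_volume(img1: np.ndarray, img2: np.ndarray,
                       K: ep.CameraIntrinsics,
                       config: PipelineConfig | None = None,
                       card_spec: scale.ReferenceCardSpec | None = None
                       ) -> tuple[volume.VolumeEstimate, dict]:
    """Run the geometric pipeline on a preprocessed, resized image pair.

    Returns the volume estimate and a diagnostics dict (match counts,
    scale factor, plane orientation, per-stage timings).  The images must
    already be at the working resolution matching ``K``.
    """
    cfg = config or PipelineConfig()
    diag: dict = {}
    t0 = time.perf_counter()

    kp1, d1 = ft.detect_and_describe(img1, cfg.max_keypoints, cfg.descriptor)
    kp2, d2 = ft.detect_and_describe(img2, cfg.max_keypoints, cfg.descriptor)
    matches = ft.match_bruteforce(kp1, d1, kp2, d2)
    diag["n_matches"] = len(matches)
    t0 = _stage(diag, "matching", t0)
    if not ft.is_relevant_pair(matches, cfg.min_matches):
        raise RelevanceGateError(
            f"only {len(matches)} matches (< {cfg.min_matches}); the two "
            "images do not show the same scene closely enough")

    est = ep.filter_inliers_ransac(
        matches, img1.shape[:2], confidence=cfg.ransac_confidence,
        seed=cfg.seed, max_iters=cfg.ransac_max_iters,
        threshold_fraction=cfg.ransac_threshold_fraction,
        model=cfg.inlier_model)
    inl = ep.inliers_from_estimate(matches, est)
    diag["n_inliers"] = len(inl)
    t0 = _stage(diag, "ransac", t0)

    F = None
    if cfg.inlier_model == "homography":
        F = ep.fundamental_plane_parallax(matches.points1, matches.points2,
                                          est.H)
    if F is None:
        F = ep.estimate_fundamental(inl)
    inl = ep.correct_optimal(inl, F)
    t0 = _stage(diag, "optimal_correction", t0)

    pose = None
    if cfg.pose_method == "homography" and cfg.inlier_model == "homography":
        terr = ep.symmetric_transfer_error(est.H, matches.points1,
                                           matches.points2)
        tight = terr < 2.0
        H_tight = est.H
        if tight.sum() >= 8:
            H_tight = ep.homography_dlt(matches.points1[tight],
                                        matches.points2[tight])
        try:
            pose, _, plane_normal_cam = ep.recover_pose_planar(
                H_tight, matches, inl, K, K)
            diag["pose_method"] = "homography-decomposition"
        except ep.AmbiguousPoseError:
            pose = None
    if pose is None:
        E = ep.essential_from_fundamental(F, K, K)
        pose, _ = ep.recover_pose(E, inl, K, K)
        diag["pose_method"] = "essential"
    t0 = _stage(diag, "pose", t0)

    cspec = card_spec or scale.ReferenceCardSpec(cfg.card_long_cm,
                                                 cfg.card_short_cm)
    det1 = scale.detect_card(img1, cspec, seed=cfg.seed,
                             method=cfg.card_descriptor)
    det2 = scale.detect_card(img2, cspec, seed=cfg.seed,
                             method=cfg.card_descriptor)
    corners3d = scale.triangulate_card(det1, det2, K, K, pose)
    s = scale.compute_scale(corners3d, cspec, cfg.card_edge)
    diag["scale_cm_per_unit"] = float(s)
    t0 = _stage(diag, "card_scale", t0)

    rect = stereo.rectify_pair(img1, img2, K, pose)
    disp = stereo.compute_disparity(rect, cfg.num_disparities,
                                    cfg.block_size, paths=cfg.sgm_paths)
    diag["disparity_invalid_frac"] = float(disp.invalid_mask.mean())
    if cfg.photometric_refine:
        disp = stereo.refine_disparity_photometric(disp, rect)
    roi = rect.valid_mask1 & rect.valid_mask2
    smoothed = stereo.filter_disparity_wls(
        disp, rect.img1_rect, cfg.wls_lambda, cfg.wls_sigma, roi_mask=roi,
        sigma_disparity=cfg.wls_sigma_disparity)
    if cfg.preserve_measured_disparity:
        # measured pixels keep their (refined) values; the smoother only
        # fills holes, and half-occlusion fills dragged away from the
        # background prior are clamped back so they cannot form a skirt
        # of phantom above-plane points next to depth edges
        pre = stereo.prefill_background(disp.values, disp.invalid_mask)
        vals = smoothed.values.copy()
        dragged = disp.invalid_mask & \
            (np.abs(vals - pre) > cfg.occlusion_clamp_px)
        vals[dragged] = pre[dragged]
        measured = ~disp.invalid_mask & np.isfinite(disp.values)
        vals[measured] = disp.values[measured]
        disp = stereo.DisparityMap(vals.astype(np.float32),
                                   smoothed.invalid_mask,
                                   disp.min_disparity)
    else:
        disp = smoothed
    cloud = stereo.reproject_to_cloud(disp, rect, s, rect.img1_rect,
                                      cfg.depth_range_cm, cfg.cloud_stride)
    diag["n_cloud_points"] = len(cloud)
    t0 = _stage(diag, "dense_stereo", t0)

    sub = cloud.points
    if len(sub) > cfg.plane_max_points:
        step = int(np.ceil(len(sub) / cfg.plane_max_points))
        sub = sub[::step]
    plane = volume.fit_plane_ransac(volume.PointCloud(sub),
                                    cfg.plane_threshold_cm, seed=cfg.seed)
    diag["plane_normal"] = [round(float(x), 4) for x in plane.normal]
    diag["plane_inliers"] = plane.inlier_count
    food = volume.extract_food_points(cloud, plane, cfg.min_food_height_cm)
    food = volume.select_food_cluster(food, plane, cfg.food_cluster_cell_cm)
    if cfg.refine_plane_locally:
        # cancel low-frequency reconstruction warp: refit the plane on the
        # table ring around the dish, then re-extract against it
        plane = volume.refine_plane_local(cloud, plane, food,
                                          cfg.plane_threshold_cm)
        diag["plane_normal_local"] = [round(float(x), 4)
                                      for x in plane.normal]
        food = volume.extract_food_points(cloud, plane,
                                          cfg.min_food_height_cm)
        food = volume.select_food_cluster(food, plane,
                                          cfg.food_cluster_cell_cm)
    diag["n_food_points"] = len(food)
    surface = volume.rasterize_food_surface(food, plane,
                                            cfg.food_raster_cell_cm)
    # phantom arcs/patches around the silhouette disconnect from the food
    # at raster resolution and stay low: keep the tall components
    surface = volume.keep_tall_components(surface, plane,
                                          cfg.food_raster_cell_cm)
    surface = volume.despeckle_surface(surface, plane,
                                       cfg.food_raster_cell_cm)
    vest = volume.estimate_volume(surface, plane)
    vest.n_food_points = len(food)
    _stage(diag, "volume", t0)
    return vest, diag


def run_pipeline(img1_path, img2_path, calib_path, food_id: str,
                 config: PipelineConfig | None = None,
                 card_spec: scale.ReferenceCardSpec | None = None
                 ) -> PipelineResult:
    """Full pipeline from image files to a nutrition estimate.

    The calibration JSON declares the image size its parameters refer to;
    the camera matrix is rescaled to the working resolution automatically.
    ``food_id`` selects the record in the food-composition table.
    """
    cfg = config or PipelineConfig()
    comp_path = cfg.composition_path or volume.default_composition_path()
    records = volume.load_composition_table(comp_path)
    if food_id not in records:
        raise InputError(
            f"food_id {food_id!r} not in composition table "
            f"({sorted(records)[:5]}...)")
    rec = records[food_id]

    K = ep.CameraIntrinsics.from_json(calib_path)
    raw1 = imaging.load_image(img1_path)
    raw2 = imaging.load_image(img2_path)
    if K.image_shape is None:
        K = ep.CameraIntrinsics(K.fx, K.fy, K.cx, K.cy, K.skew,
                                raw1.shape[:2])
    if cfg.enhance:
        raw1 = imaging.enhance_clahe(raw1, cfg.clahe_clip_limit,
                                     cfg.clahe_tile_grid)
        raw2 = imaging.enhance_clahe(raw2, cfg.clahe_clip_limit,
                                     cfg.clahe_tile_grid)
    img1 = imaging.resize_standard(raw1, cfg.resize_shape)
    img2 = imaging.resize_standard(raw2, cfg.resize_shape)
    K_work = K.rescaled(cfg.resize_shape)
    log.info("intrinsics rescaled from %s to %s", K.image_shape,
             cfg.resize_shape)

    vest, diag = reconstruct_volume(img1, img2, K_work, cfg, card_spec)
    w = volume.estimate_weight(vest.v_est, rec)
    nut = volume.estimate_macros(w, rec)
    return PipelineResult(food_id, float(vest.v_est), float(w),
                          nut.macros_est, diag)


# --------------------------------------------------------------------------
# synthetic evaluation (the five-estimates-per-dish protocol)


def estimate_scene(truth: synthetic.SceneTruth,
                   config: PipelineConfig | None = None
                   ) -> tuple[volume.VolumeEstimate, dict]:
    """Run the geometric pipeline on one rendered scene."""
    cfg = config or PipelineConfig()
    cspec = scale.ReferenceCardSpec(
        template=synthetic.make_card_template(seed=truth.spec.texture_seed))
    return reconstruct_volume(truth.images[0], truth.images[1], truth.K,
                              cfg, cspec)


def evaluate_suite(specs: list[synthetic.SceneSpec],
                   config: PipelineConfig | None = None,
                   n_estimates: int = 5,
                   render_seed: int = 0) -> dict:
    """Per-dish MAPE over repeated estimates and the overall mean.

    For each scene, ``n_estimates`` perturbed capture poses are rendered
    and the pipeline estimates the volume of each; the dish MAPE is the
    mean absolute relative error of those estimates against the analytic
    truth, and the overall figure is the mean over dishes.  Failed
    estimates are recorded and excluded (a dish with no successful
    estimate is skipped with a warning).
    """
    cfg = config or PipelineConfig()
    dishes = []
    failures = 0
    for i, spec0 in enumerate(specs):
        v_true = synthetic.analytic_volume(spec0.food_shape)
        estimates, errors = [], []
        for j in range(n_estimates):
            spec_j = synthetic.perturb_capture(spec0, j)
            try:
                truth = synthetic.render_scene(
                    spec_j, seed=render_seed + 1000 * i + j)
                vest, _ = estimate_scene(truth, cfg)
                estimates.append(float(vest.v_est))
            except Exception as exc:  # noqa: BLE001 - stage errors recorded
                failures += 1
                errors.append(f"{type(exc).__name__}: {exc}")
                log.warning("scene %d estimate %d failed: %s", i, j, exc)
        if not estimates:
            log.warning("scene %d skipped: no successful estimate", i)
            dishes.append({"scene": i, "v_true": v_true, "skipped": True,
                           "errors": errors})
            continue
        # Eq.-style dish MAPE over the available estimates (five when all
        # five capture poses succeed)
        mape_i = float(np.mean([abs(v_true - v) / v_true
                                for v in estimates]))
        dishes.append({
            "scene": i,
            "shape": type(spec0.food_shape).__name__,
            "v_true": round(v_true, 2),
            "v_estimates": [round(v, 2) for v in estimates],
            "mape_i": round(mape_i, 4),
            "errors": errors,
        })
    mapes = [d["mape_i"] for d in dishes if "mape_i" in d]
    report = {
        "n_scenes": len(specs),
        "n_failures": failures,
        "overall_mape": round(volume.mape_overall(mapes), 4) if mapes
        else None,
        "by_shape": {},
        "dishes": dishes,
    }
    for fam in ("Hemisphere", "SphericalCap", "Box"):
        fam_mapes = [d["mape_i"] for d in dishes
                     if d.get("shape") == fam and "mape_i" in d]
        if fam_mapes:
            report["by_shape"][fam] = round(float(np.mean(fam_mapes)), 4)
    return report


def format_report(report: dict) -> str:
    """Human-readable evaluation table grouped by shape family."""
    lines = ["scene  shape          v_true    estimates (cm^3)          MAPE_i"]
    for d in report["dishes"]:
        if d.get("skipped"):
            lines.append(f"{d['scene']:>5}  (skipped: no successful estimate)")
            continue
        est = ", ".join(f"{v:.0f}" for v in d["v_estimates"])
        lines.append(f"{d['scene']:>5}  {d['shape']:<13} {d['v_true']:>7.1f}"
                     f"    [{est}]  {d['mape_i']*100:5.1f}%")
    lines.append("")
    for fam, v in report["by_shape"].items():
        lines.append(f"{fam:<13} MAPE {v*100:5.1f}%")
    if report["overall_mape"] is not None:
        lines.append(f"overall       MAPE {report['overall_mape']*100:5.1f}%")
    return "\n".join(lines)
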
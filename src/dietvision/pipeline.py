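"""End-to-end orchestration: two images + gravity in, meal report out.

Stage order: card detection -> metric poses (gravity-aided) -> food
segmentation -> recognition -> dense matching -> triangulation -> table
plane -> per-item volumes -> nutrients. Each stage's failure surfaces with
the stage name; intermediates can be kept for auditing.
"""

from __future__ import annotations

import importlib.resources
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .camera import CameraIntrinsics, GravitySample, RigidPose
from .geometry import (
    CardSpec,
    DenseMatchParams,
    dense_match,
    detect_card,
    fit_table_plane,
    integrate_volume,
    pose_from_card,
    pose_gravity_aided,
    relative_pose_gravity_aided,
    table_normal_from_gravity,
    triangulate,
    _tilt_rotation,
)
from .nutrition import MealEstimate, assemble_meal
from .recognition import weighted_inference
from .segmentation import GrowParams, auto_segment, region_grow_merge


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, hint: str = ""):
        self.stage = stage
        self.hint = hint
        msg = f"pipeline stage '{stage}' failed: {cause}"
        if hint:
            msg += f" ({hint})"
        super().__init__(msg)


@dataclass
class PipelineConfig:
    """All pipeline defaults; overridable from YAML and CLI flags."""

    mode: str = "single_camera"        # or "stereo_rig"
    stereo_baseline_mm: float = 14.0
    use_gravity: bool = True
    card_width_mm: float = 85.60
    card_height_mm: float = 53.98
    grid_mm: float = 1.0
    match_z_max_mm: float = 60.0
    match_z_step_mm: float = 1.0
    match_window_px: int = 11
    match_lr_tolerance_px: float = 1.0
    match_pixel_step: int = 1
    seg_tau_grow: float = 14.0
    seg_tau_merge: float = 10.0
    level_weights: tuple = (0.4, 0.5, 1.0)
    fallback_threshold: float = 0.5
    keep_intermediates: bool = False

    @property
    def card(self) -> CardSpec:
        return CardSpec(self.card_width_mm, self.card_height_mm)

    @property
    def matcher(self) -> DenseMatchParams:
        return DenseMatchParams(
            z_max_mm=self.match_z_max_mm,
            z_step_mm=self.match_z_step_mm,
            window_px=self.match_window_px,
            lr_tolerance_px=self.match_lr_tolerance_px,
            pixel_step=self.match_pixel_step,
        )

    @property
    def grow_params(self) -> GrowParams:
        return GrowParams(tau_grow=self.seg_tau_grow, tau_merge=self.seg_tau_merge)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.level_weights, list):
            cfg.level_weights = tuple(cfg.level_weights)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["level_weights"] = list(d["level_weights"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PipelineResult:
    meal: MealEstimate | None
    volumes: list                      # VolumeEstimate per item
    recognitions: list                 # RecognitionScores or str per item
    pose1: RigidPose
    pose2: RigidPose
    plane: object
    segmentation: object
    timings: dict = field(default_factory=dict)
    intermediates: dict = field(default_factory=dict)


def default_taxonomy():
    from .recognition import load_taxonomy

    return load_taxonomy(
        importlib.resources.files("dietvision") / "data" / "taxonomy_demo.csv"
    )


def default_nutrient_table():
    from .nutrition import load_nutrient_table

    return load_nutrient_table(
        importlib.resources.files("dietvision") / "data" / "nutrients_demo.csv"
    )


def _masked_crop(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    r0, r1, c0, c1 = rows.min(), rows.max() + 1, cols.min(), cols.max() + 1
    crop = image[r0:r1, c0:c1].copy()
    crop[~mask[r0:r1, c0:c1]] = 0.0
    return crop


def run_pipeline(
    image1: np.ndarray,
    image2: np.ndarray,
    gravity1: GravitySample,
    gravity2: GravitySample,
    intrinsics: CameraIntrinsics,
    config: PipelineConfig | None = None,
    seeds=None,
    model=None,
    taxonomy=None,
    nutrient_table=None,
    correspondences=None,
    item_categories=None,
) -> PipelineResult:
    """Run the full chain on one two-view capture.

    Optional hooks: ``seeds`` switches segmentation to the semi-automatic
    mode; ``correspondences`` injects precomputed matches (skips dense
    matching); ``item_categories`` overrides recognition (list of category
    names per item); ``model`` + ``taxonomy`` + ``nutrient_table`` enable
    the recognition and nutrition stages.
    """
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}
    inter: dict[str, object] = {}

    def stage(name, fn, hint=""):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise PipelineStageError(name, exc, hint) from exc
        timings[name] = time.perf_counter() - t0
        return out

    # --- poses ------------------------------------------------------------
    if cfg.mode == "single_camera":
        det1 = stage(
            "card_detection_view1",
            lambda: detect_card(image1, cfg.card),
            "place the reference card fully inside both views",
        )
        det2 = stage(
            "card_detection_view2",
            lambda: detect_card(image2, cfg.card),
            "place the reference card fully inside both views",
        )
        corners_world = cfg.card.corners_local()
        if cfg.use_gravity:
            pose1 = stage(
                "pose_view1",
                lambda: pose_gravity_aided(
                    corners_world, det1.corners_px, intrinsics, gravity1
                ),
            )
            pose2 = stage(
                "pose_view2",
                lambda: relative_pose_gravity_aided(
                    pose1, gravity1, gravity2,
                    det1.corners_px, det2.corners_px, intrinsics,
                ),
            )
        else:
            pose1 = stage(
                "pose_view1", lambda: pose_from_card(det1, cfg.card, intrinsics)
            )
            pose2 = stage(
                "pose_view2", lambda: pose_from_card(det2, cfg.card, intrinsics)
            )
        inter["card_detections"] = (det1, det2)
    elif cfg.mode == "stereo_rig":
        # z up from gravity, metric scale from the known baseline, origin
        # anchored on the table via a coarse stereo sweep
        def rig_poses():
            from .geometry import estimate_table_distance

            R1 = _tilt_rotation(gravity1.g_cam)
            h = estimate_table_distance(
                image1, image2, R1, cfg.stereo_baseline_mm, intrinsics
            )
            t1 = -R1 @ np.array([0.0, 0.0, h])
            pose1 = RigidPose(R1, t1)
            pose2 = RigidPose(R1, t1 - np.array([cfg.stereo_baseline_mm, 0.0, 0.0]))
            return pose1, pose2

        pose1, pose2 = stage("rig_poses", rig_poses)
    else:
        raise ValueError(f"unknown pipeline mode '{cfg.mode}'")

    # --- segmentation ------------------------------------------------------
    if seeds is not None:
        seg = stage(
            "segmentation",
            lambda: region_grow_merge(image1, seeds, cfg.grow_params),
        )
    else:
        seg = stage("segmentation", lambda: auto_segment(image1))
    inter["segmentation"] = seg

    # --- recognition --------------------------------------------------------
    recognitions: list = []
    if item_categories is not None:
        if len(item_categories) != seg.n_items:
            raise PipelineStageError(
                "recognition",
                ValueError(
                    f"{len(item_categories)} categories for {seg.n_items} items"
                ),
            )
        recognitions = list(item_categories)
    elif model is not None:

        def recognize():
            out = []
            for i in range(1, seg.n_items + 1):
                crop = _masked_crop(image1, seg.mask(i))
                probs = model.predict_proba(crop[None])
                out.append(
                    weighted_inference(
                        [p[0] for p in probs],
                        cfg.level_weights,
                        cfg.fallback_threshold,
                        taxonomy=taxonomy,
                    )
                )
            return out

        recognitions = stage("recognition", recognize)

    # --- matching + reconstruction -----------------------------------------
    if correspondences is None:
        correspondences = stage(
            "dense_matching",
            lambda: dense_match(
                image1, image2, pose1, pose2, intrinsics, cfg.matcher
            ),
            "check that both images are textured and metrically posed",
        )
    inter["correspondences"] = correspondences
    cloud = stage(
        "triangulation",
        lambda: triangulate(
            correspondences.pixels_a, correspondences.pixels_b,
            pose1, pose2, intrinsics,
        ),
    )
    inter["point_cloud"] = cloud

    def plane_fit():
        n_cam = table_normal_from_gravity(gravity1)
        n_world = pose1.rotation.T @ n_cam
        n_world = n_world / np.linalg.norm(n_world)
        if n_world[2] < 0:
            n_world = -n_world
        return fit_table_plane(cloud, n_world, seg.labels == 0)

    plane = stage("table_plane", plane_fit, "needs enough background in view 1")

    volumes = stage(
        "volume_integration",
        lambda: [
            integrate_volume(cloud, plane, seg.mask(i), cfg.grid_mm, item_id=i)
            for i in range(1, seg.n_items + 1)
        ],
    )

    # --- nutrients ----------------------------------------------------------
    meal = None
    if recognitions and nutrient_table is not None:
        meal = stage(
            "nutrition",
            lambda: assemble_meal(
                list(zip(recognitions, volumes)), nutrient_table, taxonomy
            ),
        )

    return PipelineResult(
        meal=meal,
        volumes=volumes,
        recognitions=recognitions,
        pose1=pose1,
        pose2=pose2,
        plane=plane,
        segmentation=seg,
        timings=timings,
        intermediates=inter if cfg.keep_intermediates else {},
    )
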
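"""Synthetic two-view meal scenes with exact analytic ground truth.

The renderer ray-casts parametric solids (spherical cap, cylinder, cuboid,
half-ellipsoid) standing on a textured table plane carrying a reference
card. Every pixel stores its exact 3-D hit point, so ground-truth masks,
depth, and two-view correspondences are available to machine precision —
the downstream geometry can be tested with no external data.

World frame: table plane is z = 0, z up, millimetres; the card sits at the
origin and defines the x-axis. Volumes are reported in ml (1000 mm^3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .camera import (
    CameraIntrinsics,
    GravitySample,
    RigidPose,
    look_at_pose,
    pixel_rays,
    project_points,
)
from .geometry import CardSpec
from .segmentation import SegmentationMap
from .textures import ProceduralTexture, class_base_color

_EPS = 1e-9

# dark orientation mark printed on the card, offsets from corner 0 in the
# card frame (mm); placed off the card's diagonal so it breaks both the
# 180-degree and the mirror labelling ambiguities
CARD_MARK_OFFSET = (22.0, 8.0)
CARD_MARK_RADIUS = 4.5

SHAPE_KINDS = ("spherical_cap", "cylinder", "cuboid", "half_ellipsoid")


class SceneSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FoodSolid:
    """A parametric solid standing on the table plane (all lengths mm)."""

    shape_kind: str
    shape_params: dict
    base_center: tuple = (0.0, 0.0)
    texture_id: int = 0
    label: str = "food"

    def validate(self) -> None:
        if self.shape_kind not in SHAPE_KINDS:
            raise SceneSpecError(
                f"solid '{self.label}': unknown shape kind '{self.shape_kind}'"
            )
        for key, val in self.shape_params.items():
            if not np.isfinite(val) or val <= 0:
                raise SceneSpecError(
                    f"solid '{self.label}': parameter '{key}' must be positive, got {val}"
                )
        p = self.shape_params
        if self.shape_kind == "spherical_cap":
            if p["height"] > p["sphere_radius"] + _EPS:
                raise SceneSpecError(
                    f"solid '{self.label}': cap height exceeds sphere radius"
                )

    @property
    def analytic_volume_mm3(self) -> float:
        p = self.shape_params
        if self.shape_kind == "spherical_cap":
            R, h = p["sphere_radius"], p["height"]
            return np.pi * h * h * (3.0 * R - h) / 3.0
        if self.shape_kind == "cylinder":
            return np.pi * p["radius"] ** 2 * p["height"]
        if self.shape_kind == "cuboid":
            return p["size_x"] * p["size_y"] * p["size_z"]
        if self.shape_kind == "half_ellipsoid":
            return 2.0 / 3.0 * np.pi * p["semi_x"] * p["semi_y"] * p["semi_z"]
        raise SceneSpecError(self.shape_kind)

    @property
    def analytic_volume_ml(self) -> float:
        return self.analytic_volume_mm3 / 1000.0

    @property
    def max_height(self) -> float:
        p = self.shape_params
        return {
            "spherical_cap": lambda: p["height"],
            "cylinder": lambda: p["height"],
            "cuboid": lambda: p["size_z"],
            "half_ellipsoid": lambda: p["semi_z"],
        }[self.shape_kind]()

    @property
    def footprint_radius(self) -> float:
        p = self.shape_params
        if self.shape_kind == "spherical_cap":
            R, h = p["sphere_radius"], p["height"]
            return float(np.sqrt(max(2.0 * R * h - h * h, 0.0)))
        if self.shape_kind == "cylinder":
            return p["radius"]
        if self.shape_kind == "cuboid":
            return float(np.hypot(p["size_x"], p["size_y"]) / 2.0)
        return float(max(p["semi_x"], p["semi_y"]))

    def height_at(self, x, y):
        """Analytic surface height above the table (0 outside the footprint)."""
        x = np.asarray(x, dtype=float) - self.base_center[0]
        y = np.asarray(y, dtype=float) - self.base_center[1]
        p = self.shape_params
        if self.shape_kind == "spherical_cap":
            R, h = p["sphere_radius"], p["height"]
            rho2 = x * x + y * y
            z = np.sqrt(np.maximum(R * R - rho2, 0.0)) + (h - R)
            return np.maximum(z, 0.0)
        if self.shape_kind == "cylinder":
            inside = x * x + y * y <= p["radius"] ** 2
            return np.where(inside, p["height"], 0.0)
        if self.shape_kind == "cuboid":
            inside = (np.abs(x) <= p["size_x"] / 2.0) & (np.abs(y) <= p["size_y"] / 2.0)
            return np.where(inside, p["size_z"], 0.0)
        a, b, c = p["semi_x"], p["semi_y"], p["semi_z"]
        q = 1.0 - (x / a) ** 2 - (y / b) ** 2
        return c * np.sqrt(np.maximum(q, 0.0))

    def intersect(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Smallest positive ray parameter t hitting the solid (inf = miss)."""
        o = np.asarray(origin, dtype=float)
        d = np.asarray(dirs, dtype=float)
        cx, cy = self.base_center
        p = self.shape_params
        if self.shape_kind == "spherical_cap":
            R, h = p["sphere_radius"], p["height"]
            center = np.array([cx, cy, h - R])
            return _ray_sphere_band(o, d, center, R, 0.0, h)
        if self.shape_kind == "cylinder":
            return _ray_cylinder(o, d, cx, cy, p["radius"], p["height"])
        if self.shape_kind == "cuboid":
            lo = np.array([cx - p["size_x"] / 2.0, cy - p["size_y"] / 2.0, 0.0])
            hi = np.array([cx + p["size_x"] / 2.0, cy + p["size_y"] / 2.0, p["size_z"]])
            return _ray_box(o, d, lo, hi)
        s = np.array([p["semi_x"], p["semi_y"], p["semi_z"]])
        return _ray_half_ellipsoid(o, d, np.array([cx, cy, 0.0]), s)


def _pick_min_root(roots, valid):
    t = np.where(valid, roots, np.inf)
    return t.min(axis=0)


def _ray_sphere_band(o, d, center, R, z_lo, z_hi):
    oc = o[None, :] - center[None, :]
    b = np.sum(oc * d, axis=1)
    c = np.sum(oc * oc, axis=1) - R * R
    disc = b * b - c
    ok = disc >= 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    roots = np.stack([-b - sq, -b + sq])
    z = o[2] + roots * d[:, 2]
    valid = ok[None, :] & (roots > _EPS) & (z >= z_lo - 1e-7) & (z <= z_hi + 1e-7)
    return _pick_min_root(roots, valid)


def _ray_cylinder(o, d, cx, cy, r, h):
    ox, oy = o[0] - cx, o[1] - cy
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = ox * d[:, 0] + oy * d[:, 1]
    c = ox * ox + oy * oy - r * r
    disc = b * b - a * c
    ok = (disc >= 0) & (a > _EPS)
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        roots = np.stack([(-b - sq) / a, (-b + sq) / a])
    z = o[2] + roots * d[:, 2]
    valid = ok[None, :] & (roots > _EPS) & (z >= -1e-7) & (z <= h + 1e-7)
    t_side = _pick_min_root(roots, valid)
    # top disk
    with np.errstate(divide="ignore", invalid="ignore"):
        t_top = (h - o[2]) / d[:, 2]
    x = o[0] + t_top * d[:, 0] - cx
    y = o[1] + t_top * d[:, 1] - cy
    top_ok = (np.abs(d[:, 2]) > _EPS) & (t_top > _EPS) & (x * x + y * y <= r * r)
    t_top = np.where(top_ok, t_top, np.inf)
    return np.minimum(t_side, t_top)


def _ray_box(o, d, lo, hi):
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
    t1 = (lo[None, :] - o[None, :]) * inv
    t2 = (hi[None, :] - o[None, :]) * inv
    # d == 0 handled: inv = +-inf gives correct +-inf slabs unless origin on
    # the boundary (never the case for a camera above the table)
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = (tmax >= tmin) & (tmax > _EPS)
    t = np.where(tmin > _EPS, tmin, tmax)
    return np.where(hit, t, np.inf)


def _ray_half_ellipsoid(o, d, center, semi):
    op = (o[None, :] - center[None, :]) / semi[None, :]
    dp = d / semi[None, :]
    a = np.sum(dp * dp, axis=1)
    b = np.sum(op * dp, axis=1)
    c = np.sum(op * op, axis=1) - 1.0
    disc = b * b - a * c
    ok = disc >= 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        roots = np.stack([(-b - sq) / a, (-b + sq) / a])
    z = o[2] + roots * d[:, 2]
    valid = ok[None, :] & (roots > _EPS) & (z >= -1e-7)
    return _pick_min_root(roots, valid)


@dataclass(frozen=True)
class ViewSpec:
    """One camera placement.

    ``rig_offset_mm`` shifts the camera center along its own +x axis while
    keeping the rotation — two ViewSpecs differing only in the offset form a
    stereo rig with that baseline.
    """

    elevation_deg: float = 90.0
    azimuth_deg: float = 0.0
    distance_mm: float = 400.0
    target: tuple = (0.0, 0.0, 0.0)
    rig_offset_mm: float = 0.0


def default_intrinsics(width: int = 320, height: int = 240) -> CameraIntrinsics:
    # ~61 deg horizontal FOV: wide enough that a whole place setting fits
    # in the frame at the default 400 mm capture distance
    return CameraIntrinsics(
        fx=0.85 * width, fy=0.85 * width,
        cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
        width=width, height=height,
    )


@dataclass(frozen=True)
class SceneSpec:
    solids: tuple
    views: tuple = (ViewSpec(90.0), ViewSpec(75.0))
    intrinsics: CameraIntrinsics = field(default_factory=default_intrinsics)
    card: CardSpec = field(default_factory=CardSpec)
    card_center: tuple = (0.0, 0.0)
    card_angle_deg: float = 0.0
    noise_sigma: float = 0.0
    table_half_extent: float = 400.0
    table_texture_id: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["solids"] = [asdict(s) for s in self.solids]
        d["views"] = [asdict(v) for v in self.views]
        d["intrinsics"] = asdict(self.intrinsics)
        d["card"] = asdict(self.card)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            solids=tuple(FoodSolid(**s) for s in d["solids"]),
            views=tuple(ViewSpec(**{**v, "target": tuple(v["target"])}) for v in d["views"]),
            intrinsics=CameraIntrinsics(**d["intrinsics"]),
            card=CardSpec(**d["card"]),
            card_center=tuple(d["card_center"]),
            card_angle_deg=d["card_angle_deg"],
            noise_sigma=d["noise_sigma"],
            table_half_extent=d["table_half_extent"],
            table_texture_id=d["table_texture_id"],
        )


@dataclass
class SceneView:
    intrinsics: CameraIntrinsics
    pose: RigidPose
    gravity: GravitySample
    image: np.ndarray           # (H, W, 3) float in [0, 1]
    labels: SegmentationMap     # 0 background (incl. card), 1..N solids
    card_mask: np.ndarray       # (H, W) bool
    world_points: np.ndarray    # (H, W, 3) exact hit points, NaN where no hit
    hit_t: np.ndarray           # (H, W) ray parameter (mm), inf where no hit


@dataclass
class SyntheticScene:
    spec: SceneSpec
    seed: int
    views: list
    card_corners_world: np.ndarray  # (4, 3), z = 0

    @property
    def solids(self):
        return self.spec.solids

    @property
    def analytic_volumes_ml(self):
        return [s.analytic_volume_ml for s in self.spec.solids]


def view_pose(view: ViewSpec) -> RigidPose:
    e = np.deg2rad(view.elevation_deg)
    a = np.deg2rad(view.azimuth_deg)
    tgt = np.asarray(view.target, dtype=float)
    center = tgt + view.distance_mm * np.array(
        [np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e)]
    )
    if center[2] <= 0:
        raise SceneSpecError(
            f"degenerate view: camera below the table plane (elevation {view.elevation_deg} deg)"
        )
    pose = look_at_pose(center, tgt)
    if view.rig_offset_mm:
        center = center + view.rig_offset_mm * pose.rotation[0]
        pose = RigidPose(pose.rotation, -pose.rotation @ center)
    return pose


def card_corners_world(spec: SceneSpec) -> np.ndarray:
    """Ordered card corners on the table plane (corner 0 carries the mark)."""
    w, h = spec.card.width_mm / 2.0, spec.card.height_mm / 2.0
    corners = np.array([[-w, -h], [w, -h], [w, h], [-w, h]])
    ang = np.deg2rad(spec.card_angle_deg)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    xy = corners @ R.T + np.asarray(spec.card_center)
    return np.hstack([xy, np.zeros((4, 1))])


def _card_frame_coords(spec: SceneSpec, x, y):
    ang = np.deg2rad(spec.card_angle_deg)
    dx = x - spec.card_center[0]
    dy = y - spec.card_center[1]
    u = np.cos(ang) * dx + np.sin(ang) * dy
    v = -np.sin(ang) * dx + np.cos(ang) * dy
    return u, v


def _cast_scene(spec: SceneSpec, origin: np.ndarray, dirs: np.ndarray):
    """Nearest hit over table + solids. Returns (t, label); label -1 = none,
    0 = table, 1..N = solid index."""
    n = len(dirs)
    best_t = np.full(n, np.inf)
    label = np.full(n, -1, dtype=np.int32)
    # table plane z = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_pl = -origin[2] / dirs[:, 2]
    x = origin[0] + t_pl * dirs[:, 0]
    y = origin[1] + t_pl * dirs[:, 1]
    ok = (
        (np.abs(dirs[:, 2]) > _EPS)
        & (t_pl > _EPS)
        & (np.abs(x) <= spec.table_half_extent)
        & (np.abs(y) <= spec.table_half_extent)
    )
    best_t = np.where(ok, t_pl, best_t)
    label = np.where(ok, 0, label)
    for i, solid in enumerate(spec.solids, start=1):
        t = solid.intersect(origin, dirs)
        closer = t < best_t
        best_t = np.where(closer, t, best_t)
        label = np.where(closer, i, label)
    return best_t, label


_SKY_RGB = np.array([0.06, 0.06, 0.08])


def _scene_textures(spec: SceneSpec):
    table = ProceduralTexture(
        1000 + spec.table_texture_id, [0.40, 0.34, 0.27], amplitude=0.13
    )
    card = ProceduralTexture(2000, [0.94, 0.94, 0.91], amplitude=0.025)
    solids = [
        ProceduralTexture(s.texture_id, class_base_color(s.texture_id), amplitude=0.15)
        for s in spec.solids
    ]
    return table, card, solids


def _render_view(spec: SceneSpec, pose: RigidPose, rng: np.random.Generator) -> SceneView:
    K = spec.intrinsics
    H, W = K.height, K.width
    uu, vv = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    pix = np.stack([uu.ravel(), vv.ravel()], axis=1)
    origin, dirs = pixel_rays(K, pose, pix)
    t, label = _cast_scene(spec, origin, dirs)
    pts = origin[None, :] + t[:, None] * dirs
    pts[~np.isfinite(t)] = np.nan

    tex_table, tex_card, tex_solids = _scene_textures(spec)
    rgb = np.tile(_SKY_RGB, (len(pix), 1))
    on_table = label == 0
    if on_table.any():
        rgb[on_table] = tex_table(pts[on_table, 0], pts[on_table, 1])
    # card overlay (flat on the plane)
    u, v = _card_frame_coords(spec, pts[:, 0], pts[:, 1])
    w2, h2 = spec.card.width_mm / 2.0, spec.card.height_mm / 2.0
    on_card = on_table & (np.abs(u) <= w2) & (np.abs(v) <= h2)
    if on_card.any():
        rgb[on_card] = tex_card(pts[on_card, 0], pts[on_card, 1])
        mx = -w2 + CARD_MARK_OFFSET[0]
        my = -h2 + CARD_MARK_OFFSET[1]
        on_mark = on_card & ((u - mx) ** 2 + (v - my) ** 2 <= CARD_MARK_RADIUS**2)
        rgb[on_mark] = np.array([0.08, 0.08, 0.10])
    for i in range(1, len(spec.solids) + 1):
        sel = label == i
        if sel.any():
            # shear the texture coordinates with height so vertical faces
            # also carry contrast
            x = pts[sel, 0] + 0.5 * pts[sel, 2]
            y = pts[sel, 1] - 0.5 * pts[sel, 2]
            rgb[sel] = tex_solids[i - 1](x, y)

    img = rgb.reshape(H, W, 3)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SceneView(
        intrinsics=K,
        pose=pose,
        gravity=pose.gravity_in_camera(),
        image=img,
        labels=SegmentationMap(np.maximum(label, 0).reshape(H, W)),
        card_mask=on_card.reshape(H, W),
        world_points=pts.reshape(H, W, 3),
        hit_t=t.reshape(H, W),
    )


def _validate_spec(spec: SceneSpec) -> None:
    if len(spec.solids) < 1:
        raise SceneSpecError("a scene needs at least one solid")
    if len(spec.views) < 2:
        raise SceneSpecError("a scene needs at least two views")
    for s in spec.solids:
        s.validate()
    # solids must stay clear of the card (mask/card consistency invariant)
    w2, h2 = spec.card.width_mm / 2.0, spec.card.height_mm / 2.0
    for s in spec.solids:
        u, v = _card_frame_coords(
            spec, np.array(s.base_center[0]), np.array(s.base_center[1])
        )
        du = max(abs(float(u)) - w2, 0.0)
        dv = max(abs(float(v)) - h2, 0.0)
        if np.hypot(du, dv) < s.footprint_radius + 2.0:
            raise SceneSpecError(
                f"solid '{s.label}' overlaps the reference card footprint"
            )


def make_scene(spec: SceneSpec, seed: int) -> SyntheticScene:
    """Render a fully ground-truthed scene (deterministic in ``seed``)."""
    _validate_spec(spec)
    rng = np.random.default_rng(seed)
    views = []
    corners = card_corners_world(spec)
    for vs in spec.views:
        pose = view_pose(vs)
        view = _render_view(spec, pose, rng)
        for i, s in enumerate(spec.solids, start=1):
            if not (view.labels.labels == i).any():
                raise SceneSpecError(
                    f"solid '{s.label}' is not visible in view at "
                    f"elevation {vs.elevation_deg} deg"
                )
        pix, z = project_points(spec.intrinsics, pose, corners)
        if (z <= 0).any() or (pix < -0.5).any() or (
            pix[:, 0] > spec.intrinsics.width - 0.5
        ).any() or (pix[:, 1] > spec.intrinsics.height - 0.5).any():
            raise SceneSpecError("reference card is not fully visible in a view")
        views.append(view)
    return SyntheticScene(spec=spec, seed=seed, views=views, card_corners_world=corners)


@dataclass
class Correspondences:
    """Exact pixel correspondences between two views of a scene."""

    pixels_a: np.ndarray  # (N, 2) float pixel centers in view a
    pixels_b: np.ndarray  # (N, 2) float sub-pixel positions in view b
    world: np.ndarray     # (N, 3) ground-truth 3-D points
    labels: np.ndarray    # (N,) 0 = table, 1..N = solid
    scores: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.pixels_a)


def exact_correspondences(
    scene: SyntheticScene, view_a: int = 1, view_b: int = 0, stride: int = 1
) -> Correspondences:
    """Ground-truth matches: pixels of ``view_a`` visible in ``view_b``.

    Visibility is decided by re-casting a ray from view b's center to the
    candidate point (an exact z-buffer test).
    """
    va, vb = scene.views[view_a], scene.views[view_b]
    K = va.intrinsics
    H, W = K.height, K.width
    lab = va.labels.labels
    uu, vv = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    sel = np.isfinite(va.hit_t)
    if stride > 1:
        keep = np.zeros_like(sel)
        keep[::stride, ::stride] = True
        sel &= keep
    pts = va.world_points[sel]
    pix_a = np.stack([uu[sel], vv[sel]], axis=1)
    labels = lab[sel]

    pix_b, depth = project_points(vb.intrinsics, vb.pose, pts)
    inb = (
        (depth > 0)
        & (pix_b[:, 0] >= -0.5) & (pix_b[:, 0] <= W - 0.5)
        & (pix_b[:, 1] >= -0.5) & (pix_b[:, 1] <= H - 0.5)
    )
    pts, pix_a, pix_b, labels = pts[inb], pix_a[inb], pix_b[inb], labels[inb]
    cb = vb.pose.camera_center
    diff = pts - cb
    dist = np.linalg.norm(diff, axis=1)
    dirs = diff / dist[:, None]
    t, _ = _cast_scene(scene.spec, cb, dirs)
    visible = np.abs(t - dist) <= 0.1  # mm
    return Correspondences(
        pixels_a=pix_a[visible],
        pixels_b=pix_b[visible],
        world=pts[visible],
        labels=labels[visible],
    )


def render_view(scene: SyntheticScene, view_index: int):
    """(image, ground-truth SegmentationMap, correspondences to view 0)."""
    if not 0 <= view_index < len(scene.views):
        raise IndexError(f"view index {view_index} out of range")
    view = scene.views[view_index]
    corr = exact_correspondences(scene, view_index, 0)
    return view.image, view.labels, corr


# ---------------------------------------------------------------------------
# default scene sampling


def _solid_fully_visible(
    solid: FoodSolid, poses, K: CameraIntrinsics, margin_px: float = 4.0
) -> bool:
    """Does the solid's bounding cylinder project inside every view?"""
    ang = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    r = solid.footprint_radius + 1.0
    cx, cy = solid.base_center
    ring = np.stack([cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=1)
    pts = np.vstack(
        [
            np.hstack([ring, np.zeros((len(ring), 1))]),
            np.hstack([ring, np.full((len(ring), 1), solid.max_height)]),
        ]
    )
    for pose in poses:
        pix, z = project_points(K, pose, pts)
        if (z <= 0).any():
            return False
        if (
            (pix[:, 0] < margin_px).any()
            or (pix[:, 0] > K.width - 1 - margin_px).any()
            or (pix[:, 1] < margin_px).any()
            or (pix[:, 1] > K.height - 1 - margin_px).any()
        ):
            return False
    return True


def default_solids(
    n: int,
    rng: np.random.Generator,
    taxonomy_size: int = 12,
    poses=None,
    intrinsics: CameraIntrinsics | None = None,
    card: CardSpec | None = None,
):
    """Place n random solids on the table, clear of the card, of each other,
    and (when poses are given) fully visible in every view."""
    solids = []
    occupied = []
    card = card if card is not None else CardSpec()
    cw, ch = card.width_mm / 2.0, card.height_mm / 2.0
    kinds = list(SHAPE_KINDS)
    for i in range(n):
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "spherical_cap":
            R = float(rng.uniform(35.0, 55.0))
            h = float(rng.uniform(0.4, 0.7)) * R
            params = {"sphere_radius": R, "height": h}
        elif kind == "cylinder":
            params = {
                "radius": float(rng.uniform(22.0, 35.0)),
                "height": float(rng.uniform(15.0, 38.0)),
            }
        elif kind == "cuboid":
            params = {
                "size_x": float(rng.uniform(35.0, 65.0)),
                "size_y": float(rng.uniform(35.0, 65.0)),
                "size_z": float(rng.uniform(15.0, 35.0)),
            }
        else:
            params = {
                "semi_x": float(rng.uniform(25.0, 42.0)),
                "semi_y": float(rng.uniform(25.0, 42.0)),
                "semi_z": float(rng.uniform(15.0, 32.0)),
            }
        tex = int(rng.integers(taxonomy_size))
        probe = FoodSolid(kind, params, (0.0, 0.0), tex, f"item_{i}")
        r = probe.footprint_radius
        placed = None
        for _ in range(300):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(60.0 + r, 160.0)
            c = (float(rad * np.cos(ang)), float(rad * np.sin(ang)))
            # clearance from the card rectangle
            du = max(abs(c[0]) - cw, 0.0)
            dv = max(abs(c[1]) - ch, 0.0)
            if np.hypot(du, dv) < r + 4.0:
                continue
            if any(
                np.hypot(c[0] - oc[0], c[1] - oc[1]) < r + orad + 5.0
                for oc, orad in occupied
            ):
                continue
            candidate = FoodSolid(kind, params, c, tex, f"item_{i}")
            if poses is not None and intrinsics is not None:
                if not _solid_fully_visible(candidate, poses, intrinsics):
                    continue
            placed = candidate
            break
        if placed is None:
            continue
        occupied.append((placed.base_center, r))
        solids.append(placed)
    if not solids:
        raise SceneSpecError("could not place any solid")
    return tuple(solids)


def sample_scene_spec(
    rng: np.random.Generator,
    n_solids: int | None = None,
    views: Sequence[ViewSpec] | None = None,
    noise_sigma: float = 0.0,
    image_width: int = 320,
    image_height: int = 240,
) -> SceneSpec:
    n = int(rng.integers(1, 4)) if n_solids is None else n_solids
    view_tuple = tuple(views) if views is not None else (ViewSpec(90.0), ViewSpec(75.0))
    K = default_intrinsics(image_width, image_height)
    poses = [view_pose(v) for v in view_tuple]
    return SceneSpec(
        solids=default_solids(n, rng, poses=poses, intrinsics=K),
        views=view_tuple,
        intrinsics=K,
        noise_sigma=noise_sigma,
        table_texture_id=int(rng.integers(100)),
        # slanted card edges dither across the pixel grid, which is what
        # gives the corner refinement its sub-pixel accuracy
        card_angle_deg=float(rng.uniform(10.0, 80.0)),
    )


# ---------------------------------------------------------------------------
# serialization


def save_scene(scene: SyntheticScene, directory) -> None:
    """Write PNG images, 16-bit label masks and a JSON sidecar."""
    import imageio.v3 as iio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "spec": scene.spec.to_dict(),
        "seed": scene.seed,
        "card_corners_world": scene.card_corners_world.tolist(),
        "analytic_volumes_ml": scene.analytic_volumes_ml,
        "views": [],
    }
    for i, v in enumerate(scene.views):
        iio.imwrite(d / f"view{i}.png", (v.image * 255).round().astype(np.uint8))
        iio.imwrite(d / f"view{i}_labels.png", v.labels.labels.astype(np.uint16))
        iio.imwrite(d / f"view{i}_card.png", v.card_mask.astype(np.uint16) * 65535)
        sidecar["views"].append(
            {
                "intrinsics": asdict(v.intrinsics),
                "rotation": v.pose.rotation.tolist(),
                "translation": v.pose.translation.tolist(),
                "gravity": v.gravity.g_cam.tolist(),
            }
        )
    (d / "scene.json").write_text(json.dumps(sidecar, indent=2))


def load_scene(directory) -> SyntheticScene:
    """Rebuild a scene from :func:`save_scene` output.

    Geometry and ground truth are regenerated from the stored spec + seed
    (the generator is deterministic); images are taken from the PNGs.
    """
    import imageio.v3 as iio

    d = Path(directory)
    sidecar = json.loads((d / "scene.json").read_text())
    spec = SceneSpec.from_dict(sidecar["spec"])
    scene = make_scene(spec, int(sidecar["seed"]))
    for i, v in enumerate(scene.views):
        v.image = iio.imread(d / f"view{i}.png").astype(float) / 255.0
    return scene


# ---------------------------------------------------------------------------
# classification imagery


@dataclass
class ClassificationSet:
    """Labelled texture patches, one colour/texture family per fine class."""

    images: np.ndarray        # (N, H, W, 3)
    fine_idx: np.ndarray      # (N,) index into taxonomy.fine_names
    hyper2_idx: np.ndarray
    hyper1_idx: np.ndarray
    label_paths: list         # (hyper1, hyper2, fine) name tuples
    taxonomy: object

    def __len__(self) -> int:
        return len(self.images)


def make_classification_set(
    taxonomy,
    n_per_class: int,
    seed: int,
    image_size: int = 24,
    noise_sigma: float = 0.02,
) -> ClassificationSet:
    """Seeded, separable image set labelled with full three-level paths."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    n_fine = len(taxonomy.fine_names)
    if n_fine < 2:
        raise ValueError("taxonomy needs at least 2 fine-grained classes")
    rng = np.random.default_rng(seed)
    s = image_size
    mm = 2.0  # pretend pixels are 2 mm so texture wavelengths fit
    grid = np.arange(s, dtype=float) * mm
    gx, gy = np.meshgrid(grid, grid)
    images, fine_idx = [], []
    for k, fine in enumerate(taxonomy.fine_names):
        # same per-class texture family the scene renderer uses, so a model
        # trained here transfers to rendered meal crops
        tex = ProceduralTexture(
            k, class_base_color(k, max(16, n_fine)), amplitude=0.15
        )
        for _ in range(n_per_class):
            ox, oy = rng.uniform(0.0, 200.0, 2)
            img = tex(gx + ox, gy + oy)
            img = img * rng.uniform(0.92, 1.08)
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            fine_idx.append(k)
    fine_idx = np.array(fine_idx)
    h2 = np.array([taxonomy.hyper2_index_of_fine(i) for i in fine_idx])
    h1 = np.array([taxonomy.hyper1_index_of_fine(i) for i in fine_idx])
    paths = [taxonomy.path(int(i)) for i in fine_idx]
    return ClassificationSet(
        images=np.stack(images),
        fine_idx=fine_idx,
        hyper2_idx=h2,
        hyper1_idx=h1,
        label_paths=paths,
        taxonomy=taxonomy,
    )
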
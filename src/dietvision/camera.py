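"""Pinhole camera model, rigid poses and gravity samples.

Conventions (fixed so tests can be bit-exact):

* image origin at the top-left, pixel centers on integer coordinates;
* world frame: table plane is ``z = 0`` with z pointing up, millimetres;
* :class:`RigidPose` maps world points into the camera frame,
  ``x_cam = R @ x_world + t``;
* the camera looks along its +z axis, +x right, +y down (image row
  direction);
* gravity in the world frame is the unit vector ``(0, 0, -1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WORLD_DOWN = np.array([0.0, 0.0, -1.0])
WORLD_UP = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def K_inv(self) -> np.ndarray:
        return np.array(
            [
                [1.0 / self.fx, 0.0, -self.cx / self.fx],
                [0.0, 1.0 / self.fy, -self.cy / self.fy],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass(frozen=True)
class RigidPose:
    """World-to-camera rigid transform, translation in millimetres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation is not orthonormal (RR^T != I within 1e-9)")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must have determinant +1")

    @property
    def camera_center(self) -> np.ndarray:
        """Camera center expressed in world coordinates."""
        return -self.rotation.T @ self.translation

    @property
    def matrix(self) -> np.ndarray:
        """3x4 matrix ``[R | t]``."""
        return np.hstack([self.rotation, self.translation[:, None]])

    def transform(self, points_world: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_world, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse_transform(self, points_cam: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_cam, dtype=float))
        return (pts - self.translation) @ self.rotation

    def gravity_in_camera(self) -> "GravitySample":
        return GravitySample(self.rotation @ WORLD_DOWN)


@dataclass(frozen=True)
class GravitySample:
    """Direction of gravity expressed in the camera frame (unit norm)."""

    g_cam: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        g = np.asarray(self.g_cam, dtype=float).reshape(3)
        norm = np.linalg.norm(g)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError("gravity vector must be a non-zero finite 3-vector")
        object.__setattr__(self, "g_cam", g / norm)


def look_at_pose(camera_center, target, roll_reference=WORLD_UP) -> RigidPose:
    """Pose of a camera at ``camera_center`` looking at ``target``.

    The camera's +y (image down) is aligned as closely as possible with the
    world down direction, which is the natural orientation of a handheld
    phone photographing a table.
    """
    c = np.asarray(camera_center, dtype=float)
    tgt = np.asarray(target, dtype=float)
    forward = tgt - c
    norm = np.linalg.norm(forward)
    if norm < 1e-12:
        raise ValueError("camera center and target coincide")
    forward = forward / norm
    # right = forward x up (up = world +z); degenerate when looking straight
    # down/up, fall back to world +x.
    right = np.cross(forward, np.asarray(roll_reference, dtype=float))
    if np.linalg.norm(right) < 1e-9:
        right = np.array([1.0, 0.0, 0.0])
    right = right / np.linalg.norm(right)
    down = np.cross(forward, right)
    down = down / np.linalg.norm(down)
    R = np.stack([right, down, forward])  # rows: camera axes in world coords
    t = -R @ c
    return RigidPose(R, t)


def project_points(K: CameraIntrinsics, pose: RigidPose, points_world: np.ndarray):
    """Project world points; returns (pixels (N,2), depth (N,))."""
    cam = pose.transform(points_world)
    z = cam[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = K.fx * cam[:, 0] / z + K.cx
        v = K.fy * cam[:, 1] / z + K.cy
    return np.stack([u, v], axis=1), z


def pixel_rays(K: CameraIntrinsics, pose: RigidPose, pixels: np.ndarray):
    """World-frame unit rays through pixel centers.

    Returns (origin (3,), directions (N,3)).
    """
    pix = np.atleast_2d(np.asarray(pixels, dtype=float))
    d_cam = np.stack(
        [
            (pix[:, 0] - K.cx) / K.fx,
            (pix[:, 1] - K.cy) / K.fy,
            np.ones(len(pix)),
        ],
        axis=1,
    )
    d_world = d_cam @ pose.rotation  # R^T applied to rows
    d_world = d_world / np.linalg.norm(d_world, axis=1, keepdims=True)
    return pose.camera_center, d_world


def intersect_rays_plane(origin, dirs, normal, offset):
    """Intersect rays ``origin + t*dir`` with the plane ``n . x = offset``.

    Returns (points (N,3), t (N,)); ``t`` is ``inf`` for rays parallel to
    the plane.
    """
    o = np.asarray(origin, dtype=float).reshape(3)
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    n = np.asarray(normal, dtype=float).reshape(3)
    denom = d @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (offset - o @ n) / denom
    t = np.where(np.abs(denom) < 1e-12, np.inf, t)
    with np.errstate(invalid="ignore"):
        pts = o[None, :] + t[:, None] * d
    return pts, t
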
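"""Metric two-view geometry: card pose, gravity constraints, matching,
triangulation, table-plane fitting and food-volume integration.

The metric anchor is a credit-card-sized reference object lying on the
table; gravity samples from the phone's IMU fix the table-plane normal and
the tilt component of the inter-view rotation, leaving only a 1-DoF yaw
plus translation to estimate from correspondences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .camera import (
    WORLD_DOWN,
    CameraIntrinsics,
    GravitySample,
    RigidPose,
    intersect_rays_plane,
    pixel_rays,
    project_points,
)

# ---------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class CardSpec:
    """Physical reference-card size (ISO/IEC 7810 ID-1 by default)."""

    width_mm: float = 85.60
    height_mm: float = 53.98

    def corners_local(self) -> np.ndarray:
        """Card-frame corners on z=0, centered, corner 0 = marked corner."""
        w, h = self.width_mm / 2.0, self.height_mm / 2.0
        return np.array(
            [[-w, -h, 0.0], [w, -h, 0.0], [w, h, 0.0], [-w, h, 0.0]]
        )


@dataclass(frozen=True)
class CardDetection:
    """Sub-pixel card corners in canonical order (marked corner first,
    then following the card's long edge)."""

    corners_px: np.ndarray  # (4, 2)
    confidence: float

    def __post_init__(self) -> None:
        c = np.asarray(self.corners_px, dtype=float).reshape(4, 2)
        object.__setattr__(self, "corners_px", c)
        if abs(_polygon_area(c)) < 1e-9:
            raise ValueError("card corners are collinear")
        # convexity: all cross products of consecutive edges share a sign
        e = np.roll(c, -1, axis=0) - c
        cross = e[:, 0] * np.roll(e, -1, axis=0)[:, 1] - e[:, 1] * np.roll(e, -1, axis=0)[:, 0]
        if not ((cross > 0).all() or (cross < 0).all()):
            raise ValueError("card corners must form a convex quadrilateral")


class CardNotFoundError(RuntimeError):
    """No plausible card quadrilateral in the image (absence, not low
    confidence)."""


@dataclass(frozen=True)
class PlaneModel:
    """Plane {x : n . x = d}; frame is whatever the inputs were in."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-8:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)

    def height(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.normal - self.offset


@dataclass
class PointCloud:
    """Triangulated points (mm) with per-point provenance."""

    points: np.ndarray          # (N, 3)
    source_pixels: np.ndarray   # (N, 2) pixel in view 0 / view a
    residuals: np.ndarray       # (N,) mean reprojection error, px

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.source_pixels = np.atleast_2d(np.asarray(self.source_pixels, dtype=float))
        self.residuals = np.asarray(self.residuals, dtype=float).reshape(-1)
        if not np.isfinite(self.points).all():
            raise ValueError("point cloud contains non-finite coordinates")
        if (self.residuals < 0).any():
            raise ValueError("reprojection residuals must be >= 0")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class VolumeEstimate:
    item_id: int
    volume_ml: float
    footprint_area_mm2: float
    grid_resolution_mm: float

    def __post_init__(self) -> None:
        if self.volume_ml < 0:
            raise ValueError("volume must be >= 0")


class GeometryError(RuntimeError):
    pass


class InsufficientCoverageError(GeometryError):
    """No frame close enough to a target capture angle."""


# ---------------------------------------------------------------------------
# small helpers


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _rodrigues(axis: np.ndarray, cos_a: float, sin_a: float) -> np.ndarray:
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + sin_a * K + (1.0 - cos_a) * (K @ K)


def rotation_taking(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        raise GeometryError("180-degree rotation is ambiguous (anti-parallel vectors)")
    return _rodrigues(v / s, c, s)


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT homography mapping src (N,2) to dst (N,2), Hartley-normalized."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)

    def norm_T(pts):
        c = pts.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.linalg.norm(pts - c, axis=1).mean(), 1e-12)
        return np.array(
            [[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1]]
        )

    Ts, Td = norm_T(src), norm_T(dst)
    s = (np.hstack([src, np.ones((len(src), 1))]) @ Ts.T)[:, :2]
    d = (np.hstack([dst, np.ones((len(dst), 1))]) @ Td.T)[:, :2]
    rows = []
    for (x, y), (u, v) in zip(s, d):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.asarray(rows)
    _, _, Vt = np.linalg.svd(A)
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / H[2, 2]


# ---------------------------------------------------------------------------
# card detection


def _initial_quad(hull_pts: np.ndarray) -> np.ndarray:
    """4 hull vertices maximizing enclosed area."""
    n = len(hull_pts)
    if n == 4:
        return hull_pts
    if n > 28:  # decimate very dense hulls before the O(n^4) search
        idx = np.linspace(0, n - 1, 28).round().astype(int)
        hull_pts = hull_pts[np.unique(idx)]
        n = len(hull_pts)
    best, best_area = None, -1.0
    for combo in itertools.combinations(range(n), 4):
        quad = hull_pts[list(combo)]
        area = abs(_polygon_area(quad))
        if area > best_area:
            best, best_area = quad, area
    return best


def _refine_corners(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Total-least-squares line fit per edge, corners = line intersections."""
    n_edges = 4
    centers = quad
    lines = []
    for e in range(n_edges):
        a, b = centers[e], centers[(e + 1) % 4]
        ab = b - a
        L = np.linalg.norm(ab)
        u = ab / L
        rel = contour_xy - a
        along = rel @ u
        perp = np.abs(rel @ np.array([-u[1], u[0]]))
        sel = (along > 0.08 * L) & (along < 0.92 * L) & (perp < 3.0)
        pts = contour_xy[sel]
        if len(pts) < 5:
            raise CardNotFoundError("card not found: edge support too thin")
        c = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - c)
        d = Vt[0]
        lines.append((c, d))
    corners = []
    for e in range(n_edges):
        (c1, d1) = lines[(e - 1) % 4]
        (c2, d2) = lines[e]
        A = np.stack([d1, -d2], axis=1)
        if abs(np.linalg.det(A)) < 1e-9:
            raise CardNotFoundError("card not found: degenerate edge pair")
        s = np.linalg.solve(A, c2 - c1)
        corners.append(c1 + s[0] * d1)
    return np.asarray(corners)


def detect_card(
    image: np.ndarray,
    card: CardSpec | None = None,
    brightness_threshold: float = 0.75,
    min_area_px: int = 200,
) -> CardDetection:
    """Locate the white reference card and return sub-pixel corners.

    The card renders near-white with a dark orientation mark near one
    corner; detection thresholds on the minimum colour channel, fits a
    quadrilateral to the largest bright blob, refines each edge by
    total-least-squares and disambiguates the 8 corner labellings using the
    mark. Raises :class:`CardNotFoundError` when no plausible card exists
    (as opposed to returning a low-confidence detection).
    """
    from skimage.measure import find_contours

    if card is None:
        card = CardSpec()
    img = np.asarray(image, dtype=float)
    bright = img.min(axis=2) > brightness_threshold
    lbl, n = ndimage.label(bright)
    if n == 0:
        raise CardNotFoundError("card not found: no bright region")
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_area_px:
        raise CardNotFoundError("card not found: bright region too small")
    mask = ndimage.binary_fill_holes(lbl == biggest)

    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    contour_xy = contour[:, ::-1]  # (x, y)
    from scipy.spatial import ConvexHull

    hull = ConvexHull(contour_xy)
    quad0 = _initial_quad(contour_xy[hull.vertices])
    corners = _refine_corners(contour_xy, quad0)

    # plausible credit-card aspect?
    e = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
    long_e, short_e = (e[0] + e[2]) / 2.0, (e[1] + e[3]) / 2.0
    ratio = max(long_e, short_e) / max(min(long_e, short_e), 1e-9)
    if not 1.1 < ratio < 2.6:
        raise CardNotFoundError(
            f"card not found: quadrilateral aspect {ratio:.2f} implausible"
        )

    # resolve the 8-fold labelling ambiguity with the printed mark
    local = card.corners_local()[:, :2] - card.corners_local()[:, :2].min(axis=0)
    from .scene import CARD_MARK_OFFSET  # lazy: avoids import cycle at load

    mark_local = np.array(CARD_MARK_OFFSET)
    best_order, best_val = None, np.inf
    candidates = [np.roll(np.arange(4), -k) for k in range(4)]
    candidates += [np.roll(np.arange(4)[::-1], -k) for k in range(4)]
    h, w = img.shape[:2]
    gray = img.mean(axis=2)
    for order in candidates:
        H = homography_dlt(local, corners[order])
        p = H @ np.array([mark_local[0], mark_local[1], 1.0])
        u, v = p[0] / p[2], p[1] / p[2]
        iu, iv = int(round(u)), int(round(v))
        if not (2 <= iu < w - 2 and 2 <= iv < h - 2):
            continue
        val = float(gray[iv - 2 : iv + 3, iu - 2 : iu + 3].mean())
        if val < best_val:
            best_val, best_order = val, order
    if best_order is None or best_val > 0.6:
        raise CardNotFoundError("card not found: orientation mark missing")
    corners = corners[best_order]

    poly_area = abs(_polygon_area(corners))
    mask_area = float(mask.sum())
    confidence = float(np.clip(1.0 - abs(poly_area - mask_area) / mask_area, 0.0, 1.0))
    return CardDetection(corners_px=corners, confidence=confidence)


# ---------------------------------------------------------------------------
# pose from planar points


def pose_from_plane_points(
    world_xy: np.ndarray, pixels: np.ndarray, K: CameraIntrinsics
) -> RigidPose:
    """Metric camera pose from >= 4 coplanar (z = 0) world points.

    Homography decomposition; of the two planar solutions the one with the
    camera above the plane (positive z of the camera center) is returned.
    """
    world_xy = np.asarray(world_xy, dtype=float)[:, :2]
    pixels = np.asarray(pixels, dtype=float)
    if len(world_xy) < 4:
        raise GeometryError("need >= 4 planar points for pose")
    H = homography_dlt(world_xy, pixels)
    M = K.K_inv @ H
    for sign in (1.0, -1.0):
        Ms = sign * M
        lam = 2.0 / (np.linalg.norm(Ms[:, 0]) + np.linalg.norm(Ms[:, 1]))
        r1 = lam * Ms[:, 0]
        r2 = lam * Ms[:, 1]
        r3 = np.cross(r1, r2)
        R = _orthonormalize(np.stack([r1, r2, r3], axis=1))
        t = lam * Ms[:, 2]
        pose = RigidPose(R, t)
        if pose.camera_center[2] > 0:
            return pose
    raise GeometryError("planar pose: no solution with the camera above the plane")


def pose_from_card(
    det: CardDetection, card: CardSpec, K: CameraIntrinsics, min_area_px: float = 25.0
) -> RigidPose:
    """Metric pose of the camera in the card/world frame."""
    area = abs(_polygon_area(det.corners_px))
    if area < min_area_px:
        raise GeometryError(f"card quadrilateral near-degenerate (area {area:.1f} px^2)")
    return pose_from_plane_points(
        card.corners_local()[:, :2], det.corners_px, K
    )


# ---------------------------------------------------------------------------
# gravity


def table_normal_from_gravity(g: GravitySample) -> np.ndarray:
    """Table-plane up-normal in the camera frame (assumes horizontal table)."""
    return -g.g_cam.copy()


def camera_elevation_deg(g: GravitySample) -> float:
    """Angle between the optical axis and the table plane; 90 = nadir."""
    cos_to_axis = float(np.clip(g.g_cam[2], -1.0, 1.0))
    elev = 90.0 - np.degrees(np.arccos(cos_to_axis))
    return float(max(elev, 0.0))


@dataclass(frozen=True)
class FramePair:
    index_90: int
    index_75: int
    residual_90_deg: float
    residual_75_deg: float


def select_frame_pair(
    stream, targets=(90.0, 75.0), tolerance_deg: float = 10.0
) -> FramePair:
    """Pick the frames whose elevations are nearest 90 and 75 degrees.

    ``stream`` is a sequence of (frame, GravitySample) pairs; the two picked
    indices are always distinct.
    """
    if len(stream) < 2:
        raise GeometryError("need at least two frames")
    elev = np.array([camera_elevation_deg(g) for _, g in stream])
    r90 = np.abs(elev - targets[0])
    i90 = int(np.argmin(r90))
    r75 = np.abs(elev - targets[1])
    r75[i90] = np.inf
    i75 = int(np.argmin(r75))
    res90, res75 = float(r90[i90]), float(abs(elev[i75] - targets[1]))
    if res90 > tolerance_deg or res75 > tolerance_deg:
        raise InsufficientCoverageError(
            f"insufficient coverage: best residuals {res90:.1f}/{res75:.1f} deg "
            f"exceed tolerance {tolerance_deg} deg"
        )
    return FramePair(i90, i75, res90, res75)


def _tilt_rotation(g_cam: np.ndarray) -> np.ndarray:
    """Any rotation mapping the world down-vector onto ``g_cam``.

    The choice among the 1-parameter family is irrelevant: the residual
    yaw about the vertical is estimated separately.
    """
    c = float(np.dot(WORLD_DOWN, g_cam))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # pi about the x-axis
    return rotation_taking(WORLD_DOWN, g_cam)


def pose_gravity_aided(
    world_points: np.ndarray,
    pixels: np.ndarray,
    K: CameraIntrinsics,
    g: GravitySample,
) -> RigidPose:
    """Camera pose with the tilt fixed analytically by gravity.

    The rotation is constrained to ``A(g) @ Rz(yaw)`` where ``A(g)`` maps
    the world down-vector onto the measured gravity direction; yaw (1 DoF)
    and translation (3 DoF) are solved linearly from >= 2 known world
    points (the card corners suffice).
    """
    X = np.atleast_2d(np.asarray(world_points, dtype=float))
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    if len(X) < 2 or len(pixels) != len(X):
        raise GeometryError("need >= 2 paired world points")
    A = _tilt_rotation(g.g_cam)
    u = np.stack([X[:, 0], X[:, 1], np.zeros(len(X))], axis=1) @ A.T
    v = np.stack([-X[:, 1], X[:, 0], np.zeros(len(X))], axis=1) @ A.T
    wv = np.stack([np.zeros(len(X)), np.zeros(len(X)), X[:, 2]], axis=1) @ A.T

    # each pixel row gives a @ (c*Au + s*Av + Aw + t) = 0 — homogeneous in
    # (c, s, t, 1) because table points have z ~ 0; the metric scale is
    # pinned afterwards by c^2 + s^2 = 1
    rows = []
    for i in range(len(X)):
        px, py = pixels[i]
        a_u = np.array([K.fx, 0.0, K.cx - px])
        a_v = np.array([0.0, K.fy, K.cy - py])
        for a in (a_u, a_v):
            rows.append([a @ u[i], a @ v[i], a[0], a[1], a[2], a @ wv[i]])
    M = np.asarray(rows)
    if np.linalg.norm(M[:, 5]) < 1e-9 * np.linalg.norm(M[:, :5]):
        # all points on z = 0: the last column vanishes and would admit a
        # trivial null vector — drop it
        _, _, Vt = np.linalg.svd(M[:, :5])
        sol = np.r_[Vt[-1], 0.0]
    else:
        _, _, Vt = np.linalg.svd(M)
        sol = Vt[-1]
    norm = np.hypot(sol[0], sol[1])
    if norm < 1e-12:
        raise GeometryError("degenerate yaw solution")
    sol = sol / norm
    c, s, t0 = sol[0], sol[1], sol[2:5]
    # sign: the scene must be in front of the camera
    depths = (c * u + s * v + wv + t0)[:, 2]
    if np.median(depths) < 0:
        c, s = -c, -s
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    R = _orthonormalize(A @ Rz)

    # re-solve translation exactly for the orthonormalized rotation
    rows_t, rhs_t = [], []
    RX = X @ R.T
    for i in range(len(X)):
        px, py = pixels[i]
        a_u = np.array([K.fx, 0.0, K.cx - px])
        a_v = np.array([0.0, K.fy, K.cy - py])
        for a in (a_u, a_v):
            rows_t.append(a)
            rhs_t.append(-a @ RX[i])
    t, *_ = np.linalg.lstsq(np.asarray(rows_t), np.asarray(rhs_t), rcond=None)
    return RigidPose(R, t)


def relative_pose_gravity_aided(
    pose1: RigidPose,
    g1: GravitySample,
    g2: GravitySample,
    pixels1: np.ndarray,
    pixels2: np.ndarray,
    K: CameraIntrinsics,
) -> RigidPose:
    """Pose of view 2 using gravity for the tilt component.

    Gravity pins the inter-view rotation up to a yaw about the vertical;
    the yaw (1 DoF) and translation (3 DoF) are solved linearly from >= 4
    correspondences of table-plane points (card corners suffice). The
    result is metric because view 1 is metric.
    """
    pixels1 = np.atleast_2d(np.asarray(pixels1, dtype=float))
    pixels2 = np.atleast_2d(np.asarray(pixels2, dtype=float))
    if len(pixels1) < 4 or len(pixels2) != len(pixels1):
        raise GeometryError("need >= 4 paired correspondences")
    if float(np.dot(g1.g_cam, g2.g_cam)) < -0.866:
        raise GeometryError("gravity vectors are anti-parallel: impossible tilt")

    # lift view-1 pixels to table-plane world points
    origin, dirs = pixel_rays(K, pose1, pixels1)
    X, _ = intersect_rays_plane(origin, dirs, [0.0, 0.0, 1.0], 0.0)
    return pose_gravity_aided(X, pixels2, K, g2)


# ---------------------------------------------------------------------------
# dense matching (plane sweep + NCC)


@dataclass(frozen=True)
class DenseMatchParams:
    z_min_mm: float = 0.0
    z_max_mm: float = 60.0
    z_step_mm: float = 1.0
    window_px: int = 11
    lr_tolerance_px: float = 1.0
    min_score: float = 0.5
    min_texture_std: float = 0.008
    pixel_step: int = 1


def _gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    return img.mean(axis=2) if img.ndim == 3 else img


def plane_homography(
    K: CameraIntrinsics, pose_a: RigidPose, pose_b: RigidPose, z_mm: float
) -> np.ndarray:
    """Homography mapping view-a pixels to view-b pixels for the horizontal
    plane at height z (world frame)."""
    n_c = pose_a.rotation @ np.array([0.0, 0.0, 1.0])
    d_c = z_mm + n_c @ pose_a.translation
    R_rel = pose_b.rotation @ pose_a.rotation.T
    t_rel = pose_b.translation - R_rel @ pose_a.translation
    H = K.K @ (R_rel + np.outer(t_rel, n_c) / d_c) @ K.K_inv
    return H


def _sweep_scores(g_a, g_b, K, pose_a, pose_b, zs, window):
    from functools import partial

    from scipy.ndimage import gaussian_filter, map_coordinates

    # Gaussian-weighted NCC: soft windows reduce boundary adhesion (pixels
    # near an item edge otherwise lock onto the dominant neighbouring plane)
    uniform_filter = partial(gaussian_filter, sigma=window / 4.0)

    H_img, W_img = g_a.shape
    uu, vv = np.meshgrid(np.arange(W_img, dtype=float), np.arange(H_img, dtype=float))
    ones = np.ones_like(uu)
    m_a = uniform_filter(g_a)
    v_a = uniform_filter(g_a * g_a) - m_a * m_a
    best = np.full(g_a.shape, -np.inf)
    best_idx = np.zeros(g_a.shape, dtype=np.int32)
    prev_scores = []
    all_scores = np.empty((len(zs), H_img, W_img), dtype=np.float32)
    for zi, z in enumerate(zs):
        Hm = plane_homography(K, pose_a, pose_b, z)
        x = Hm[0, 0] * uu + Hm[0, 1] * vv + Hm[0, 2] * ones
        y = Hm[1, 0] * uu + Hm[1, 1] * vv + Hm[1, 2] * ones
        w = Hm[2, 0] * uu + Hm[2, 1] * vv + Hm[2, 2] * ones
        px = x / w
        py = y / w
        warped = map_coordinates(g_b, [py, px], order=1, mode="constant", cval=np.nan)
        invalid = ~np.isfinite(warped)
        warped = np.where(invalid, 0.0, warped)
        m_b = uniform_filter(warped)
        v_b = uniform_filter(warped * warped) - m_b * m_b
        cov = uniform_filter(g_a * warped) - m_a * m_b
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = cov / np.sqrt(np.maximum(v_a, 1e-12) * np.maximum(v_b, 1e-12))
        ncc = np.where(
            invalid | ndimage.binary_dilation(invalid, iterations=window // 2),
            -np.inf,
            ncc,
        )
        all_scores[zi] = ncc
    best_idx = np.argmax(all_scores, axis=0)
    best = np.take_along_axis(all_scores, best_idx[None], axis=0)[0]
    return best, best_idx, all_scores, v_a


def _refine_z(best_idx, all_scores, zs):
    """Sub-step parabolic refinement of the best plane hypothesis."""
    nz = len(zs)
    i = best_idx
    im = np.clip(i - 1, 0, nz - 1)
    ip = np.clip(i + 1, 0, nz - 1)
    s0 = np.take_along_axis(all_scores, im[None], axis=0)[0]
    s1 = np.take_along_axis(all_scores, i[None], axis=0)[0]
    s2 = np.take_along_axis(all_scores, ip[None], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = s0 - 2.0 * s1 + s2
        delta = 0.5 * (s0 - s2) / denom
    delta = np.where(np.isfinite(delta) & (np.abs(delta) <= 1.0), delta, 0.0)
    step = zs[1] - zs[0] if nz > 1 else 1.0
    z = zs[0] + (i + delta) * step
    return np.clip(z, zs[0], zs[-1])


def _match_pixels_at_height(pixels, z, K, pose_a, pose_b):
    """Project view-a pixels at hypothesized heights z into view b."""
    origin, dirs = pixel_rays(K, pose_a, pixels)
    nrm = np.array([0.0, 0.0, 1.0])
    denom = dirs @ nrm
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (z - origin @ nrm) / denom
    pts = origin[None, :] + t[:, None] * dirs
    pix_b, depth = project_points(K, pose_b, pts)
    return pix_b, depth, pts


def dense_match(
    image_a: np.ndarray,
    image_b: np.ndarray,
    pose_a: RigidPose,
    pose_b: RigidPose,
    K: CameraIntrinsics,
    params: DenseMatchParams | None = None,
):
    """Plane-sweep NCC block matching with a left-right consistency check.

    Returns a :class:`dietvision.scene.Correspondences` (sub-pixel matches
    with NCC scores). A textureless pair yields an empty set with a warning
    rather than an error.
    """
    from .scene import Correspondences

    if params is None:
        params = DenseMatchParams()
    g_a, g_b = _gray(image_a), _gray(image_b)
    zs = np.arange(params.z_min_mm, params.z_max_mm + 1e-9, params.z_step_mm)
    if len(zs) < 2:
        zs = np.array([params.z_min_mm, params.z_min_mm + params.z_step_mm])

    best_ab, idx_ab, scores_ab, tex_a = _sweep_scores(
        g_a, g_b, K, pose_a, pose_b, zs, params.window_px
    )
    z_ab = _refine_z(idx_ab, scores_ab, zs)
    best_ba, idx_ba, scores_ba, _ = _sweep_scores(
        g_b, g_a, K, pose_b, pose_a, zs, params.window_px
    )
    z_ba = _refine_z(idx_ba, scores_ba, zs)

    H_img, W_img = g_a.shape
    valid = (best_ab >= params.min_score) & (
        np.sqrt(np.maximum(tex_a, 0.0)) >= params.min_texture_std
    )
    if params.pixel_step > 1:
        keep = np.zeros_like(valid)
        keep[:: params.pixel_step, :: params.pixel_step] = True
        valid &= keep
    if not valid.any():
        warnings.warn("dense_match: no textured, matchable pixels", stacklevel=2)
        return Correspondences(
            np.empty((0, 2)), np.empty((0, 2)), np.empty((0, 3)), np.empty(0, int),
            scores=np.empty(0),
        )

    vs, us = np.nonzero(valid)
    pix_a = np.stack([us.astype(float), vs.astype(float)], axis=1)
    pix_b, depth, pts = _match_pixels_at_height(
        pix_a, z_ab[vs, us], K, pose_a, pose_b
    )
    inb = (
        (depth > 0)
        & (pix_b[:, 0] >= 0) & (pix_b[:, 0] <= W_img - 1)
        & (pix_b[:, 1] >= 0) & (pix_b[:, 1] <= H_img - 1)
    )
    # left-right check: the reverse sweep at the matched pixel must come back
    ub = np.clip(np.round(pix_b[:, 0]).astype(int), 0, W_img - 1)
    vb = np.clip(np.round(pix_b[:, 1]).astype(int), 0, H_img - 1)
    back_pix, _, _ = _match_pixels_at_height(
        np.stack([ub.astype(float), vb.astype(float)], axis=1),
        z_ba[vb, ub],
        K,
        pose_b,
        pose_a,
    )
    # allow for the rounding of the reverse lookup on top of the tolerance
    lr_ok = (
        np.linalg.norm(back_pix - pix_a, axis=1)
        <= params.lr_tolerance_px + np.linalg.norm(pix_b - np.stack([ub, vb], axis=1).astype(float), axis=1)
    )
    sel = inb & lr_ok
    if not sel.any():
        warnings.warn("dense_match: left-right check removed all matches", stacklevel=2)
    return Correspondences(
        pixels_a=pix_a[sel],
        pixels_b=pix_b[sel],
        world=pts[sel],
        labels=np.zeros(int(sel.sum()), dtype=int),
        scores=best_ab[vs, us][sel],
    )


def estimate_table_distance(
    image_a: np.ndarray,
    image_b: np.ndarray,
    tilt_rotation: np.ndarray,
    baseline_mm: float,
    K: CameraIntrinsics,
    search_mm=(250.0, 800.0),
    step_mm: float = 5.0,
) -> float:
    """Camera height above the table for a gravity-levelled stereo rig.

    Sweeps table-plane hypotheses and keeps the one whose induced
    homography best aligns the two images (global NCC). Used to anchor the
    rig's world frame on the table when no reference card is available.
    """
    g_a, g_b = _gray(image_a), _gray(image_b)
    heights = np.arange(search_mm[0], search_mm[1] + 1e-9, step_mm)
    scores = []
    from scipy.ndimage import map_coordinates

    uu, vv = np.meshgrid(
        np.arange(0, K.width, 2, dtype=float), np.arange(0, K.height, 2, dtype=float)
    )
    for h in heights:
        pose_a = RigidPose(tilt_rotation, -tilt_rotation @ np.array([0.0, 0.0, h]))
        pose_b = RigidPose(
            tilt_rotation, pose_a.translation - np.array([baseline_mm, 0.0, 0.0])
        )
        Hm = plane_homography(K, pose_a, pose_b, 0.0)
        w = Hm[2, 0] * uu + Hm[2, 1] * vv + Hm[2, 2]
        px = (Hm[0, 0] * uu + Hm[0, 1] * vv + Hm[0, 2]) / w
        py = (Hm[1, 0] * uu + Hm[1, 1] * vv + Hm[1, 2]) / w
        warped = map_coordinates(g_b, [py, px], order=1, mode="constant", cval=np.nan)
        ref = g_a[::2, ::2]
        ok = np.isfinite(warped)
        if ok.sum() < 100:
            scores.append(-np.inf)
            continue
        a = ref[ok] - ref[ok].mean()
        b = warped[ok] - warped[ok].mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        scores.append(float((a * b).sum() / denom) if denom > 0 else -np.inf)
    best = int(np.argmax(scores))
    if not np.isfinite(scores[best]):
        raise GeometryError("table distance estimation failed: no image overlap")
    # parabolic sub-step refinement
    if 0 < best < len(heights) - 1:
        s0, s1, s2 = scores[best - 1], scores[best], scores[best + 1]
        denom = s0 - 2.0 * s1 + s2
        if np.isfinite(denom) and abs(denom) > 1e-12:
            delta = 0.5 * (s0 - s2) / denom
            if abs(delta) <= 1.0:
                return float(heights[best] + delta * step_mm)
    return float(heights[best])


# ---------------------------------------------------------------------------
# triangulation


def triangulate(
    pixels1: np.ndarray,
    pixels2: np.ndarray,
    pose1: RigidPose,
    pose2: RigidPose,
    K: CameraIntrinsics,
) -> PointCloud:
    """Linear (DLT) two-view triangulation with reprojection residuals.

    Points behind either camera are excluded.
    """
    pixels1 = np.atleast_2d(np.asarray(pixels1, dtype=float))
    pixels2 = np.atleast_2d(np.asarray(pixels2, dtype=float))
    baseline = np.linalg.norm(pose1.camera_center - pose2.camera_center)
    if baseline < 1e-6:
        raise GeometryError("baseline is (near) zero: no parallax to triangulate")
    P1 = K.K @ pose1.matrix
    P2 = K.K @ pose2.matrix
    n = len(pixels1)
    A = np.empty((n, 4, 4))
    A[:, 0] = pixels1[:, 0, None] * P1[2] - P1[0]
    A[:, 1] = pixels1[:, 1, None] * P1[2] - P1[1]
    A[:, 2] = pixels2[:, 0, None] * P2[2] - P2[0]
    A[:, 3] = pixels2[:, 1, None] * P2[2] - P2[1]
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[:, -1, :]
    w = Xh[:, 3]
    ok_w = np.abs(w) > 1e-12
    X = np.where(ok_w[:, None], Xh[:, :3] / np.where(ok_w, w, 1.0)[:, None], np.nan)

    z1 = pose1.transform(X)[:, 2]
    z2 = pose2.transform(X)[:, 2]
    front = ok_w & np.isfinite(X).all(axis=1) & (z1 > 0) & (z2 > 0)
    X = X[front]
    r1, _ = project_points(K, pose1, X)
    r2, _ = project_points(K, pose2, X)
    res = 0.5 * (
        np.linalg.norm(r1 - pixels1[front], axis=1)
        + np.linalg.norm(r2 - pixels2[front], axis=1)
    )
    return PointCloud(points=X, source_pixels=pixels1[front], residuals=res)


# ---------------------------------------------------------------------------
# table plane + volume


def fit_table_plane(
    cloud: PointCloud,
    normal_prior: np.ndarray,
    background_mask: np.ndarray,
    min_background_points: int = 10,
) -> PlaneModel:
    """Plane with the gravity-fixed normal; offset = median of n.x over
    background (non-food) points."""
    n = np.asarray(normal_prior, dtype=float)
    px = np.clip(
        np.round(cloud.source_pixels).astype(int),
        0,
        [background_mask.shape[1] - 1, background_mask.shape[0] - 1],
    )
    bg = background_mask[px[:, 1], px[:, 0]]
    if int(bg.sum()) < min_background_points:
        raise GeometryError(
            f"too few background points to fit the table plane ({int(bg.sum())})"
        )
    d = float(np.median(cloud.points[bg] @ n))
    return PlaneModel(normal=n, offset=d)


def _plane_basis(normal: np.ndarray):
    n = np.asarray(normal, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def integrate_volume(
    cloud: PointCloud,
    plane: PlaneModel,
    item_mask: np.ndarray,
    grid_mm: float = 1.0,
    item_id: int = 1,
) -> VolumeEstimate:
    """Grid the item's footprint on the table plane and integrate height.

    Per-cell height is the median of member points clipped at >= 0;
    interior holes are filled from the nearest supported cell; cells with
    neither support nor interior fill contribute nothing.
    """
    if grid_mm <= 0:
        raise ValueError("grid_mm must be positive")
    px = np.clip(
        np.round(cloud.source_pixels).astype(int),
        0,
        [item_mask.shape[1] - 1, item_mask.shape[0] - 1],
    )
    sel = item_mask[px[:, 1], px[:, 0]]
    if not sel.any():
        warnings.warn(f"item {item_id}: no reconstructed points in mask", stacklevel=2)
        return VolumeEstimate(item_id, 0.0, 0.0, grid_mm)
    pts = cloud.points[sel]
    h = np.maximum(plane.height(pts), 0.0)
    e1, e2 = _plane_basis(plane.normal)
    u = pts @ e1
    v = pts @ e2
    iu = np.floor((u - u.min()) / grid_mm).astype(int)
    iv = np.floor((v - v.min()) / grid_mm).astype(int)
    nu, nv = iu.max() + 1, iv.max() + 1
    cell = iu * nv + iv
    order = np.argsort(cell, kind="stable")
    cell_sorted = cell[order]
    h_sorted = h[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cell_sorted) > 0])
    bounds = np.r_[starts, len(cell_sorted)]
    grid = np.zeros((nu, nv))
    support = np.zeros((nu, nv), dtype=bool)
    for a, b in zip(bounds[:-1], bounds[1:]):
        c = cell_sorted[a]
        grid[c // nv, c % nv] = np.median(h_sorted[a:b])
        support[c // nv, c % nv] = True
    # close small gaps first: sample spacing can exceed the grid pitch, in
    # which case unsupported cells leak to the border and would never count
    # as interior
    closed = ndimage.binary_closing(
        support, structure=np.ones((3, 3), dtype=bool), border_value=0
    )
    interior = ndimage.binary_fill_holes(closed) & ~support
    if interior.any():
        _, (inds_u, inds_v) = ndimage.distance_transform_edt(
            ~support, return_indices=True
        )
        grid[interior] = grid[inds_u[interior], inds_v[interior]]
    filled = support | interior
    volume_mm3 = float(grid[filled].sum()) * grid_mm * grid_mm
    return VolumeEstimate(
        item_id=item_id,
        volume_ml=volume_mm3 / 1000.0,
        footprint_area_mm2=float(filled.sum()) * grid_mm * grid_mm,
        grid_resolution_mm=grid_mm,
    )


def save_point_cloud_ply(cloud: PointCloud, path) -> None:
    """ASCII PLY export."""
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    lines += [f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}" for p in cloud.points]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
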
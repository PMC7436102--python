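import warnings

import numpy as np
import pytest

from dietvision.geometry import (
    GeometryError,
    PlaneModel,
    PointCloud,
    fit_table_plane,
    integrate_volume,
    save_point_cloud_ply,
    triangulate,
)
from dietvision.scene import exact_correspondences


@pytest.fixture(scope="module")
def golden_cloud(golden_scene):
    v0, v1 = golden_scene.views
    K = golden_scene.spec.intrinsics
    corr = exact_correspondences(golden_scene, 0, 1)
    cloud = triangulate(corr.pixels_a, corr.pixels_b, v0.pose, v1.pose, K)
    return cloud


class TestFitTablePlane:
    def test_noiseless_offset_near_zero(self, golden_scene, golden_cloud):
        bg = golden_scene.views[0].labels.labels == 0
        plane = fit_table_plane(golden_cloud, np.array([0.0, 0.0, 1.0]), bg)
        assert abs(plane.offset) < 0.5

    def test_contaminated_background_median_robust(self, golden_scene, golden_cloud):
        # corrupt 30% of the background mask with food pixels above the plane
        v0 = golden_scene.views[0]
        bg = v0.labels.labels == 0
        contaminated = bg | (v0.labels.labels > 0)  # all food counted as background
        n_food = (v0.labels.labels > 0).sum()
        assert n_food / contaminated.sum() > 0.05  # contamination is real
        plane = fit_table_plane(golden_cloud, np.array([0.0, 0.0, 1.0]), contaminated)
        assert abs(plane.offset) < 2.0

    def test_normal_prior_returned_unchanged(self, golden_cloud, golden_scene):
        bg = golden_scene.views[0].labels.labels == 0
        prior = np.array([0.0, 0.0, 1.0])
        plane = fit_table_plane(golden_cloud, prior, bg)
        assert np.array_equal(plane.normal, prior)

    def test_too_few_background_points(self, golden_cloud, golden_scene):
        empty = np.zeros(golden_scene.views[0].labels.shape, dtype=bool)
        with pytest.raises(GeometryError, match="background"):
            fit_table_plane(golden_cloud, np.array([0.0, 0.0, 1.0]), empty)


class TestIntegrateVolume:
    def test_spherical_cap_within_five_percent(self, golden_scene, golden_cloud):
        bg = golden_scene.views[0].labels.labels == 0
        plane = fit_table_plane(golden_cloud, np.array([0.0, 0.0, 1.0]), bg)
        cap_mask = golden_scene.views[0].labels.labels == 1
        vol = integrate_volume(golden_cloud, plane, cap_mask, 1.0, item_id=1)
        assert vol.volume_ml == pytest.approx(
            golden_scene.solids[0].analytic_volume_ml, rel=0.05
        )

    def test_points_on_plane_give_zero(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 50, (500, 2)), np.zeros(500)])
        pix = rng.uniform(0, 100, (500, 2))
        cloud = PointCloud(pts, pix, np.zeros(500))
        plane = PlaneModel(np.array([0.0, 0.0, 1.0]), 0.0)
        mask = np.ones((120, 120), dtype=bool)
        vol = integrate_volume(cloud, plane, mask, 1.0)
        assert vol.volume_ml == 0.0

    def test_two_items_sum_to_whole(self, golden_scene, golden_cloud):
        labels = golden_scene.views[0].labels.labels
        bg = labels == 0
        plane = fit_table_plane(golden_cloud, np.array([0.0, 0.0, 1.0]), bg)
        v1 = integrate_volume(golden_cloud, plane, labels == 1, 1.0, 1)
        v2 = integrate_volume(golden_cloud, plane, labels == 2, 1.0, 2)
        whole = integrate_volume(golden_cloud, plane, labels > 0, 1.0, 3)
        assert v1.volume_ml + v2.volume_ml == pytest.approx(whole.volume_ml, rel=0.01)

    def test_empty_mask_warns_zero(self, golden_cloud, golden_scene):
        plane = PlaneModel(np.array([0.0, 0.0, 1.0]), 0.0)
        empty = np.zeros(golden_scene.views[0].labels.shape, dtype=bool)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            vol = integrate_volume(golden_cloud, plane, empty, 1.0, item_id=9)
        assert vol.volume_ml == 0.0
        assert any("no reconstructed points" in str(w.message) for w in rec)

    def test_invalid_grid(self, golden_cloud, golden_scene):
        plane = PlaneModel(np.array([0.0, 0.0, 1.0]), 0.0)
        mask = np.ones(golden_scene.views[0].labels.shape, dtype=bool)
        with pytest.raises(ValueError):
            integrate_volume(golden_cloud, plane, mask, 0.0)


class TestMetricGauge:
    def test_scaling_world_scales_translation_and_volume(self, golden_scene, golden_cloud):
        """Scaling the reference card by s scales translations by s and
        volumes by s^3 (same pixel observations)."""
        from dietvision.camera import project_points
        from dietvision.geometry import pose_gravity_aided

        s = 1.7
        K = golden_scene.spec.intrinsics
        v0 = golden_scene.views[0]
        pix, _ = project_points(K, v0.pose, golden_scene.card_corners_world)
        pose_1 = pose_gravity_aided(golden_scene.card_corners_world, pix, K, v0.gravity)
        pose_s = pose_gravity_aided(
            s * golden_scene.card_corners_world, pix, K, v0.gravity
        )
        assert np.allclose(pose_s.translation, s * pose_1.translation, rtol=1e-9)
        assert np.allclose(pose_s.rotation, pose_1.rotation, atol=1e-9)

        # scaled cloud -> volume scales by s^3
        labels = golden_scene.views[0].labels.labels
        plane = fit_table_plane(golden_cloud, np.array([0.0, 0.0, 1.0]), labels == 0)
        scaled = PointCloud(
            golden_cloud.points * s, golden_cloud.source_pixels, golden_cloud.residuals
        )
        v_base = integrate_volume(golden_cloud, plane, labels == 1, 1.0, 1)
        v_scaled = integrate_volume(scaled, plane, labels == 1, 1.0 * s, 1)
        assert v_scaled.volume_ml == pytest.approx(v_base.volume_ml * s**3, rel=0.02)


def test_ply_export(tmp_path, golden_cloud):
    path = tmp_path / "cloud.ply"
    save_point_cloud_ply(golden_cloud, path)
    text = path.read_text().splitlines()
    assert text[0] == "ply"
    assert int(text[2].split()[-1]) == len(golden_cloud)
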
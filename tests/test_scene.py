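import numpy as np
import pytest

from dietvision.camera import project_points
from dietvision.geometry import homography_dlt
from dietvision.recognition import toy_taxonomy
from dietvision.scene import (
    FoodSolid,
    SceneSpec,
    SceneSpecError,
    ViewSpec,
    exact_correspondences,
    load_scene,
    make_classification_set,
    make_scene,
    render_view,
    sample_scene_spec,
    save_scene,
)

CAP = FoodSolid("spherical_cap", {"sphere_radius": 60.0, "height": 30.0}, (-110.0, 20.0), 0, "cap")
BOX = FoodSolid("cuboid", {"size_x": 40.0, "size_y": 40.0, "size_z": 20.0}, (100.0, -60.0), 1, "box")


class TestAnalyticVolumes:
    def test_spherical_cap_closed_form(self):
        # pi h^2 (3R - h) / 3 with R=60, h=30
        assert CAP.analytic_volume_ml == pytest.approx(141.3716694, abs=1e-6)

    def test_cuboid(self):
        assert BOX.analytic_volume_ml == pytest.approx(32.0)

    def test_cylinder_and_half_ellipsoid(self):
        cyl = FoodSolid("cylinder", {"radius": 30.0, "height": 20.0}, (0, 0), 0, "c")
        assert cyl.analytic_volume_ml == pytest.approx(np.pi * 900 * 20 / 1000)
        he = FoodSolid("half_ellipsoid", {"semi_x": 30.0, "semi_y": 20.0, "semi_z": 10.0}, (0, 0), 0, "e")
        assert he.analytic_volume_ml == pytest.approx(2 / 3 * np.pi * 6000 / 1000)

    def test_invalid_parameters_rejected_with_label(self):
        bad = FoodSolid("cylinder", {"radius": -1.0, "height": 5.0}, (120.0, 0.0), 0, "soup")
        with pytest.raises(SceneSpecError, match="soup"):
            make_scene(SceneSpec(solids=(bad,)), seed=0)

    def test_cap_height_cannot_exceed_radius(self):
        bad = FoodSolid("spherical_cap", {"sphere_radius": 20.0, "height": 30.0}, (120.0, 0.0), 0, "dome")
        with pytest.raises(SceneSpecError, match="dome"):
            make_scene(SceneSpec(solids=(bad,)), seed=0)


class TestMakeScene:
    def test_determinism_bit_identical(self):
        spec = SceneSpec(solids=(CAP, BOX), noise_sigma=0.01)
        a = make_scene(spec, seed=7)
        b = make_scene(spec, seed=7)
        for va, vb in zip(a.views, b.views):
            assert np.array_equal(va.image, vb.image)
            assert np.array_equal(va.labels.labels, vb.labels.labels)

    def test_needs_two_views_and_one_solid(self):
        with pytest.raises(SceneSpecError):
            make_scene(SceneSpec(solids=(), views=(ViewSpec(90), ViewSpec(75))), seed=0)
        with pytest.raises(SceneSpecError):
            make_scene(SceneSpec(solids=(CAP,), views=(ViewSpec(90),)), seed=0)

    def test_camera_below_table_rejected(self):
        with pytest.raises(SceneSpecError, match="below"):
            make_scene(
                SceneSpec(solids=(CAP,), views=(ViewSpec(-30.0), ViewSpec(75.0))),
                seed=0,
            )

    def test_solid_on_card_rejected(self):
        on_card = FoodSolid("cylinder", {"radius": 20.0, "height": 10.0}, (0.0, 0.0), 0, "oops")
        with pytest.raises(SceneSpecError, match="card"):
            make_scene(SceneSpec(solids=(on_card,)), seed=0)

    def test_gravity_consistency(self, golden_scene):
        # rotating g_cam back by the camera rotation gives the world
        # down-vector to machine precision
        for v in golden_scene.views:
            down = v.pose.rotation.T @ v.gravity.g_cam
            assert np.allclose(down, [0.0, 0.0, -1.0], atol=1e-12)

    def test_masks_never_overlap_card(self, golden_scene):
        for v in golden_scene.views:
            assert not ((v.labels.labels > 0) & v.card_mask).any()

    def test_every_solid_visible_in_every_view(self, golden_scene):
        for v in golden_scene.views:
            for i in range(1, len(golden_scene.solids) + 1):
                assert (v.labels.labels == i).any()


class TestDepthFieldConsistency:
    def test_integrated_height_field_matches_analytic_volume(self):
        # 0.5 mm grid integration of the analytic surface within 1 %
        g = 0.5
        for solid in (CAP, BOX):
            cx, cy = solid.base_center
            r = solid.footprint_radius + 5.0
            xs = np.arange(cx - r, cx + r, g)
            ys = np.arange(cy - r, cy + r, g)
            X, Y = np.meshgrid(xs, ys)
            vol = solid.height_at(X, Y).sum() * g * g / 1000.0
            assert vol == pytest.approx(solid.analytic_volume_ml, rel=0.01)

    def test_rendered_depth_matches_height_field(self, golden_scene):
        v = golden_scene.views[0]
        for i, solid in enumerate(golden_scene.solids, start=1):
            sel = v.labels.labels == i
            pts = v.world_points[sel]
            expected = solid.height_at(pts[:, 0], pts[:, 1])
            assert np.abs(pts[:, 2] - expected).max() < 1e-6


class TestCorrespondences:
    def test_plane_points_satisfy_ground_truth_homography(self, golden_scene):
        # oracle: direct projection of table points through both poses
        v0, v1 = golden_scene.views
        K = golden_scene.spec.intrinsics
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-100, 100, (20, 2)), np.zeros(20)])
        p0, _ = project_points(K, v0.pose, pts)
        p1, _ = project_points(K, v1.pose, pts)
        H = homography_dlt(p0[:8], p1[:8])
        mapped = np.column_stack([p0, np.ones(20)]) @ H.T
        mapped = mapped[:, :2] / mapped[:, 2:3]
        assert np.allclose(mapped, p1, atol=1e-6)

    def test_correspondences_reproject_exactly(self, golden_scene):
        corr = exact_correspondences(golden_scene, 1, 0, stride=3)
        K = golden_scene.spec.intrinsics
        v0 = golden_scene.views[0]
        pix, depth = project_points(K, v0.pose, corr.world)
        assert (depth > 0).all()
        assert np.abs(pix - corr.pixels_b).max() < 1e-9

    def test_occluded_points_absent(self):
        # a tall cylinder occludes table points behind it in the 75-deg view
        tall = FoodSolid("cylinder", {"radius": 30.0, "height": 55.0}, (-120.0, 0.0), 0, "tower")
        scene = make_scene(SceneSpec(solids=(tall,)), seed=3)
        corr = exact_correspondences(scene, 0, 1)
        keys = {(int(a[0]), int(a[1])) for a in corr.pixels_a}
        v0, v1 = scene.views
        K = scene.spec.intrinsics
        # find a view-0 table pixel whose point is hidden in view 1
        sel = v0.labels.labels == 0
        pts = v0.world_points[sel]
        pix = np.stack(np.meshgrid(np.arange(K.width), np.arange(K.height)), axis=-1)[sel]
        p1, z1 = project_points(K, v1.pose, pts)
        inb = (p1[:, 0] > 0) & (p1[:, 0] < K.width - 1) & (p1[:, 1] > 0) & (p1[:, 1] < K.height - 1)
        hidden = 0
        for j in np.nonzero(inb)[0]:
            u, v_ = int(round(p1[j, 0])), int(round(p1[j, 1]))
            if v1.labels.labels[v_, u] == 1 and (int(pix[j, 0]), int(pix[j, 1])) not in keys:
                hidden += 1
        assert hidden > 0  # occlusion exists and is excluded

    def test_render_view_returns_triple(self, golden_scene):
        img, labels, corr = render_view(golden_scene, 1)
        assert img.shape[:2] == labels.shape
        assert len(corr) > 1000
        with pytest.raises(IndexError):
            render_view(golden_scene, 5)


class TestSerialization:
    def test_round_trip(self, tmp_path, golden_scene):
        save_scene(golden_scene, tmp_path / "s")
        loaded = load_scene(tmp_path / "s")
        assert loaded.analytic_volumes_ml == golden_scene.analytic_volumes_ml
        for va, vb in zip(loaded.views, golden_scene.views):
            assert np.allclose(va.pose.rotation, vb.pose.rotation)
            assert np.array_equal(va.labels.labels, vb.labels.labels)
            # images go through 8-bit quantization
            assert np.abs(va.image - vb.image).max() < 1.0 / 255.0 + 1e-9


class TestClassificationSet:
    def test_counts_and_paths(self, taxonomy):
        ds = make_classification_set(taxonomy, n_per_class=8, seed=0)
        assert len(ds) == 8 * len(taxonomy.fine_names)
        h1, h2, fine = ds.label_paths[0]
        assert taxonomy.fine_to_hyper2[fine] == h2
        assert taxonomy.hyper2_to_hyper1[h2] == h1

    def test_noise_free_class_means_distinct(self, taxonomy):
        ds = make_classification_set(taxonomy, n_per_class=4, seed=0, noise_sigma=0.0)
        means = []
        for k in range(len(taxonomy.fine_names)):
            means.append(ds.images[ds.fine_idx == k].mean(axis=(0, 1, 2)))
        means = np.asarray(means)
        d = np.linalg.norm(means[:, None] - means[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.01

    def test_determinism(self, taxonomy):
        a = make_classification_set(taxonomy, n_per_class=4, seed=5)
        b = make_classification_set(taxonomy, n_per_class=4, seed=5)
        assert np.array_equal(a.images, b.images)

    def test_invalid_inputs(self, taxonomy):
        with pytest.raises(ValueError):
            make_classification_set(taxonomy, n_per_class=0, seed=0)
        with pytest.raises(ValueError):
            make_classification_set(toy_taxonomy(1, 1, 1), n_per_class=2, seed=0)


def test_sampled_scenes_render(tmp_path):
    rng = np.random.default_rng(123)
    spec = sample_scene_spec(rng, n_solids=2, noise_sigma=0.01)
    scene = make_scene(spec, seed=123)
    assert len(scene.views) == 2
    assert all(v.image.min() >= 0 and v.image.max() <= 1 for v in scene.views)
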
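"""Pinhole projection, rasterization coverage, shading terms, post-processing."""

import numpy as np
import pytest

from synthrig.rendering import (
    CameraConfig, CameraModel, PostProcessSpec, camera_from_lookat,
    pixels_from_view_projection, post_process, project, rasterize, shade, spawn_camera,
)
from synthrig.scene_generation import LightRig, RGBMap, Scene, build_terrain
from synthrig.placement_pose import PosingConfig, place_subject, pose_subject
from synthrig.subject_model import PopulationSpec, build_population


def look_down_camera(height=5.0, resolution=(128, 128)):
    return camera_from_lookat(
        np.array([0.0, 0.0, height]), np.zeros(3),
        focal_length=35.0, resolution=resolution,
    )


def flat_scene(extent=12.0):
    return Scene(terrain=build_terrain(RGBMap(np.full((16, 16, 3), 0.5)), extent, 0.0))


def scene_with_subject(stick_model, seed=3):
    scene = flat_scene()
    spec = PopulationSpec(entries=[(stick_model, 1.0)], population_size=1)
    inst = build_population(spec, np.random.default_rng(seed))[0]
    cfg = PosingConfig(midair_fraction=0.0)
    pl = place_subject(scene, inst, np.random.default_rng(seed), cfg)
    scene.subjects.append(pose_subject(inst, pl, scene, np.random.default_rng(seed), cfg))
    return scene


class TestProjection:
    def test_optical_axis_projects_to_principal_point(self):
        cam = look_down_camera()
        for depth in (0.5, 2.0, 10.0):
            target = cam.position + cam.axes()[:, 2] * depth
            xy, z, behind = project(cam, target)
            assert not behind[0]
            assert np.allclose(xy[0], [64.0, 64.0], atol=1e-9)
            assert np.isclose(z[0], depth)

    def test_pinhole_closed_form(self):
        # fx = 100 px via focal 25 mm, sensor 32 mm, 128 px; principal point (64, 64)
        cam = CameraModel(
            position=np.zeros(3), rotation=np.zeros(3),
            focal_length=25.0, sensor_width=32.0, sensor_height=32.0, resolution=(128, 128),
        )
        # camera axes = identity: camera-space point (1, 0, 2) sits at pixel (64 + 100*1/2, 64)
        world = cam.axes() @ np.array([1.0, 0.0, 2.0]) + cam.position
        xy, z, _ = project(cam, world)
        assert np.allclose(xy[0], [114.0, 64.0], atol=1e-9)
        assert np.isclose(z[0], 2.0)

    def test_point_behind_camera_flagged(self):
        cam = look_down_camera()
        behind_pt = cam.position - cam.axes()[:, 2] * 1.0
        _, _, behind = project(cam, behind_pt)
        assert behind[0]

    def test_view_projection_matrix_agrees_with_direct_projection(self):
        cam = camera_from_lookat(np.array([3.0, -2.0, 4.0]), np.array([0.5, 0.5, 0.0]))
        pts = np.random.default_rng(0).uniform(-1, 1, (20, 3))
        xy, z, behind = project(cam, pts)
        vp_xy = pixels_from_view_projection(cam.view_projection(), pts, cam.resolution)
        assert np.allclose(xy[~behind], vp_xy[~behind], atol=1e-9)

    def test_fov_diagonal_formula(self):
        cam = CameraModel(np.zeros(3), np.zeros(3), focal_length=21.633, sensor_width=36, sensor_height=24)
        expect = np.degrees(2 * np.arctan(np.hypot(36, 24) / (2 * 21.633)))
        assert np.isclose(cam.fov_diagonal_deg(), expect)


class TestSpawnCamera:
    def test_zero_offset_centers_chosen_subject(self, stick_model):
        scene = scene_with_subject(stick_model)
        cfg = CameraConfig(resolution=(128, 128), offset_bound=0.0)
        cam = spawn_camera(scene, np.random.default_rng(1), cfg)
        center = scene.subjects[0].vertices_world.mean(axis=0)
        xy, _, behind = project(cam, center)
        assert not behind[0]
        assert np.allclose(xy[0], [64.0, 64.0], atol=0.5)

    def test_bounded_offset_keeps_subject_in_frame(self, stick_model):
        scene = scene_with_subject(stick_model)
        cfg = CameraConfig(resolution=(128, 128), offset_bound=8.0)
        for seed in range(10):
            cam = spawn_camera(scene, np.random.default_rng(seed), cfg)
            center = scene.subjects[0].vertices_world.mean(axis=0)
            xy, _, behind = project(cam, center)
            assert not behind[0]
            assert 0 <= xy[0, 0] <= 128 and 0 <= xy[0, 1] <= 128

    def test_seed_determinism(self, stick_model):
        scene = scene_with_subject(stick_model)
        a = spawn_camera(scene, np.random.default_rng(7), CameraConfig())
        b = spawn_camera(scene, np.random.default_rng(7), CameraConfig())
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.rotation, b.rotation)

    def test_empty_scene_rejected(self):
        with pytest.raises(ValueError):
            spawn_camera(flat_scene(), np.random.default_rng(0), CameraConfig())


class TestRasterize:
    def test_empty_scene_id_pass_all_background(self):
        scene = flat_scene()
        cam = look_down_camera()
        passes = rasterize(scene, cam)
        assert np.all(passes.id == 0)
        assert passes.hit.any()  # terrain is visible
        assert np.all(passes.depth[passes.hit] > 0)

    def test_subject_pixels_carry_its_id_color(self, stick_model):
        scene = scene_with_subject(stick_model)
        center = scene.subjects[0].vertices_world.mean(axis=0)
        cam = camera_from_lookat(center + np.array([0, 0, 4.0]), center, resolution=(128, 128))
        passes = rasterize(scene, cam)
        colors = {tuple(c) for c in passes.id.reshape(-1, 3)}
        assert tuple(scene.subjects[0].instance.id_color) in colors
        assert colors <= {(0, 0, 0), tuple(scene.subjects[0].instance.id_color)}

    def test_nearer_surface_wins_the_z_buffer(self, stick_model):
        # a subject standing on flat ground seen from above: subject pixels
        # must be nearer than the surrounding terrain pixels
        scene = scene_with_subject(stick_model)
        center = scene.subjects[0].vertices_world.mean(axis=0)
        cam = camera_from_lookat(center + np.array([0, 0, 5.0]), center, resolution=(96, 96))
        passes = rasterize(scene, cam)
        subj = np.any(passes.id != 0, axis=2)
        assert subj.any()
        assert passes.depth[subj].mean() < passes.depth[passes.hit & ~subj].mean()

    def test_single_triangle_coverage_matches_halfspace_oracle(self):
        # one triangle as a minimal "subject"; per-pixel half-space test oracle
        from synthrig.scene_generation import PlacedSubject
        from synthrig.subject_model import Bone, SubjectModel
        tri_world = np.array([[-1.0, -1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 1.5, 0.0]])
        model = SubjectModel(
            "tri", tri_world, np.array([[0, 1, 2]]), np.full((3, 3), 0.5),
            bones=[Bone("root", None, np.zeros(3), np.array([0, 1, 2]))], joints=[],
        )
        from synthrig.subject_model import SubjectInstance
        inst = SubjectInstance(1, model, 1.0, (0.0, 0.0, 1.0, 1.0), (5, 0, 0))
        subject = PlacedSubject(inst, np.zeros(3), np.zeros(3), {}, tri_world, {})
        scene = flat_scene()
        scene.terrain.heightfield[:] = -5.0  # push terrain far below
        scene.subjects.append(subject)
        cam = look_down_camera(height=4.0, resolution=(64, 64))
        passes = rasterize(scene, cam)
        got = np.any(passes.id != 0, axis=2)
        pix, _, _ = project(cam, tri_world)
        expect = np.zeros((64, 64), dtype=bool)
        for r in range(64):
            for c in range(64):
                p = np.array([c + 0.5, r + 0.5])
                w = []
                for a, b in ((0, 1), (1, 2), (2, 0)):
                    e = (pix[b] - pix[a])
                    w.append(e[0] * (p[1] - pix[a][1]) - e[1] * (p[0] - pix[a][0]))
                w = np.array(w)
                expect[r, c] = np.all(w >= 0) or np.all(w <= 0)
        # allow the oracle and rasterizer to differ only on exact edges
        disagree = got ^ expect
        assert disagree.sum() == 0


class TestShade:
    def test_pure_ambient_reproduces_albedo(self):
        scene = flat_scene()
        cam = look_down_camera()
        passes = rasterize(scene, cam)
        rig = LightRig(np.array([0, 0, -1.0]), np.ones(3), 0.0, [], ambient=1.0, fog_density=0.0)
        out = shade(scene, cam, passes, rig)
        assert np.allclose(out[passes.hit], passes.albedo[passes.hit], atol=1e-12)

    def test_grazing_directional_light_contributes_nothing(self):
        scene = flat_scene()
        cam = look_down_camera()
        passes = rasterize(scene, cam)
        # light direction parallel to the flat ground: n . (-l) = 0
        rig = LightRig(np.array([1.0, 0, 0]), np.ones(3), 1.0, [], ambient=0.0, fog_density=0.0)
        out = shade(scene, cam, passes, rig)
        assert np.allclose(out[passes.hit], 0.0, atol=1e-12)

    def test_fog_blend_follows_exponential_attenuation(self):
        scene = flat_scene()
        cam = look_down_camera(height=5.0)
        passes = rasterize(scene, cam)
        d = 0.3
        rig = LightRig(np.array([0, 0, -1.0]), np.ones(3), 0.0, [], ambient=1.0,
                       fog_density=d, sky_color=np.array([1.0, 1.0, 1.0]))
        out = shade(scene, cam, passes, rig)
        r, c = np.argwhere(passes.hit)[0]
        z = passes.depth[r, c]
        expect = 1.0 + (passes.albedo[r, c] - 1.0) * np.exp(-d * z)
        assert np.allclose(out[r, c], expect, atol=1e-12)


class TestPostProcess:
    def test_identity_spec_is_bitwise_noop(self, rng):
        img = rng.random((32, 32, 3))
        assert post_process(img, PostProcessSpec()) is img

    def test_vignette_attenuates_corner_by_radial_formula(self):
        img = np.ones((64, 64, 3))
        out = post_process(img, PostProcessSpec(vignette_strength=0.5))
        H = W = 64
        r2 = (0.5 - W / 2) ** 2 + (0.5 - H / 2) ** 2
        r2max = (W / 2) ** 2 + (H / 2) ** 2
        assert np.isclose(out[0, 0, 0], 1 - 0.5 * r2 / r2max)
        assert np.isclose(out[32, 32, 0], 1 - 0.5 * ((0.5) ** 2 + (0.5) ** 2) / r2max)

    def test_same_grain_seed_reproduces_noise_field(self, rng):
        img = rng.random((32, 32, 3))
        spec = PostProcessSpec(grain_amplitude=0.05, grain_seed=99)
        assert np.array_equal(post_process(img, spec), post_process(img, spec))

    def test_saturation_zero_is_grayscale(self, rng):
        img = rng.random((8, 8, 3))
        out = post_process(img, PostProcessSpec(saturation=0.0))
        assert np.allclose(out[..., 0], out[..., 1]) and np.allclose(out[..., 1], out[..., 2])
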
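import numpy as np
import pytest

from endofuse.camera import default_endoscope, project
from endofuse.geometry import RigidTransform
from endofuse.simulator import (
    SceneState,
    fov_positions,
    make_calibration_plate,
    make_checkerboard,
    make_grid_phantom,
    observe_markers,
    render_circles,
    render_endoscope_image,
    run_accuracy_protocol,
)
from conftest import random_rigid


class TestGridPhantom:
    def test_deterministic_per_seed(self):
        a, b = make_grid_phantom(0), make_grid_phantom(0)
        assert np.array_equal(a.sphere_centers, b.sphere_centers)
        assert np.array_equal(a.marker_positions, b.marker_positions)
        c = make_grid_phantom(1)
        assert not np.array_equal(a.sphere_centers, c.sphere_centers)

    @pytest.mark.parametrize("seed", [0, 1, 17, 202])
    def test_layout_constraints(self, seed):
        ph = make_grid_phantom(seed)
        assert len(ph.sphere_ids) == 13 and len(ph.marker_ids) == 11
        xy = ph.sphere_centers[:, :2]
        half_roi = ph.roi_size_mm / 2.0
        assert np.abs(xy).max() <= half_roi
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 3.0
        # markers live on the plate border, outside the ROI
        assert np.abs(ph.marker_positions[:, :2]).max() <= ph.plate_size_mm / 2.0
        assert (np.abs(ph.marker_positions[:, :2]).max(axis=1) > half_roi).all()

    def test_diameters_exact_by_default_with_optional_tolerance(self):
        ph = make_grid_phantom(0)
        assert np.all(ph.sphere_diameters_mm == 2.0)
        ph_tol = make_grid_phantom(0, diameter_tolerance_mm=0.005)
        assert np.abs(ph_tol.sphere_diameters_mm - 2.0).max() <= 0.005
        assert np.any(ph_tol.sphere_diameters_mm != 2.0)


class TestPlanarTargets:
    def test_calibration_plate_25_coplanar(self):
        plate = make_calibration_plate()
        pts = np.array(list(plate.values()))
        assert len(pts) == 25
        assert np.all(pts[:, 2] == 0.0)

    def test_checkerboard_dimensions_and_spacing(self):
        pts = make_checkerboard(7, 9, 5.0)
        assert pts.shape == (63, 3)
        assert np.all(pts[:, 2] == 0.0)
        row = pts[:9]
        assert np.allclose(np.diff(row[:, 0]), 5.0)


class TestObserveMarkers:
    def test_zero_sigma_is_exact_forward_kinematics(self, rng):
        pose = random_rigid(rng, source="plate", target="ots")
        markers = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(5)}
        obs = observe_markers(pose, markers)
        for o in obs:
            assert np.allclose(o.position.to_array(), pose.apply(markers[o.marker_id]))

    def test_sample_sd_matches_sigma(self):
        pose = RigidTransform.identity("ots", source="plate")
        markers = {f"m{i}": np.zeros(3) for i in range(11)}
        rng = np.random.default_rng(9)
        draws = np.array(
            [
                o.position.to_array()
                for _ in range(1000)
                for o in observe_markers(pose, markers, 0.05, rng)
            ]
        )
        sd = draws.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 0.05) / 0.05 < 0.05)

    def test_same_seed_identical(self, rng):
        pose = random_rigid(rng, source="plate", target="ots")
        markers = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(5)}
        a = observe_markers(pose, markers, 0.1, np.random.default_rng(3))
        b = observe_markers(pose, markers, 0.1, np.random.default_rng(3))
        for x, y in zip(a, b):
            assert np.array_equal(x.position.to_array(), y.position.to_array())


class TestRendering:
    def test_on_axis_sphere_renders_at_principal_point(self, cam):
        K = type(cam)(fx=cam.fx, fy=cam.fy, cx=cam.cx, cy=cam.cy,
                      width=cam.width, height=cam.height)  # zero distortion
        d = 25.0
        scene = SceneState(
            camera_pose=RigidTransform.identity("ots", source="camera"),
            em_pose=RigidTransform.identity("ots", source="marker"),
            phantom_pose=RigidTransform(np.eye(3), [0, 0, d], source="plate", target="ots"),
            intrinsics=K,
        )
        ph = make_grid_phantom(0)
        # move one sphere onto the plate origin so it sits on the optical axis
        centers = ph.sphere_centers.copy()
        centers[0] = 0.0
        ph = type(ph)(ph.sphere_ids, centers, ph.sphere_diameters_mm,
                      ph.marker_ids, ph.marker_positions)
        img, truth = render_endoscope_image(scene, ph)
        on_axis = [t for t in truth if t.sphere_id == "s00"][0]
        assert on_axis.center_px == pytest.approx((K.cx, K.cy))
        assert on_axis.radius_px == pytest.approx(K.fx * 1.0 / d)
        # the principal point lies inside a filled (bright) disc
        assert img[int(round(K.cy)), int(round(K.cx))] > 0.9

    def test_truth_is_consistent_with_project(self, tiny_run):
        run = tiny_run
        for frame in run.frames[:10]:
            cam_from_plate = run.tco.invert() @ frame.phantom_pose
            cam = cam_from_plate.apply(run.phantom.sphere_centers)
            by_id = dict(zip(run.phantom.sphere_ids, cam))
            for t in frame.truth:
                assert np.allclose(
                    t.center_px, project(run.intrinsics, by_id[t.sphere_id]), atol=1e-9
                )

    def test_render_intensity_profile(self):
        img = render_circles(64, 48, [(32.0, 24.0)], [6.0])
        assert img[24, 32] > 0.9
        assert img[0, 0] == pytest.approx(0.10)


class TestAccuracyProtocol:
    def test_structure_and_determinism(self):
        a = run_accuracy_protocol((5.0, 30.0), 10, render=False, seed=4)
        b = run_accuracy_protocol((5.0, 30.0), 10, render=False, seed=4)
        assert len(a.frames) == 20
        for fa, fb in zip(a.frames, b.frames):
            assert fa.phantom_pose.is_close(fb.phantom_pose, 1e-15, 1e-15)

    def test_grid_stays_perpendicular_to_line_of_sight(self, tiny_run):
        for frame in tiny_run.frames:
            cam_from_plate = tiny_run.tco.invert() @ frame.phantom_pose
            # plate normal (z of the plate frame) must align with the optical axis
            assert np.allclose(cam_from_plate.rotation[:, 2], [0, 0, 1.0], atol=1e-12)
            assert cam_from_plate.translation[2] == pytest.approx(frame.distance_mm)

    def test_fov_coverage_per_distance(self):
        run = run_accuracy_protocol((10.0,), 100, render=False, seed=0)
        K = run.intrinsics
        pts = np.array([t.center_px for f in run.frames for t in f.truth])
        bins = 8
        H, _, _ = np.histogram2d(
            pts[:, 0], pts[:, 1],
            bins=[np.linspace(0, K.width, bins + 1), np.linspace(0, K.height, bins + 1)],
        )
        xc = (np.arange(bins) + 0.5) * K.width / bins
        yc = (np.arange(bins) + 0.5) * K.height / bins
        XX, YY = np.meshgrid(xc, yc, indexing="ij")
        inside = (XX - K.cx) ** 2 + (YY - K.cy) ** 2 <= (0.8 * min(K.cx, K.cy)) ** 2
        assert (H[inside] > 0).mean() >= 0.9

    def test_sigma_zero_is_continuous_limit(self):
        """No branch flips at σ=0: a tiny sigma perturbs outputs only tinily."""
        a = run_accuracy_protocol((20.0,), 5, render=False, seed=8, sigma_marker_mm=0.0)
        b = run_accuracy_protocol((20.0,), 5, render=False, seed=8, sigma_marker_mm=1e-9)
        for fa, fb in zip(a.frames, b.frames):
            for oa, ob in zip(fa.observations, fb.observations):
                diff = np.linalg.norm(oa.position.to_array() - ob.position.to_array())
                assert diff < 1e-8

    def test_sunflower_positions_fill_the_disc(self):
        pts = fov_positions(200, 100.0, (0.0, 0.0))
        r = np.linalg.norm(pts, axis=1)
        assert r.max() <= 100.0
        assert (r < 50.0).mean() == pytest.approx(0.25, abs=0.05)
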
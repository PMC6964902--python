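import numpy as np
import pytest

from endofuse.camera import CameraIntrinsics, default_endoscope
from endofuse.geometry import RigidTransform
from endofuse.overlay import (
    EvaluationError,
    OverlayCircle,
    compute_tre,
    detect_spheres,
    evaluate_run,
    match_circles,
    overlay_structures,
)
from endofuse.simulator import (
    make_grid_phantom,
    render_circles,
    run_accuracy_protocol,
)
from endofuse.tracking import estimate_patient_pose
from conftest import random_rigid


def circle(u, v, r=10.0, source="real", sid=""):
    return OverlayCircle((u, v), r, source, sid)


class TestOverlayStructures:
    def test_identity_chain_on_axis(self, cam):
        i = RigidTransform.identity
        structures = {"s": (np.array([0.0, 0.0, 40.0]), 1.0)}
        circles, dropped = overlay_structures(
            structures, i("ots", "cbct"), i("ots", "marker"), i("marker", "camera"), cam
        )
        assert dropped == 0
        assert circles[0].center == pytest.approx((cam.cx, cam.cy))
        assert circles[0].radius_px == pytest.approx(cam.fx / 40.0)

    def test_behind_camera_dropped_and_counted(self, cam):
        i = RigidTransform.identity
        structures = {
            "front": (np.array([0.0, 0.0, 40.0]), 1.0),
            "behind": (np.array([0.0, 0.0, -40.0]), 1.0),
        }
        circles, dropped = overlay_structures(
            structures, i("ots", "cbct"), i("ots", "marker"), i("marker", "camera"), cam
        )
        assert dropped == 1 and len(circles) == 1

    def test_zero_noise_overlay_coincides_with_truth(self, tiny_run):
        """Master zero-noise law on a reduced protocol."""
        for frame in tiny_run.frames:
            pose = estimate_patient_pose(tiny_run.vrg, frame.observations)
            circles, _ = overlay_structures(
                tiny_run.structures, pose.tpo, tiny_run.tmo, tiny_run.tcm,
                tiny_run.intrinsics, tiny_run.radius_mode,
            )
            by_id = {c.sphere_id: c for c in circles}
            for t in frame.truth:
                c = by_id[t.sphere_id]
                assert np.hypot(
                    c.center[0] - t.center_px[0], c.center[1] - t.center_px[1]
                ) < 1e-6
                assert abs(c.radius_px - t.radius_px) < 1e-6


class TestDetectSpheres:
    def test_blank_image_yields_nothing(self):
        assert detect_spheres(np.full((100, 120), 0.1)) == []

    def test_rendered_spheres_recovered_to_subpixel(self, rng):
        centers = np.array([[40.0, 30.0], [95.5, 70.25], [160.2, 40.8]])
        radii = np.array([8.0, 11.5, 6.25])
        img = render_circles(220, 120, centers, radii)
        det = [c for c in detect_spheres(img) if not c.ambiguous]
        assert len(det) == 3
        got = np.array([c.center for c in det])
        order = np.argsort(got[:, 0])
        by_x = np.argsort(centers[:, 0])
        assert np.abs(got[order] - centers[by_x]).max() < 0.1
        got_r = np.array([c.radius_px for c in det])
        assert np.abs(got_r[order] - radii[by_x]).max() < 0.15

    def test_robust_to_pixel_noise(self):
        rng = np.random.default_rng(2)
        centers = np.array([[40.0, 30.0], [95.5, 70.25], [160.2, 40.8]])
        radii = np.array([8.0, 11.5, 6.25])
        img = render_circles(220, 120, centers, radii, sigma_pixel=2.0 / 255.0, rng=rng)
        det = [c for c in detect_spheres(img) if not c.ambiguous]
        assert len(det) == 3
        got = np.array(sorted([c.center for c in det]))
        assert np.abs(got - centers[np.argsort(centers[:, 0])]).max() < 0.5

    def test_border_clipped_blob_flagged_ambiguous(self):
        img = render_circles(120, 100, [(2.0, 50.0)], [10.0])
        det = detect_spheres(img)
        assert len(det) == 1 and det[0].ambiguous

    def test_full_frame_13_sphere_detection(self, cam):
        from endofuse.simulator import SceneState, make_grid_phantom, render_endoscope_image
        from endofuse.geometry import RigidTransform

        # grid centred at 20 mm: all 13 spheres fully inside the image
        scene = SceneState(
            camera_pose=RigidTransform.identity("ots", source="camera"),
            em_pose=RigidTransform.identity("ots", source="marker"),
            phantom_pose=RigidTransform(np.eye(3), [0, 0, 20.0], source="plate", target="ots"),
            intrinsics=cam,
        )
        image, truth = render_endoscope_image(scene, make_grid_phantom(0))
        det = [c for c in detect_spheres(image) if not c.ambiguous]
        assert len(det) == len(truth) == 13
        for c in det:
            err = min(
                np.hypot(c.center[0] - t.center_px[0], c.center[1] - t.center_px[1])
                for t in truth
            )
            assert err < 0.1


class TestMatchCircles:
    def test_identical_lists_pair_perfectly(self, rng):
        reals = [circle(*rng.uniform(0, 500, 2)) for _ in range(8)]
        ovls = [OverlayCircle(c.center, c.radius_px, "overlay", f"s{i}") for i, c in enumerate(reals)]
        m = match_circles(reals, ovls)
        assert len(m.pairs) == 8 and not m.unmatched_real and not m.unmatched_overlay
        for r, o in m.pairs:
            assert r.center == o.center

    def test_uniform_shift_keeps_pairs(self):
        reals = [circle(50.0 * i, 40.0) for i in range(5)]
        ovls = [OverlayCircle((c.center[0] + 3, c.center[1] + 4), 10.0, "overlay") for c in reals]
        m = match_circles(reals, ovls)
        assert len(m.pairs) == 5
        for r, o in m.pairs:
            assert np.hypot(r.center[0] - o.center[0], r.center[1] - o.center[1]) == pytest.approx(5.0)

    def test_spurious_detection_stays_unpaired(self):
        reals = [circle(100, 100), circle(300, 100), circle(500, 400)]
        ovls = [OverlayCircle(c.center, 10.0, "overlay") for c in reals[:2]]
        m = match_circles(reals, ovls)
        assert len(m.pairs) == 2
        assert [c.center for c in m.unmatched_real] == [(500, 400)]

    def test_distance_gate(self):
        m = match_circles([circle(0, 0)], [OverlayCircle((100.0, 0.0), 5.0, "overlay")],
                          max_distance_px=50.0)
        assert not m.pairs


class TestComputeTre:
    def test_zero_offset(self):
        assert compute_tre(circle(10, 10, r=20), circle(10, 10, r=20, source="overlay")) == 0.0

    def test_formula_arithmetic(self):
        # 10 px offset, 40 px detected diameter, 2 mm spheres → 0.5 mm
        real = circle(100.0, 100.0, r=20.0)
        ovl = circle(110.0, 100.0, r=20.0, source="overlay")
        assert compute_tre(real, ovl, sphere_diameter_mm=2.0) == pytest.approx(0.5)

    def test_rejects_nonpositive_diameter(self):
        with pytest.raises(EvaluationError):
            OverlayCircle((0.0, 0.0), 0.0, "real")

    def test_known_inplane_offset_maps_to_mm(self, cam):
        """Shifting the overlaid sphere by δ in the object plane must read
        back as ≈|δ| mm of TRE (small-angle regime)."""
        i = RigidTransform.identity
        d = 25.0
        delta = np.array([0.8, -0.6, 0.0])  # |δ| = 1 mm in-plane
        base = {"s": (np.array([1.5, -2.0, d]), 1.0)}
        moved = {"s": (base["s"][0] + delta, 1.0)}
        args = (i("ots", "cbct"), i("ots", "marker"), i("marker", "camera"), cam)
        c_real, _ = overlay_structures(base, *args)
        c_ovl, _ = overlay_structures(moved, *args)
        real = OverlayCircle(c_real[0].center, c_real[0].radius_px, "real")
        tre = compute_tre(real, c_ovl[0], sphere_diameter_mm=2.0)
        assert tre == pytest.approx(np.linalg.norm(delta), rel=0.02)


class TestEvaluateRun:
    def test_zero_noise_records_are_numerically_zero(self, tiny_run):
        rec = evaluate_run(tiny_run)
        assert len(rec) > 100
        assert rec.tre_mm.max() < 1e-6

    def test_moved_phantom_compensated(self):
        """Motion compensation: random rigid motions of the grid leave the
        overlay on the rendered truth."""
        run = run_accuracy_protocol((15.0, 25.0), 8, render=False, seed=13)
        rec = evaluate_run(run)
        # every pose in the protocol is a different rigid motion of the grid
        poses = {(f.distance_mm, f.position_index) for f in run.frames}
        assert len(poses) == 16
        assert rec.tre_mm.max() < 1e-6

    def test_detection_path_close_to_truth_path(self):
        run = run_accuracy_protocol((20.0,), 3, render=True, seed=1)
        rec_truth = evaluate_run(run, real_source="truth")
        rec_det = evaluate_run(run, real_source="detect")
        assert len(rec_det) >= 0.9 * len(rec_truth)
        # detected-real TRE is bounded by detection error scaled to mm
        assert rec_det.tre_mm.max() < 0.05

    def test_scale_invariance_of_tre(self):
        """Doubling the sensor resolution must not change TRE in mm: the
        Ø_px normalization cancels the pixel scale."""
        base = run_accuracy_protocol((15.0,), 6, render=False, seed=5,
                                     sigma_marker_mm=0.05, image_scale=0.25)
        double = run_accuracy_protocol((15.0,), 6, render=False, seed=5,
                                       sigma_marker_mm=0.05, image_scale=0.5)
        a, b = evaluate_run(base), evaluate_run(double)
        merged = a.merge(b, on=["sphere_id", "distance_mm", "position_index"],
                         suffixes=("_1x", "_2x"))
        assert len(merged) > 30
        ratio = merged.tre_mm_2x / merged.tre_mm_1x
        assert np.abs(ratio - 1.0).max() < 0.01
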
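import numpy as np
import pytest

from endofuse.geometry import Point3, RigidTransform
from endofuse.tracking import (
    DegeneracyError,
    MarkerObservation,
    build_vrg,
    estimate_patient_pose,
    kabsch,
    register_point_sets,
)
from endofuse.simulator import make_grid_phantom, observe_markers
from conftest import random_rigid


def obs_from(points: dict, frame="ots", occluded=()):
    return [
        MarkerObservation(k, Point3.from_array(v, frame), visible=k not in occluded)
        for k, v in points.items()
    ]


class TestRegisterPointSets:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.uniform(-30, 30, size=(8, 3))
        t, fre = register_point_sets(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)
        assert fre == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform(self, rng):
        for _ in range(10):
            true = random_rigid(rng)
            src = rng.uniform(-40, 40, size=(10, 3))
            t, fre = register_point_sets(src, true.apply(src))
            assert t.rotation_angle_to(true) < 1e-10
            assert t.translation_distance_to(true) < 1e-10
            assert fre < 1e-10

    def test_fre_tracks_noise_level(self):
        """σ=0.1 mm on n=10 points: mean FRE sits near σ·sqrt(1 - 6/(3n))."""
        fres = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            true = random_rigid(rng)
            src = rng.uniform(-40, 40, size=(10, 3))
            dst = true.apply(src) + 0.1 * rng.standard_normal((10, 3))
            fres.append(register_point_sets(src, dst)[1])
        assert 0.05 < np.mean(fres) < 0.15

    def test_id_matching_uses_intersection(self, rng):
        true = random_rigid(rng)
        src = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(6)}
        dst = {k: true.apply(v) for k, v in src.items() if k != "m0"}
        dst["extra"] = np.zeros(3)
        t, fre = register_point_sets(src, dst)
        assert t.rotation_angle_to(true) < 1e-10

    def test_degenerate_inputs(self, rng):
        with pytest.raises(DegeneracyError):
            register_point_sets(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegeneracyError):
            register_point_sets(line, line)
        src = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(5)}
        with pytest.raises(DegeneracyError):
            register_point_sets(src, {"m0": src["m0"], "m1": src["m1"]})

    def test_reflection_guard_on_planar_sets(self, rng):
        """Near-planar marker configurations must still yield det +1."""
        for _ in range(20):
            true = random_rigid(rng)
            src = rng.uniform(-25, 25, size=(6, 3))
            src[:, 2] *= 1e-6  # almost flat
            t, _ = register_point_sets(src, true.apply(src))
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_optimality_vs_random_transforms(self, rng):
        """The closed-form fit beats 1000 random rigid transforms."""
        true = random_rigid(rng)
        src = rng.uniform(-30, 30, size=(8, 3))
        dst = true.apply(src) + 0.2 * rng.standard_normal((8, 3))
        _, fre = register_point_sets(src, dst)

        def rms(t):
            r = dst - t.apply(src)
            return np.sqrt(np.mean(np.sum(r * r, axis=1)))

        for _ in range(1000):
            assert fre <= rms(random_rigid(rng)) + 1e-12


class TestVRG:
    def test_hybrid_same_coordinates_gives_identity(self, rng):
        pts = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(5)}
        vrg = build_vrg(obs_from(pts), hybrid_cbct_positions=pts)
        assert np.allclose(vrg.cbct_from_ots.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(vrg.cbct_from_ots.translation, 0, atol=1e-10)

    def test_hybrid_offset_recovers_transform(self, rng):
        true = random_rigid(rng, source="ots", target="cbct")
        pts = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(6)}
        hybrid = {k: true.apply(v) for k, v in pts.items()}
        vrg = build_vrg(obs_from(pts), hybrid_cbct_positions=hybrid)
        assert vrg.cbct_from_ots.rotation_angle_to(true) < 1e-10
        assert vrg.cbct_from_ots.translation_distance_to(true) < 1e-10

    def test_too_few_markers(self, rng):
        pts = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(2)}
        with pytest.raises(DegeneracyError):
            build_vrg(obs_from(pts))

    def test_invisible_markers_do_not_count(self, rng):
        pts = {f"m{i}": rng.uniform(-20, 20, 3) for i in range(4)}
        with pytest.raises(DegeneracyError):
            build_vrg(obs_from(pts, occluded=("m0", "m1")))


class TestPatientPose:
    def setup_scene(self, rng):
        phantom = make_grid_phantom(3)
        ref_pose = random_rigid(rng, source="plate", target="ots")
        obs = observe_markers(ref_pose, phantom.markers)
        return phantom, ref_pose, build_vrg(obs)

    def test_unmoved_phantom_has_zero_fre(self, rng):
        phantom, ref_pose, vrg = self.setup_scene(rng)
        res = estimate_patient_pose(vrg, observe_markers(ref_pose, phantom.markers))
        assert not res.tracking_lost
        assert res.fre_mm < 1e-10
        # CBCT frame == OTS at acquisition: the pose must be the identity map
        assert np.allclose(res.tpo.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.tpo.translation, 0.0, atol=1e-10)

    def test_known_motion_recovered(self, rng):
        phantom, ref_pose, vrg = self.setup_scene(rng)
        motion = random_rigid(rng, source="ots", target="ots")
        moved = motion @ ref_pose
        res = estimate_patient_pose(vrg, observe_markers(moved, phantom.markers))
        assert res.tpo.rotation_angle_to(motion) < 1e-9
        assert res.tpo.translation_distance_to(motion) < 1e-8

    def test_occlusion_of_one_marker_is_tolerated(self, rng):
        phantom, ref_pose, vrg = self.setup_scene(rng)
        motion = random_rigid(rng, source="ots", target="ots")
        moved = motion @ ref_pose
        obs = observe_markers(moved, phantom.markers, occluded={"g00"})
        res = estimate_patient_pose(vrg, obs)
        assert not res.tracking_lost
        assert res.n_markers == len(phantom.marker_ids) - 1
        assert res.tpo.rotation_angle_to(motion) < 1e-9

    def test_tracking_loss_is_a_state_not_an_exception(self, rng):
        phantom, ref_pose, vrg = self.setup_scene(rng)
        occluded = set(list(phantom.marker_ids)[:-2])
        res = estimate_patient_pose(
            vrg, observe_markers(ref_pose, phantom.markers, occluded=occluded)
        )
        assert res.tracking_lost and res.tpo is None

    def test_order_invariance(self, rng):
        phantom, ref_pose, vrg = self.setup_scene(rng)
        motion = random_rigid(rng, source="ots", target="ots")
        obs = observe_markers(motion @ ref_pose, phantom.markers)
        a = estimate_patient_pose(vrg, obs)
        b = estimate_patient_pose(vrg, list(reversed(obs)))
        assert a.tpo.rotation_angle_to(b.tpo) < 1e-12
        assert a.tpo.translation_distance_to(b.tpo) < 1e-12


def test_kabsch_matches_register_interface(rng):
    src = rng.uniform(-10, 10, size=(5, 3))
    true = random_rigid(rng)
    R, t, fre = kabsch(src, true.apply(src))
    assert np.allclose(R, true.rotation, atol=1e-10)
    assert np.allclose(t, true.translation, atol=1e-9)
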
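import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from knapkin import calibration as cal, rig
from knapkin.geometry import quat_from_rotation
from knapkin.io import CalibrationRecord, LandmarkRecord


def _sphere_points(center, radius, n, rng, cap_deg=60.0):
    """Points on a spherical cap (arc-like coverage) around +z."""
    phi = np.deg2rad(cap_deg) * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    pts = np.stack(
        [
            np.sin(phi) * np.cos(theta),
            np.sin(phi) * np.sin(theta),
            np.cos(phi),
        ],
        axis=1,
    )
    return center + radius * pts


class TestLandmarkOffsets:
    def test_identity_sensor_pose(self):
        out = cal.landmark_offsets(
            {"acromion": np.array([0.1, 0.0, 0.0])},
            {"scapula": (np.zeros(3), np.array([1.0, 0, 0, 0]))},
            {"acromion": "scapula"},
        )
        np.testing.assert_allclose(out["acromion"].offset, [0.1, 0, 0], atol=1e-15)

    def test_rotated_sensor_pose(self):
        q = quat_from_rotation(Rotation.from_euler("z", 90, degrees=True))
        out = cal.landmark_offsets(
            {"p": np.array([0.1, 0.0, 0.0])},
            {"s": (np.zeros(3), q)},
            {"p": "s"},
        )
        np.testing.assert_allclose(out["p"].offset, [0, -0.1, 0], atol=1e-12)

    def test_synthetic_offsets_match_generator_mounts(self, model):
        # the rig's stylus simulation and the CAST offset computation agree
        traj = rig.JointTrajectory(fs=240.0, angles_deg=model.rest_angles_deg[None, :])
        fr = rig.forward_kinematics(model, traj)
        stylus = {name: pos[0] for name, pos in fr.landmarks.items()}
        poses = {s: (p[0], q[0]) for s, (p, q) in fr.sensors.items()}
        out = cal.landmark_offsets(stylus, poses, model.landmark_sensor)
        sim = rig.simulate_stylus_calibration(model)
        for name in stylus:
            np.testing.assert_allclose(
                out[name].offset, sim.landmarks[name].offset, atol=1e-12
            )


class TestFitSphere:
    def test_six_axis_points_unit_sphere(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        center, radius, rms = cal.fit_sphere(pts)
        np.testing.assert_allclose(center, 0, atol=1e-12)
        assert radius == pytest.approx(1.0, abs=1e-12)
        assert rms < 1e-12

    def test_translation_equivariance(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        shift = np.array([0.1, 0.2, 0.3])
        center, radius, _ = cal.fit_sphere(pts + shift)
        np.testing.assert_allclose(center, shift, atol=1e-12)
        assert radius == pytest.approx(1.0, abs=1e-12)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.3, 0.7, 0]])
        with pytest.raises(cal.DegenerateFitError):
            cal.fit_sphere(pts)

    def test_monte_carlo_center_error_under_noise(self):
        # 200 arc points, r = 0.28 m, 1 mm noise: center error < 2 mm in
        # >= 95% of 100 seeded runs
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = _sphere_points(np.array([0.1, -0.05, 0.2]), 0.28, 200, rng)
            pts = pts + rng.normal(0, 1e-3, pts.shape)
            center, _, _ = cal.fit_sphere(pts)
            hits += np.linalg.norm(center - [0.1, -0.05, 0.2]) < 2e-3
        assert hits >= 95

    def test_agrees_with_grid_search_oracle_on_small_sets(self):
        # brute-force refinement of the geometric objective around the
        # solver's answer cannot improve it on 5-point instances
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = _sphere_points(rng.normal(0, 0.1, 3), 0.25, 5, rng, cap_deg=80)
            pts += rng.normal(0, 1e-4, pts.shape)
            center, radius, rms = cal.fit_sphere(pts)

            def objective(c, r):
                d = np.linalg.norm(pts - c, axis=1)
                return np.sum((d - r) ** 2)

            best = objective(center, radius)
            for dc in 1e-6 * np.array(
                [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
            ):
                for dr in (-1e-6, 0, 1e-6):
                    assert objective(center + dc, radius + dr) >= best - 1e-18

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_rigid_transform_invariance(self, seed):
        # rotating + translating the capture volume moves the fitted center
        # with it and leaves the radius unchanged
        rng = np.random.default_rng(seed)
        pts = _sphere_points(rng.normal(0, 0.2, 3), 0.3, 40, rng)
        pts += rng.normal(0, 5e-4, pts.shape)
        rot = Rotation.random(rng=np.random.default_rng(seed + 1))
        shift = rng.normal(0, 1.0, 3)
        c0, r0, _ = cal.fit_sphere(pts)
        c1, r1, _ = cal.fit_sphere(rot.apply(pts) + shift)
        np.testing.assert_allclose(c1, rot.apply(c0) + shift, atol=1e-6)
        assert r1 == pytest.approx(r0, abs=1e-6)


class TestShoulderCenter:
    def test_noiseless_circumduction_exact_recovery(self, model):
        fr = rig.forward_kinematics(model, rig.make_circumduction_trial(model))
        motion = rig.render_sensor_tracks(fr, model)
        fit = cal.estimate_shoulder_center(motion)
        from knapkin.geometry import invert_pose

        sc = model.sensor_mounts["scapula"]
        truth = invert_pose(sc.position, sc.quat, np.zeros(3))  # shoulder = torso origin
        assert np.linalg.norm(fit["center_offset"] - truth) < 1e-9

    def test_static_arm_degenerate(self, model):
        traj = rig.JointTrajectory(
            fs=240.0, angles_deg=np.tile(model.rest_angles_deg, (100, 1))
        )
        motion = rig.render_sensor_tracks(rig.forward_kinematics(model, traj), model)
        with pytest.raises(cal.DegenerateFitError, match="circumduction|movement"):
            cal.estimate_shoulder_center(motion)

    def test_millimeter_noise_median_error(self, model):
        fr = rig.forward_kinematics(model, rig.make_circumduction_trial(model, duration=3.0))
        from knapkin.geometry import invert_pose

        sc = model.sensor_mounts["scapula"]
        truth = invert_pose(sc.position, sc.quat, np.zeros(3))
        errors = []
        for seed in range(50):
            motion = rig.render_sensor_tracks(
                fr, model, noise_sd=1e-3, rng=np.random.default_rng(seed)
            )
            fit = cal.estimate_shoulder_center(motion)
            errors.append(np.linalg.norm(fit["center_offset"] - truth))
        assert np.median(errors) < 3e-3


class TestMidpointAndSurface:
    def test_epicondyle_midpoint(self):
        np.testing.assert_allclose(
            cal.midpoint_center([0, 0, 0], [0.06, 0, 0]), [0.03, 0, 0]
        )

    def test_coincident_landmarks_return_point(self):
        np.testing.assert_allclose(cal.midpoint_center([1, 2, 3], [1, 2, 3]), [1, 2, 3])

    def test_plane_through_four_points(self):
        rec = CalibrationRecord(
            landmarks={},
            working_point=LandmarkRecord("hand", [0, 0, 0]),
            surface_points=[
                LandmarkRecord("core_base", [x, y, 0.42])
                for x, y in ((0, 0), (0.1, 0), (0, 0.1), (0.1, 0.1))
            ],
        )
        wp, plane = cal.register_tool_and_surface(rec)
        assert plane.point[2] == pytest.approx(0.42)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)

    def test_two_points_rejected(self):
        rec = CalibrationRecord(
            landmarks={},
            working_point=LandmarkRecord("hand", [0, 0, 0]),
            surface_points=[
                LandmarkRecord("core_base", [0, 0, 0]),
                LandmarkRecord("core_base", [1, 0, 0]),
            ],
        )
        with pytest.raises(cal.DegenerateFitError):
            cal.register_tool_and_surface(rec)

    def test_collinear_points_rejected(self):
        rec = CalibrationRecord(
            landmarks={},
            working_point=LandmarkRecord("hand", [0, 0, 0]),
            surface_points=[
                LandmarkRecord("core_base", [x, 0, 0]) for x in (0.0, 0.5, 1.0, 1.5)
            ],
        )
        with pytest.raises(cal.DegenerateFitError, match="collinear"):
            cal.register_tool_and_surface(rec)

    def test_synthetic_registration_recovers_surface_height(self, model, limb_model):
        from knapkin.geometry import apply_pose

        core = model.sensor_mounts["core_base"]
        world_point = apply_pose(
            core.position, core.quat, limb_model.striking_surface.point
        )
        assert world_point[2] == pytest.approx(model.core_surface_height, abs=1e-12)
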
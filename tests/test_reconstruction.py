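import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from knapkin import reconstruction as rc, rig
from knapkin.geometry import quat_from_rotation
from knapkin.io import SensorTrack, TrialRecording


class TestReconstructLandmarks:
    def test_identity_pose_offset_passthrough(self, limb_model, model):
        traj = rig.JointTrajectory(fs=240.0, angles_deg=model.rest_angles_deg[None, :])
        rec = rig.render_sensor_tracks(rig.forward_kinematics(model, traj), model)
        recon = rc.reconstruct_landmarks(rec, limb_model)
        fr = rig.forward_kinematics(model, traj)
        for name, pos in fr.landmarks.items():
            np.testing.assert_allclose(recon.landmarks[name][0], pos[0], atol=1e-12)

    def test_noiseless_trial_matches_rig_truth(
        self, three_strike_trial, limb_model, model
    ):
        traj, _, rec = three_strike_trial
        fr = rig.forward_kinematics(model, traj)
        recon = rc.reconstruct_landmarks(rec, limb_model)
        np.testing.assert_allclose(
            recon.joint_centers["elbow"], fr.joint_centers["elbow"], atol=1e-12
        )
        np.testing.assert_allclose(recon.working_point, fr.working_point, atol=1e-12)

    def test_missing_sensor_named(self, three_strike_trial, limb_model):
        _, _, rec = three_strike_trial
        broken = TrialRecording(
            fs=rec.fs,
            tracks={k: v for k, v in rec.tracks.items() if k != "forearm"},
            hammer_mass=rec.hammer_mass,
        )
        with pytest.raises(ValueError, match="forearm"):
            rc.reconstruct_landmarks(broken, limb_model)


class TestSegmentLengths:
    def _centers(self, dist):
        n = len(dist)
        return {
            "shoulder": np.zeros((n, 3)),
            "elbow": np.column_stack([dist, np.zeros(n), np.zeros(n)]),
            "wrist": np.column_stack([dist + 0.26, np.zeros(n), np.zeros(n)]),
        }

    def test_constant_distance(self):
        means, sds = rc.measure_segment_lengths(self._centers(np.full(50, 0.30)), (0, 50))
        assert means["upper_arm"] == pytest.approx(0.30)
        assert sds["upper_arm"] == pytest.approx(0.0, abs=1e-12)

    def test_sinusoidal_drift_closed_form(self):
        # 0.30 +- 0.005 sinusoid: mean 0.30, SD = amplitude / sqrt(2)
        t = np.arange(480)
        dist = 0.30 + 0.005 * np.sin(2 * np.pi * t / 120)
        means, sds = rc.measure_segment_lengths(self._centers(dist), (0, 480))
        assert means["upper_arm"] == pytest.approx(0.30, abs=1e-6)
        assert sds["upper_arm"] == pytest.approx(0.005 / np.sqrt(2), rel=0.01)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="10 frames"):
            rc.measure_segment_lengths(self._centers(np.full(50, 0.3)), (0, 5))

    def test_enforcement_pulls_along_ray(self):
        centers = {
            "shoulder": np.zeros((1, 3)),
            "elbow": np.array([[0.31, 0.0, 0.0]]),
            "wrist": np.array([[0.31, -0.26, 0.0]]),
        }
        out = rc.enforce_segment_lengths(centers, {"upper_arm": 0.30, "forearm": 0.26})
        np.testing.assert_allclose(out["elbow"][0], [0.30, 0, 0], atol=1e-12)
        # direction from (corrected) elbow to raw wrist preserved, length imposed
        d = out["wrist"][0] - out["elbow"][0]
        assert np.linalg.norm(d) == pytest.approx(0.26, abs=1e-12)

    def test_enforcement_identity_when_consistent(self):
        centers = {
            "shoulder": np.zeros((3, 3)),
            "elbow": np.tile([0.30, 0, 0], (3, 1)),
            "wrist": np.tile([0.30, -0.26, 0], (3, 1)),
        }
        out = rc.enforce_segment_lengths(centers, {"upper_arm": 0.30, "forearm": 0.26})
        np.testing.assert_allclose(out["elbow"], centers["elbow"], atol=1e-15)
        np.testing.assert_allclose(out["wrist"], centers["wrist"], atol=1e-15)

    def test_enforcement_idempotent(self, three_strike_trial, limb_model, model):
        traj, _, _ = three_strike_trial
        fr = rig.forward_kinematics(model, traj)
        rec = rig.render_sensor_tracks(fr, model, 0.005, 0.0, np.random.default_rng(2))
        recon = rc.reconstruct_landmarks(rec, limb_model)
        lengths, _ = rc.measure_segment_lengths(recon.joint_centers, (0, 480))
        once = rc.enforce_segment_lengths(recon.joint_centers, lengths)
        twice = rc.enforce_segment_lengths(once, lengths)
        for k in once:
            np.testing.assert_allclose(twice[k], once[k], atol=1e-12)

    def test_coincident_centers_rejected(self):
        centers = {
            "shoulder": np.zeros((1, 3)),
            "elbow": np.zeros((1, 3)),
            "wrist": np.array([[0.3, 0, 0]]),
        }
        with pytest.raises(ValueError, match="[Cc]oincident"):
            rc.enforce_segment_lengths(centers, {"upper_arm": 0.3, "forearm": 0.26})

    def test_artifact_correction_restores_constant_lengths(
        self, three_strike_trial, limb_model, model
    ):
        traj, _, _ = three_strike_trial
        fr = rig.forward_kinematics(model, traj)
        rec = rig.render_sensor_tracks(fr, model, 0.005, 0.0, np.random.default_rng(2))
        recon, _ = rc.reconstruct_trial(rec, limb_model)
        for a, b in (("shoulder", "elbow"), ("elbow", "wrist")):
            d = np.linalg.norm(recon.joint_centers[b] - recon.joint_centers[a], axis=1)
            assert d.std() < 1e-12


class TestJointAngles:
    def test_identity_relative_orientation_zero_angles(self, model, limb_model):
        traj = rig.JointTrajectory(fs=240.0, angles_deg=np.zeros((12, 9)))
        rec = rig.render_sensor_tracks(rig.forward_kinematics(model, traj), model)
        recon, angles = rc.reconstruct_trial(rec, limb_model, enforce_lengths=False)
        np.testing.assert_allclose(angles.angles_deg, 0.0, atol=1e-9)

    def test_pure_flexion_recovered_on_first_channel(self, model, limb_model):
        ang = np.zeros((12, 9))
        ang[:, 3] = 30.0  # elbow flexion
        traj = rig.JointTrajectory(fs=240.0, angles_deg=ang)
        rec = rig.render_sensor_tracks(rig.forward_kinematics(model, traj), model)
        _, angles = rc.reconstruct_trial(rec, limb_model, enforce_lengths=False)
        np.testing.assert_allclose(angles.angles_deg[:, 3], 30.0, atol=1e-9)
        others = np.delete(angles.angles_deg, 3, axis=1)
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_round_trip_rms_below_half_degree_noiseless(
        self, three_strike_trial, limb_model
    ):
        traj, _, rec = three_strike_trial
        _, angles = rc.reconstruct_trial(rec, limb_model)
        rms = np.sqrt(np.mean((angles.angles_deg - traj.angles_deg) ** 2))
        assert rms < 0.5
        assert rms < 1e-9  # noiseless reconstruction is exact in practice

    def test_angle_error_grows_with_noise(self, three_strike_trial, limb_model, model):
        traj, _, _ = three_strike_trial
        fr = rig.forward_kinematics(model, traj)
        errs = []
        for noise in (1e-4, 1e-3):
            rec = rig.render_sensor_tracks(
                fr, model, 0.0, noise, np.random.default_rng(4)
            )
            _, angles = rc.reconstruct_trial(rec, limb_model)
            errs.append(np.sqrt(np.mean((angles.angles_deg - traj.angles_deg) ** 2)))
        assert errs[0] < errs[1]

    def test_world_frame_rigid_transform_leaves_angles_unchanged(
        self, three_strike_trial, limb_model
    ):
        _, _, rec = three_strike_trial
        rot = Rotation.from_euler("z", 37, degrees=True)
        shift = np.array([1.0, -2.0, 0.5])
        moved = TrialRecording(
            fs=rec.fs,
            tracks={
                name: SensorTrack(
                    t=tr.t,
                    pos=rot.apply(tr.pos) + shift,
                    quat=quat_from_rotation(
                        rot * Rotation.from_quat(tr.quat, scalar_first=True)
                    ),
                )
                for name, tr in rec.tracks.items()
            },
            hammer_mass=rec.hammer_mass,
        )
        _, base_angles = rc.reconstruct_trial(rec, limb_model)
        _, moved_angles = rc.reconstruct_trial(moved, limb_model)
        np.testing.assert_allclose(
            moved_angles.angles_deg, base_angles.angles_deg, atol=1e-8
        )
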
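import numpy as np
import pytest

from knapkin import rig
from knapkin.geometry import minimum_jerk


class TestMakeArmModel:
    def test_construction_with_explicit_lengths(self):
        m = rig.make_arm_model((0.30, 0.26, 0.08))
        assert m.segment_lengths == {"upper_arm": 0.30, "forearm": 0.26, "hand": 0.08}
        assert m.hammer_mass == 0.6

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="must be > 0"):
            rig.make_arm_model((0.0, 0.26, 0.08))

    def test_same_inputs_identical_rigs(self):
        a = rig.make_arm_model()
        b = rig.make_arm_model()
        np.testing.assert_array_equal(a.rest_angles_deg, b.rest_angles_deg)
        np.testing.assert_array_equal(a.hammer_offset, b.hammer_offset)

    def test_epicondyle_midpoint_is_elbow_center(self, model):
        lm = model.landmarks
        mid = 0.5 * (lm["epicondyle_lat"][1] + lm["epicondyle_med"][1])
        np.testing.assert_allclose(
            mid, [0.0, -model.segment_lengths["upper_arm"], 0.0], atol=1e-15
        )


class TestStrikeTrajectory:
    def test_sample_count_matches_duration(self):
        traj = rig.generate_strike_trajectory(np.eye(9)[3] * 40, 1.0, 240.0)
        assert len(traj) == 240

    def test_single_dof_bell_curve(self):
        # 40 deg elbow flexion over 0.4 s at 240 Hz: 96 samples, rises
        # monotonically to the min-jerk midpoint then returns to zero
        traj = rig.generate_strike_trajectory(np.eye(9)[3] * 40, 0.4, 240.0)
        curve = traj.angles_deg[:, 3]
        assert len(curve) == 96
        peak = np.argmax(curve)
        assert np.all(np.diff(curve[: peak + 1]) >= 0)
        assert np.all(np.diff(curve[peak:]) <= 0)
        assert curve[0] == 0 and curve[-1] == pytest.approx(0, abs=1e-12)
        assert curve.max() == pytest.approx(40.0, abs=0.01)  # grid straddles the peak
        # closed-form min-jerk value at an interior sample
        tau = (20 / 95) * 2  # sample 20 of the rising half
        assert curve[20] == pytest.approx(40 * minimum_jerk(np.array(tau)), abs=1e-9)

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rig.generate_strike_trajectory(np.zeros(9), 0.4, 240.0)


class TestForwardKinematics:
    def test_reference_posture_closed_form(self, model):
        # all angles zero: the arm hangs straight down from the shoulder
        traj = rig.JointTrajectory(fs=240.0, angles_deg=np.zeros((1, 9)))
        fr = rig.forward_kinematics(model, traj)
        lua = model.segment_lengths["upper_arm"]
        lfa = model.segment_lengths["forearm"]
        np.testing.assert_allclose(fr.joint_centers["shoulder"][0], model.shoulder_base)
        np.testing.assert_allclose(
            fr.joint_centers["elbow"][0], model.shoulder_base - [0, 0, lua], atol=1e-12
        )
        np.testing.assert_allclose(
            fr.joint_centers["wrist"][0],
            model.shoulder_base - [0, 0, lua + lfa],
            atol=1e-12,
        )

    def test_straight_arm_shoulder_flexion_traces_circle(self, model):
        # pure shoulder flexion with a straight arm: the wrist center stays
        # at distance L_upperarm + L_forearm from the shoulder
        angles = np.zeros((90, 9))
        angles[:, 0] = np.linspace(0, 89, 90)
        fr = rig.forward_kinematics(model, rig.JointTrajectory(fs=240.0, angles_deg=angles))
        radius = np.linalg.norm(
            fr.joint_centers["wrist"] - fr.joint_centers["shoulder"], axis=1
        )
        expected = model.segment_lengths["upper_arm"] + model.segment_lengths["forearm"]
        np.testing.assert_allclose(radius, expected, atol=1e-12)
        # and the wrist moves in the vertical plane of the flexion arc
        assert np.ptp(fr.joint_centers["wrist"][:, 2]) > 0.1

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="9"):
            rig.JointTrajectory(fs=240.0, angles_deg=np.zeros((5, 7)))

    def test_rigid_body_distances_constant(self, model, three_strike_trial):
        traj, _, _ = three_strike_trial
        fr = rig.forward_kinematics(model, traj)
        for a, b in (("shoulder", "elbow"), ("elbow", "wrist")):
            d = np.linalg.norm(fr.joint_centers[b] - fr.joint_centers[a], axis=1)
            assert d.std() < 1e-12


class TestRenderSensorTracks:
    def test_zero_artifact_zero_noise_is_identity(self, model):
        traj = rig.make_circumduction_trial(model, duration=0.5)
        fr = rig.forward_kinematics(model, traj)
        rec = rig.render_sensor_tracks(fr, model)
        for name, (pos, _) in fr.sensors.items():
            np.testing.assert_array_equal(rec.tracks[name].pos, pos)

    def test_same_seed_identical_tracks(self, model):
        traj = rig.make_circumduction_trial(model, duration=0.5)
        fr = rig.forward_kinematics(model, traj)
        a = rig.render_sensor_tracks(fr, model, 0.005, 1e-4, np.random.default_rng(3))
        b = rig.render_sensor_tracks(fr, model, 0.005, 1e-4, np.random.default_rng(3))
        np.testing.assert_array_equal(a.tracks["hand"].pos, b.tracks["hand"].pos)

    def test_artifact_perturbs_interjoint_distances(self, model, limb_model, three_strike_trial):
        from knapkin.reconstruction import reconstruct_landmarks

        traj, _, _ = three_strike_trial
        fr = rig.forward_kinematics(model, traj)
        rec = rig.render_sensor_tracks(fr, model, 0.005, 0.0, np.random.default_rng(0))
        recon = reconstruct_landmarks(rec, limb_model)
        d = np.linalg.norm(
            recon.joint_centers["elbow"] - recon.joint_centers["shoulder"], axis=1
        )
        # the imposed 5 mm drift shows up as mm-scale distance variation
        assert 5e-4 < d.std() < 1.5e-2

    def test_negative_noise_rejected(self, model):
        traj = rig.make_circumduction_trial(model, duration=0.1)
        fr = rig.forward_kinematics(model, traj)
        with pytest.raises(ValueError):
            rig.render_sensor_tracks(fr, model, noise_sd=-1.0, rng=np.random.default_rng(0))


class TestStylusCalibration:
    def test_working_point_offset_verbatim(self, model):
        cal = rig.simulate_stylus_calibration(model)
        np.testing.assert_array_equal(cal.working_point.offset, model.hammer_offset)

    def test_landmark_round_trip_at_frame_zero(self, model):
        # reconstructing landmarks from the records at any frame reproduces
        # the true positions to float precision
        cal = rig.simulate_stylus_calibration(model)
        traj = rig.make_circumduction_trial(model, duration=0.1)
        fr = rig.forward_kinematics(model, traj)
        for name, lrec in cal.landmarks.items():
            pos, quat = fr.sensors[lrec.sensor]
            from knapkin.geometry import apply_pose

            rebuilt = apply_pose(pos[0], quat[0], lrec.offset)
            np.testing.assert_allclose(rebuilt, fr.landmarks[name][0], atol=1e-12)

    def test_surface_points_lie_on_surface(self, model):
        from knapkin.geometry import apply_pose

        cal = rig.simulate_stylus_calibration(model)
        core = model.sensor_mounts["core_base"]
        for rec in cal.surface_points:
            world = apply_pose(core.position, core.quat, rec.offset)
            assert world[2] == pytest.approx(model.core_surface_height, abs=1e-12)


class TestFlakeMassModel:
    def _group(self, sigma_w=0.0, sigma_b=0.0):
        return rig.GroupSpec(
            "g", 2, 5.0, 1.0, 2.0, 0.5, 1.5, 10.0, 40.0, sigma_w, sigma_b,
            (0.75, 0.17, 0.08),
        )

    def test_zero_noise_fixed_ek_identical_masses(self):
        g = self._group()
        masses, produced = rig.simulate_flake_masses(
            g, np.full(5, 5.0), np.random.default_rng(0)
        )
        assert np.all(produced)
        assert np.allclose(masses, masses[0])
        assert masses[0] == pytest.approx(10.0)  # ek at the group mean

    def test_mass_monotone_in_delivered_energy(self):
        g = self._group()
        masses, _ = rig.simulate_flake_masses(
            g, np.array([1.0, 3.0, 5.0, 9.0]), np.random.default_rng(0)
        )
        assert np.all(np.diff(masses) > 0)

    def test_failure_probability_zero_every_strike_flakes(self):
        g = self._group(sigma_w=0.5)
        _, produced = rig.simulate_flake_masses(
            g, np.full(200, 5.0), np.random.default_rng(1), failure_prob=0.0
        )
        assert produced.all()

    def test_dispersion_ordering_recovered_under_strong_contrast(self):
        # noisy-group sample SD exceeds regular-group sample SD in >= 95%
        # of seeded replicates when the noise magnitudes differ strongly
        noisy = self._group(sigma_w=1.0)
        regular = self._group(sigma_w=0.2)
        wins = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            ek = np.full(50, 5.0)
            m_noisy, _ = rig.simulate_flake_masses(noisy, ek, r)
            m_reg, _ = rig.simulate_flake_masses(regular, ek, r)
            wins += m_noisy.std(ddof=1) > m_reg.std(ddof=1)
        assert wins >= 190


class TestBallisticTrial:
    def test_gravity_drop_energy_balance(self, model):
        # over the free-fall frames, the kinetic energy gained matches the
        # potential energy lost to 1% using 240 Hz central differences
        traj, truth = rig.make_ballistic_trial(model)
        fr = rig.forward_kinematics(model, traj)
        wp = fr.working_point
        v = np.gradient(wp, 1 / 240.0, axis=0)
        speed = np.linalg.norm(v, axis=1)
        m = model.hammer_mass
        a, b = truth.apex_frame + 2, truth.contact_frame  # interior frames
        ek_gain = 0.5 * m * (speed[b] ** 2 - speed[a] ** 2)
        ep_loss = m * rig.GRAVITY * (wp[a, 2] - wp[b, 2])
        assert ek_gain == pytest.approx(ep_loss, rel=0.01)

    def test_drop_height_matches_drop_time(self, model):
        traj, truth = rig.make_ballistic_trial(model, drop_time=0.25)
        t_drop = truth.contact_frame - truth.apex_frame
        assert t_drop == round(0.25 * 240)
        h = truth.apex_wp_height - model.core_surface_height
        assert h == pytest.approx(0.5 * rig.GRAVITY * 0.25**2, rel=1e-9)


class TestCohort:
    def test_default_cohort_structure(self):
        spec = rig.default_cohort_spec()
        assert [g.n_subjects for g in spec.groups] == [6, 6, 3, 4]
        assert spec.n_subjects == 19

    def test_minimal_single_subject_study(self):
        spec = rig.CohortSpec(
            groups=[
                rig.GroupSpec(
                    "expert", 1, 4.4, 0.0, 1.4, 0.0, 1.0,
                    12.0, 50.0, 0.0, 0.0, (0.76, 0.16, 0.08),
                )
            ],
            flakes_per_condition=1,
        )
        study = rig.simulate_cohort(spec, seed=0)
        assert len(study.subjects) == 1
        sub = study.subjects[0]
        assert len(sub.task_trials) == 1
        assert len(sub.strike_truths[0]) == 1  # success prob 1 -> one strike
        assert sub.outcomes[0].flake_produced

    def test_seeded_run_byte_identical(self, small_cohort_spec, tmp_path):
        import hashlib

        def digest(d):
            h = hashlib.sha256()
            for f in sorted(d.rglob("*")):
                if f.is_file():
                    h.update(f.name.encode())
                    h.update(f.read_bytes())
            return h.hexdigest()

        a, b = tmp_path / "a", tmp_path / "b"
        rig.simulate_cohort(small_cohort_spec, seed=9).write(a)
        rig.simulate_cohort(small_cohort_spec, seed=9).write(b)
        assert digest(a) == digest(b)

    def test_distinct_pc1_loadings_across_strikes(self, small_study):
        # per-strike primary directions drawn with jitter differ between
        # strikes of the same subject
        sub = small_study.subjects[0]
        dirs = [t.direction for truths in sub.strike_truths for t in truths]
        assert len(dirs) >= 2
        r = abs(np.corrcoef(dirs[0], dirs[1])[0, 1])
        assert r < 0.999

    def test_invalid_group_spec_rejected(self):
        with pytest.raises(ValueError):
            rig.GroupSpec(
                "g", 0, 5.0, 1.0, 2.0, 0.5, 1.5, 10.0, 40.0, 0.5, 0.5,
                (0.75, 0.17, 0.08),
            )
        with pytest.raises(ValueError):
            rig.GroupSpec(
                "g", 2, -5.0, 1.0, 2.0, 0.5, 1.5, 10.0, 40.0, 0.5, 0.5,
                (0.75, 0.17, 0.08),
            )
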
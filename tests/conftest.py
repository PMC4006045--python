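import numpy as np
import pytest

from knapkin import rig
from knapkin.calibration import build_limb_model
from knapkin.reconstruction import reconstruct_trial


@pytest.fixture(scope="session")
def model():
    """Default synthetic arm rig."""
    return rig.make_arm_model()


@pytest.fixture(scope="session")
def limb_model(model):
    """CAST product built from a noiseless calibration of the default rig."""
    cal = rig.simulate_stylus_calibration(model)
    frames = rig.forward_kinematics(model, rig.make_circumduction_trial(model))
    motion = rig.render_sensor_tracks(frames, model)
    return build_limb_model(cal, motion)


@pytest.fixture(scope="session")
def three_strike_trial(model):
    """A noiseless 3-strike trial with jittered directions and task-null
    secondary components, plus its ground truth: (trajectory, truths,
    recording)."""
    rng = np.random.default_rng(42)
    plans = []
    for ek, ep in ((12.0, 3.4), (4.2, 2.2), (4.4, 1.4)):
        d = rig.draw_strike_direction(model, rig._TEMPLATE_DIRECTION, 0.9, rng)
        seeds = [rng.standard_normal(9), rng.standard_normal(9)]
        plans.append(
            rig.StrikePlan(ek, ep, d, secondary=[(seeds[0], 0.25), (seeds[1], 0.12)])
        )
    traj, truths = rig.build_strike_trial(model, plans)
    rec = rig.render_sensor_tracks(rig.forward_kinematics(model, traj), model)
    return traj, truths, rec


@pytest.fixture(scope="session")
def reconstructed(three_strike_trial, limb_model):
    _, _, rec = three_strike_trial
    return reconstruct_trial(rec, limb_model)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """A 2-group, 2-subject-per-group cohort for fast pipeline tests."""
    return rig.CohortSpec(
        groups=[
            rig.GroupSpec(
                "uninitiated", 2, 12.30, 4.88, 3.39, 1.06, 2.2,
                3.5, 4.5, 0.85, 1.50, (0.64, 0.20, 0.16),
            ),
            rig.GroupSpec(
                "expert", 2, 4.44, 2.56, 1.37, 0.45, 1.4,
                12.0, 50.0, 0.58, 0.675, (0.76, 0.16, 0.08),
            ),
        ],
        flakes_per_condition=2,
    )


@pytest.fixture(scope="session")
def small_study(small_cohort_spec):
    return rig.simulate_cohort(small_cohort_spec, seed=5)
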
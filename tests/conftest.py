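import json

import numpy as np
import pytest

from drumpose.pose_io import N_KEYPOINTS, TrialInfo
from drumpose.synth import CohortSpec, generate_trial


def make_frame_doc(persons, hands=True):
    """Build an OpenPose-dialect JSON doc from (67, 3) person arrays."""
    people = []
    for kp in persons:
        kp = np.asarray(kp, dtype=float)
        entry = {"person_id": [-1], "pose_keypoints_2d": kp[:25].ravel().tolist()}
        if hands:
            entry["hand_left_keypoints_2d"] = kp[25:46].ravel().tolist()
            entry["hand_right_keypoints_2d"] = kp[46:67].ravel().tolist()
        people.append(entry)
    return json.dumps({"version": 1.3, "people": people})


def person_at(x, y, conf=0.8, n=N_KEYPOINTS):
    """A fully detected person whose keypoints all sit at (x, y)."""
    kp = np.zeros((n, 3))
    kp[:, 0] = x
    kp[:, 1] = y
    kp[:, 2] = conf
    return kp


@pytest.fixture
def trial_info():
    return TrialInfo(
        child_id="c0", trial_index=2, trial_type="P500", fps=30.0, order_condition=1
    )


@pytest.fixture
def clean_spec():
    """Noiseless study conditions: perfect pacing, no jitter, no corruption."""
    return CohortSpec(adaptation=1.0, motor_noise_sd_ms=0.0, pos_noise_px=0.0)


@pytest.fixture
def clean_trial(clean_spec):
    return generate_trial(clean_spec, "c0", 2, "P500", 1, 550.0, seed=7)
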
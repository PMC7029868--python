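"""Shared fixtures: small deterministic geometries and cohorts."""

import numpy as np
import pytest

from signkin.containers import (
    LANDMARK_INDEX,
    N_LANDMARKS,
    SignRecording,
    SkeletonSequence,
)
from signkin.synthetic_data import AngleTrajectorySet, forward_kinematics


def neutral_hand_positions():
    """One frame of landmarks in a simple axis-aligned pose.

    Hand frame equals the global axes: M2-M5 along +z, knuckles and palm
    in the global yz-plane (plane normal +x), forearm triad axis-aligned.
    """
    lm = {}
    lm["US"] = np.array([0.0, 0.0, -15.0])
    lm["RS"] = np.array([0.0, 0.0, 15.0])
    lm["WR"] = np.array([0.0, 0.0, 0.0])
    lm["EL"] = np.array([0.0, 250.0, -15.0])
    lm["PALM"] = np.array([0.0, -30.0, 0.0])
    z_knuckle = {1: 35.0, 2: 22.5, 3: 7.5, 4: -7.5, 5: -22.5}
    y_knuckle = {1: -25.0, 2: -60.0, 3: -60.0, 4: -60.0, 5: -60.0}
    for i in range(1, 6):
        m = np.array([0.0, y_knuckle[i], z_knuckle[i]])
        lm[f"M{i}"] = m
        # straight digits extending along -y
        lm[f"P{i}"] = m + np.array([0.0, -40.0, 0.0])
        lm[f"D{i}"] = m + np.array([0.0, -70.0, 0.0])
        lm[f"EF{i}"] = m + np.array([0.0, -95.0, 0.0])
    return lm


def positions_dict_to_array(lm: dict) -> np.ndarray:
    arr = np.zeros((N_LANDMARKS, 3))
    for name, pos in lm.items():
        arr[LANDMARK_INDEX[name]] = pos
    return arr


@pytest.fixture
def neutral_landmarks():
    return neutral_hand_positions()


def simple_trajectories(T=40, seed=0, bone_scale=1.0):
    """Smooth, anatomically valid trajectories exercising every channel."""
    tau = np.linspace(0, 1, T)
    alpha = np.zeros((T, 5))
    phi = np.zeros((T, 5))
    for i in range(4):
        alpha[:, i] = 25 * np.sin(2 * np.pi * tau + i)
    for i in range(5):
        phi[:, i] = (12 if i == 4 else 20) * np.sin(2 * np.pi * 1.3 * tau + i)
    beta = 130 + 30 * np.sin(2 * np.pi * tau[:, None] + np.arange(4))
    theta = 140 + 25 * np.sin(2 * np.pi * 0.7 * tau[:, None] + np.arange(5))
    return AngleTrajectorySet(
        alpha=alpha,
        phi=phi,
        beta=beta,
        theta=theta,
        wrist_flexion=40 * np.sin(2 * np.pi * tau),
        wrist_deviation=30 * np.sin(2 * np.pi * 0.5 * tau + 1),
        bone_scale=bone_scale,
        global_rotvec=0.3 * np.sin(2 * np.pi * tau[:, None] + np.arange(3)),
        global_translation=50 * np.sin(2 * np.pi * tau[:, None] + np.arange(3)),
    )


def make_recording(subject="S00", label="wave", T=30, seed=0):
    """A valid bimanual synthetic recording."""
    tr = simple_trajectories(T=T, seed=seed)
    right = forward_kinematics(tr, hand="right", subject_id=subject, sign_label=label)
    left_positions = right.positions + np.array([0.0, 0.0, -250.0])
    left = SkeletonSequence(
        subject_id=subject, sign_label=label, hand="left", positions=left_positions
    )
    return SignRecording(
        subject_id=subject, sign_label=label, left=left, right=right
    )


@pytest.fixture
def recording():
    return make_recording()


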
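"""Synthetic multi-subject skeleton cohorts and a forward-kinematics oracle.

The generator emulates what a depth sensor records during sign performance:
smooth multi-joint angle trajectories (sums of up to three sinusoids per
channel), constant per-subject bone lengths, per-subject amplitude/phase/
offset variability, global rigid motion of the forearm, variable raw
sequence lengths, and Gaussian landmark noise in millimetres.

Class identity lives in the sinusoid coefficients (``class_separation``
controls how far class templates sit apart, in degrees), subject identity
in per-subject perturbations (``subject_variability``) and, optionally, in
a planted per-subject additive offset (``subject_confound``) used to
demonstrate identity leakage in non-user-independent evaluation.

Forward kinematics places landmarks so that feature extraction recovers
the generating angles *exactly* (to machine precision) at zero noise:

* the forearm triad (EL, RS, US) realises the forearm frame directly;
* knuckles and palm lie in the hand frame's YZ plane and the pinky's
  proximal segment stays in that plane (its in-plane angle ``alpha5`` is
  held at 0), so the hand-frame construction — which involves P5 and RS —
  reproduces the intended frame axes exactly for any wrist angles;
* the wrist rotation is applied as Rz(flexion) Rx(deviation) with zero
  pronation, matching the Z–X–Y decomposition read back by the extractor;
* digit segments are built from the projection angles and bent by exact
  axis-angle rotations realising the requested link angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import (
    LANDMARK_INDEX,
    N_LANDMARKS,
    SignRecording,
    SkeletonSequence,
)
from .errors import ConfigError, SignkinError

# ---------------------------------------------------------------------------
# base hand geometry (mm, right-hand template; scaled per subject)

_BONE = {
    # knuckle positions in hand coordinates (x=0 plane; z spans the palm)
    "M1": (0.0, -25.0, 35.0),
    "M2": (0.0, -60.0, 22.5),
    "M3": (0.0, -60.0, 7.5),
    "M4": (0.0, -60.0, -7.5),
    "M5": (0.0, -60.0, -22.5),
    "PALM": (0.0, -30.0, 0.0),
    # segment lengths per digit: proximal (M->P), middle (P->D), distal (D->EF)
    # thumb: M1->D1 and D1->EF1 (P1 is placed midway on M1-D1)
    "proximal": (50.0, 45.0, 50.0, 47.0, 40.0),
    "middle": (0.0, 28.0, 32.0, 30.0, 25.0),
    "distal": (30.0, 22.0, 25.0, 24.0, 20.0),
    "wrist_width": 30.0,  # RS-US distance
    "forearm_length": 250.0,  # US-EL distance
}

# channel catalogue: 26 smooth scalar trajectories per hand
_CHANNELS = (
    ["wrist_flex", "wrist_dev"]
    + [f"alpha{i}" for i in (1, 2, 3, 4)]  # alpha5 is structurally 0
    + [f"phi{i}" for i in (1, 2, 3, 4, 5)]
    + [f"beta{i}" for i in (2, 3, 4, 5)]
    + [f"theta{i}" for i in (1, 2, 3, 4, 5)]
    + ["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]
)
_CH = {name: i for i, name in enumerate(_CHANNELS)}
_N_CH = len(_CHANNELS)
_N_HARMONICS = 3

# per-channel clip ranges keeping geometry well-conditioned
_CLIP_LOW = np.array(
    [-75.0, -60.0] + [-80.0] * 4 + [-55.0] * 4 + [-30.0] + [30.0] * 9
    + [-0.5] * 3 + [-120.0] * 3
)
_CLIP_HIGH = np.array(
    [75.0, 60.0] + [80.0] * 4 + [55.0] * 4 + [30.0] + [180.0] * 9
    + [0.5] * 3 + [120.0] * 3
)
# class-delta scale per channel (angles in degrees, rotations in radians, mm)
_DELTA_SCALE = np.array([1.0] * 20 + [0.01] * 3 + [1.0] * 3)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``class_separation`` is the spread (degrees) between class-template
    offsets; ``subject_variability`` the s.d. (degrees) of per-subject
    offset perturbations (amplitude/phase perturbations scale with it);
    ``subject_confound`` a per-subject additive offset magnitude (degrees)
    planted to make subject identity informative; ``noise_sd`` is Gaussian
    landmark noise in mm.
    """

    n_subjects: int = 10
    n_classes: int = 8
    repetitions_per_class: int = 10
    frame_count_range: tuple[int, int] = (60, 140)
    class_separation: float = 12.0
    subject_variability: float = 3.0
    subject_confound: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_classes, self.repetitions_per_class) < 1:
            raise ConfigError("counts must be >= 1")
        lo, hi = self.frame_count_range
        if lo < 4 or hi < lo:
            raise ConfigError("frame_count_range must be [lo, hi] with lo >= 4")
        for name in ("class_separation", "subject_variability",
                     "subject_confound", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class AngleTrajectorySet:
    """Smooth angle-vs-time curves plus bone lengths for one hand.

    Angle arrays are degrees over T frames: ``alpha``/``phi``/``theta``
    have shape (T, 5) (digits 1..5), ``beta`` (T, 4) (digits 2..5).
    ``alpha[:, 4]`` (pinky in-plane angle) must be 0 — see module notes.
    ``global_rotvec`` (radians) and ``global_translation`` (mm) carry the
    rigid forearm motion.
    """

    alpha: np.ndarray
    phi: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    wrist_flexion: np.ndarray
    wrist_deviation: np.ndarray
    bone_scale: float = 1.0
    global_rotvec: Optional[np.ndarray] = None
    global_translation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arrays = {
            "alpha": (5,), "phi": (5,), "beta": (4,), "theta": (5,),
            "wrist_flexion": (), "wrist_deviation": (),
        }
        T = None
        for name, tail in arrays.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[1:] != tail:
                raise SignkinError(f"{name} must have shape (T,{tail})")
            T = arr.shape[0] if T is None else T
            if arr.shape[0] != T:
                raise SignkinError("trajectory arrays disagree on frame count")
        if self.bone_scale <= 0:
            raise SignkinError("bone_scale must be positive")
        if np.any(self.beta < 0) or np.any(self.beta > 180) or \
           np.any(self.theta < 0) or np.any(self.theta > 180):
            raise SignkinError("link angles must lie in [0, 180] degrees")
        if np.any(np.abs(self.alpha) >= 90) or np.any(np.abs(self.phi) >= 90):
            raise SignkinError("projection angles must lie in (-90, 90) degrees")
        if np.max(np.abs(self.alpha[:, 4])) > 1e-12:
            raise SignkinError("alpha5 must be 0 (pinky proximal in palm plane)")
        if np.any(np.abs(self.wrist_deviation) >= 90):
            raise SignkinError("wrist deviation must lie in (-90, 90) degrees")

    @property
    def n_frames(self) -> int:
        return self.alpha.shape[0]


# ---------------------------------------------------------------------------
# rotation helpers (vectorised over frames)


def _rotate_about(axis: np.ndarray, angle_deg: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` (all shape (T, 3))."""
    ang = np.deg2rad(angle_deg)[:, None]
    cos, sin = np.cos(ang), np.sin(ang)
    cross = np.cross(axis, v)
    dot = np.einsum("ij,ij->i", axis, v)[:, None]
    return v * cos + cross * sin + axis * dot * (1 - cos)


def _perp_unit(reference: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Unit component of ``reference`` orthogonal to unit vectors ``w``."""
    proj = reference - np.einsum("ij,ij->i", reference, w)[:, None] * w
    norm = np.linalg.norm(proj, axis=1, keepdims=True)
    if np.any(norm < 1e-9):
        raise SignkinError("bend-axis construction degenerate (segment along Z)")
    return proj / norm


def _wrist_rotation(flexion: np.ndarray, deviation: np.ndarray) -> np.ndarray:
    """Rz(flexion) @ Rx(deviation) per frame, shape (T, 3, 3)."""
    c, a = np.deg2rad(flexion), np.deg2rad(deviation)
    cz, sz, cx, sx = np.cos(c), np.sin(c), np.cos(a), np.sin(a)
    T = flexion.shape[0]
    R = np.zeros((T, 3, 3))
    R[:, 0, 0] = cz
    R[:, 0, 1] = -sz * cx
    R[:, 0, 2] = sz * sx
    R[:, 1, 0] = sz
    R[:, 1, 1] = cz * cx
    R[:, 1, 2] = -cz * sx
    R[:, 2, 1] = sx
    R[:, 2, 2] = cx
    return R


def _rotvec_matrices(rotvec: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rotvec).as_matrix().reshape(-1, 3, 3)


# ---------------------------------------------------------------------------
# forward kinematics


def forward_kinematics(
    trajectories: AngleTrajectorySet,
    hand: str = "right",
    subject_id: str = "synthetic",
    sign_label: str = "synthetic",
) -> SkeletonSequence:
    """Construct landmark positions realising the given angle trajectories.

    The returned sequence, passed through feature extraction, reproduces
    the generating wrist, projection and link angles exactly (machine
    precision) and respects the bone lengths at every frame.
    """
    tr = trajectories
    T = tr.n_frames
    s = tr.bone_scale
    ez = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (T, 3))

    local = np.zeros((T, N_LANDMARKS, 3))

    def put(name: str, value: np.ndarray) -> None:
        local[:, LANDMARK_INDEX[name], :] = value

    # forearm triad in forearm coordinates (wrist centre at the origin)
    half_w = s * _BONE["wrist_width"] / 2.0
    us = np.array([0.0, 0.0, -half_w])
    rs = np.array([0.0, 0.0, half_w])
    el = us + np.array([0.0, s * _BONE["forearm_length"], 0.0])
    for name, point in (("US", us), ("RS", rs), ("EL", el), ("WR", np.zeros(3))):
        put(name, np.broadcast_to(point, (T, 3)))

    # hand-local landmark positions, then rotate into forearm coordinates
    Q = _wrist_rotation(tr.wrist_flexion, tr.wrist_deviation)

    hand_points: dict[str, np.ndarray] = {}
    for name in ("M1", "M2", "M3", "M4", "M5", "PALM"):
        hand_points[name] = np.broadcast_to(s * np.array(_BONE[name]), (T, 3)).copy()

    tan = lambda deg: np.tan(np.deg2rad(deg))
    for digit in range(1, 6):
        i = digit - 1
        len_prox = s * _BONE["proximal"][i]
        len_dist = s * _BONE["distal"][i]
        if digit == 1:
            # thumb planes are swapped: alpha from YZ, phi from XY
            v = np.stack(
                [tan(tr.phi[:, 0]), np.ones(T), tan(tr.alpha[:, 0])], axis=1
            )
        else:
            v = np.stack(
                [tan(tr.alpha[:, i]), np.ones(T), tan(tr.phi[:, i])], axis=1
            )
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        m = hand_points[f"M{digit}"]
        if digit == 1:
            d1 = m - len_prox * v  # M1 -> D1 segment
            w = (d1 - m) / len_prox
            axis = _perp_unit(ez, w)
            ef = d1 + len_dist * _rotate_about(axis, tr.theta[:, 0], -w)
            hand_points["D1"] = d1
            hand_points["P1"] = 0.5 * (m + d1)
            hand_points["EF1"] = ef
        else:
            len_mid = s * _BONE["middle"][i]
            p = m - len_prox * v
            w1 = (p - m) / len_prox
            axis1 = _perp_unit(ez, w1)
            d = p + len_mid * _rotate_about(axis1, 180.0 - tr.beta[:, i - 1], w1)
            w2 = (d - p) / len_mid
            axis2 = _perp_unit(ez, w2)
            ef = d + len_dist * _rotate_about(axis2, tr.theta[:, i], -w2)
            hand_points[f"P{digit}"] = p
            hand_points[f"D{digit}"] = d
            hand_points[f"EF{digit}"] = ef

    for name, pts in hand_points.items():
        put(name, np.einsum("tij,tj->ti", Q, pts))

    # global rigid motion of the whole forearm
    positions = local
    if tr.global_rotvec is not None:
        R = _rotvec_matrices(np.asarray(tr.global_rotvec, dtype=float))
        positions = np.einsum("tij,tlj->tli", R, positions)
    if tr.global_translation is not None:
        positions = positions + np.asarray(tr.global_translation, dtype=float)[:, None, :]

    return SkeletonSequence(
        subject_id=subject_id, sign_label=sign_label, hand=hand, positions=positions
    )


# ---------------------------------------------------------------------------
# cohort generation


def _draw_base_template(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Cohort-wide base trajectory template, one row per channel."""
    offsets = np.empty(_N_CH)
    offsets[_CH["wrist_flex"]] = rng.uniform(-25, 25)
    offsets[_CH["wrist_dev"]] = rng.uniform(-20, 20)
    for i in (1, 2, 3, 4):
        offsets[_CH[f"alpha{i}"]] = rng.uniform(-35, 35)
    for i in range(1, 6):
        offsets[_CH[f"phi{i}"]] = rng.uniform(-20, 20)
    for i in range(2, 6):
        offsets[_CH[f"beta{i}"]] = rng.uniform(100, 160)
    for i in range(1, 6):
        offsets[_CH[f"theta{i}"]] = rng.uniform(100, 160)
    for ax in ("x", "y", "z"):
        offsets[_CH[f"rot_{ax}"]] = rng.uniform(-0.15, 0.15)
        offsets[_CH[f"trans_{ax}"]] = rng.uniform(-30, 30)

    amps = rng.uniform(5, 18, size=(_N_CH, _N_HARMONICS))
    amps /= np.arange(1, _N_HARMONICS + 1)  # higher harmonics weaker
    for ax in ("x", "y", "z"):
        amps[_CH[f"rot_{ax}"]] = rng.uniform(0.03, 0.15, _N_HARMONICS)
        amps[_CH[f"trans_{ax}"]] = rng.uniform(10, 35, _N_HARMONICS)
    phases = rng.uniform(0, 2 * np.pi, size=(_N_CH, _N_HARMONICS))
    freqs = rng.uniform(0.3, 2.2, size=(_N_CH, _N_HARMONICS))
    return {"offsets": offsets, "amps": amps, "phases": phases, "freqs": freqs}


def _class_template(
    base: dict[str, np.ndarray], separation: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    scale = _DELTA_SCALE
    return {
        "offsets": base["offsets"] + separation * scale * rng.standard_normal(_N_CH),
        "amps": base["amps"]
        + 0.3 * separation * scale[:, None]
        * rng.standard_normal((_N_CH, _N_HARMONICS)),
        "phases": base["phases"]
        + 0.04 * separation * rng.standard_normal((_N_CH, _N_HARMONICS)),
        "freqs": base["freqs"]
        + 0.01 * separation * rng.standard_normal((_N_CH, _N_HARMONICS)),
    }


def _subject_perturbation(sv: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        "offsets": sv * _DELTA_SCALE * rng.standard_normal(_N_CH),
        "amp_factor": np.clip(
            1.0 + (sv / 30.0) * rng.standard_normal(_N_CH), 0.2, None
        ),
        "phases": (sv * np.pi / 180.0) * rng.standard_normal((_N_CH, _N_HARMONICS)),
    }


def _evaluate_channels(
    template: dict[str, np.ndarray],
    perturb: dict[str, np.ndarray],
    confound: np.ndarray,
    rep_jitter: dict[str, np.ndarray],
    n_frames: int,
) -> np.ndarray:
    """Channel values, shape (T, n_channels), clipped to valid ranges."""
    tau = np.linspace(0.0, 1.0, n_frames)[:, None, None]  # (T, 1, 1)
    amps = template["amps"] * perturb["amp_factor"][:, None]
    phases = template["phases"] + perturb["phases"] + rep_jitter["phases"]
    waves = amps[None] * np.sin(
        2 * np.pi * template["freqs"][None] * tau + phases[None]
    )
    values = (
        template["offsets"]
        + perturb["offsets"]
        + confound
        + rep_jitter["offsets"]
        + waves.sum(axis=2)
    )
    return np.clip(values, _CLIP_LOW, _CLIP_HIGH)


def _trajectories_from_channels(
    values: np.ndarray, bone_scale: float
) -> AngleTrajectorySet:
    T = values.shape[0]
    alpha = np.zeros((T, 5))
    phi = np.zeros((T, 5))
    for i in (1, 2, 3, 4):
        alpha[:, i - 1] = values[:, _CH[f"alpha{i}"]]
    for i in range(1, 6):
        phi[:, i - 1] = values[:, _CH[f"phi{i}"]]
    beta = np.stack([values[:, _CH[f"beta{i}"]] for i in range(2, 6)], axis=1)
    theta = np.stack([values[:, _CH[f"theta{i}"]] for i in range(1, 6)], axis=1)
    rotvec = np.stack([values[:, _CH[f"rot_{ax}"]] for ax in "xyz"], axis=1)
    trans = np.stack([values[:, _CH[f"trans_{ax}"]] for ax in "xyz"], axis=1)
    return AngleTrajectorySet(
        alpha=alpha,
        phi=phi,
        beta=beta,
        theta=theta,
        wrist_flexion=values[:, _CH["wrist_flex"]],
        wrist_deviation=values[:, _CH["wrist_dev"]],
        bone_scale=bone_scale,
        global_rotvec=rotvec,
        global_translation=trans,
    )


def generate_cohort(spec: CohortSpec) -> list[SignRecording]:
    """Generate a labelled cohort of bimanual recordings.

    Returns ``n_subjects * n_classes * repetitions_per_class`` recordings
    with exactly balanced labels; deterministic given ``spec.seed``.  The
    per-subject confound offsets are always drawn (and scaled by
    ``spec.subject_confound``) so that cohorts generated from the same seed
    with different confound magnitudes differ only by the planted offsets.
    """
    rng = np.random.default_rng(spec.seed)
    base = {hand: _draw_base_template(rng) for hand in ("right", "left")}
    classes = [f"sign{c:02d}" for c in range(spec.n_classes)]
    templates = {
        (hand, c): _class_template(base[hand], spec.class_separation, rng)
        for c in range(spec.n_classes)
        for hand in ("right", "left")
    }

    recordings: list[SignRecording] = []
    for si in range(spec.n_subjects):
        subject = f"S{si:02d}"
        bone_scale = float(
            np.clip(1.0 + (spec.subject_variability / 100.0)
                    * rng.standard_normal(), 0.5, 1.5)
        )
        perturb = {h: _subject_perturbation(spec.subject_variability, rng)
                   for h in ("right", "left")}
        confound = {
            h: spec.subject_confound * _DELTA_SCALE * rng.standard_normal(_N_CH)
            for h in ("right", "left")
        }
        # per-repetition draws shared across classes so that a cohort with
        # zero separation/variability/noise carries no class signal at all
        rep_draws = []
        for _ in range(spec.repetitions_per_class):
            n_frames = int(rng.integers(spec.frame_count_range[0],
                                        spec.frame_count_range[1] + 1))
            jitter = {
                h: {
                    "offsets": 0.3 * spec.subject_variability * _DELTA_SCALE
                    * rng.standard_normal(_N_CH),
                    "phases": 0.3 * (spec.subject_variability * np.pi / 180.0)
                    * rng.standard_normal((_N_CH, _N_HARMONICS)),
                }
                for h in ("right", "left")
            }
            rep_draws.append((n_frames, jitter))

        for c, label in enumerate(classes):
            for rep, (n_frames, jitter) in enumerate(rep_draws):
                seqs = {}
                for hand in ("right", "left"):
                    values = _evaluate_channels(
                        templates[(hand, c)], perturb[hand], confound[hand],
                        jitter[hand], n_frames,
                    )
                    traj = _trajectories_from_channels(values, bone_scale)
                    if hand == "left":
                        # place the left forearm beside the right one
                        traj.global_translation = (
                            traj.global_translation + np.array([0.0, 0.0, -250.0])
                        )
                    seq = forward_kinematics(
                        traj, hand=hand, subject_id=subject, sign_label=label
                    )
                    noise = spec.noise_sd * rng.standard_normal(seq.positions.shape)
                    seq.positions = seq.positions + noise
                    seqs[hand] = seq
                recordings.append(
                    SignRecording(
                        subject_id=subject,
                        sign_label=label,
                        repetition=rep,
                        left=seqs["left"],
                        right=seqs["right"],
                    )
                )
    return recordings


def planted_confound_cohort(spec: CohortSpec) -> list[SignRecording]:
    """Cohort with subject-level offsets planted into the trajectories.

    Requires ``spec.subject_confound > 0``; makes subject identity
    informative, so evaluation protocols that let subjects straddle
    train/test (the holdout method) overestimate accuracy relative to
    user-independent testing.
    """
    if spec.subject_confound <= 0:
        raise ConfigError("planted_confound_cohort requires subject_confound > 0")
    return generate_cohort(spec)
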
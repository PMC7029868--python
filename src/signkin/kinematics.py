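"""Kinematic feature model of the forearm/hand/finger system.

Per time frame and per hand, 30 scalar features are computed from the 25
named landmarks:

* ``d1..d4``   — Euclidean distances between successive fingertips
  (EF1–EF2, EF2–EF3, EF3–EF4, EF4–EF5), mm;
* ``d5..d9``   — distances between each fingertip EFi and the palm centre, mm;
* ``wrist_flex``, ``wrist_dev`` — flexion/extension and radial/ulnar
  deviation of the hand relative to the forearm, from an intrinsic Z–X–Y
  Euler decomposition of the relative frame rotation (the Y/pronation angle
  is discarded), degrees;
* ``alpha1..alpha5``, ``phi1..phi5`` — orientation of each digit's proximal
  segment relative to the hand frame, as signed angles of its planar
  projections.  Fingers (i=2–5) use segment (Mi − Pi): alpha in the hand XY
  plane, phi in the YZ plane.  The thumb uses segment (M1 − D1) with the
  planes swapped (alpha from YZ, phi from XY), degrees;
* ``beta2..beta5`` — interior angle at Pi between (Pi − Di) and (Pi − Mi);
* ``theta1..theta5`` — angle at Di between (EFi − Di) and (Pi − Di) for
  fingers, and between (EF1 − D1) and (M1 − D1) for the thumb, degrees,
  range [0, 180].

The hand frame has Z along (M2 − M5), X normal to the plane of (M2 − RS)
and (P5 − RS), Y = Z x X, origin at PALM.  The forearm frame has Y along
(EL − US), X = Y x (RS − US) normalised, Z = X x Y, origin at WR.  Both are
re-orthonormalised so the returned axes are orthogonal and right-handed to
machine precision.

All features are relative angles and distances: a global rigid motion of
all landmarks leaves every feature unchanged, and a uniform scaling scales
only the distances.

Signed-angle convention: projected angles are measured from the hand Y axis
toward +X in the XY plane and toward +Z in the YZ plane (``atan2`` order),
in (−180, 180].  Degenerate projections (zero-length) yield 0 and a flag
rather than an error, so a single sensor dropout does not destroy a
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .containers import (
    FEATURE_GROUPS,
    FeatureMatrix,
    LANDMARK_INDEX,
    N_LANDMARKS,
    SignRecording,
)
from .errors import SingularGeometryError

_EPS = 1e-12
_GIMBAL_TOL = 1e-6

LandmarkSet = Union[Mapping[str, np.ndarray], np.ndarray]

# ---------------------------------------------------------------------------
# feature-column catalogue

_PER_HAND_FEATURES: tuple[tuple[str, str], ...] = (
    tuple((f"d{j}", "ef_distance") for j in range(1, 5))
    + tuple((f"d{j}", "palm_distance") for j in range(5, 10))
    + (("wrist_flex", "hand_forearm"), ("wrist_dev", "hand_forearm"))
    + tuple((f"alpha{i}", "digit_orientation") for i in range(1, 6))
    + tuple((f"phi{i}", "digit_orientation") for i in range(1, 6))
    + tuple((f"beta{i}", "digit_link") for i in range(2, 6))
    + tuple((f"theta{i}", "digit_link") for i in range(1, 6))
)

#: fixed documented column order: right hand then left hand
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{side}_{name}" for side in ("R", "L") for name, _ in _PER_HAND_FEATURES
)
FEATURE_GROUP_TAGS: tuple[str, ...] = tuple(
    group for _ in ("R", "L") for _, group in _PER_HAND_FEATURES
)
N_FEATURES = len(FEATURE_COLUMNS)  # 60

assert set(FEATURE_GROUP_TAGS) == set(FEATURE_GROUPS)


@dataclass
class CoordinateFrame:
    """A right-handed orthonormal frame (unit axes + origin, mm)."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        for name in ("X", "Y", "Z", "origin"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        axes = np.stack([self.X, self.Y, self.Z])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise SingularGeometryError("frame axes are not orthonormal")
        if not np.isclose(np.cross(self.X, self.Y) @ self.Z, 1.0, atol=1e-9):
            raise SingularGeometryError("frame is not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-local rotation matrix with columns (X, Y, Z)."""
        return np.column_stack([self.X, self.Y, self.Z])


# ---------------------------------------------------------------------------
# landmark access helpers


def _as_position_array(landmarks: LandmarkSet) -> np.ndarray:
    """Coerce a landmark mapping or array to shape (..., 25, 3)."""
    if isinstance(landmarks, Mapping):
        arr = np.full((N_LANDMARKS, 3), np.nan)
        for name, pos in landmarks.items():
            arr[LANDMARK_INDEX[name]] = np.asarray(pos, dtype=float)
        return arr
    arr = np.asarray(landmarks, dtype=float)
    if arr.shape[-2:] != (N_LANDMARKS, 3):
        raise SingularGeometryError(
            f"landmark array must end with shape ({N_LANDMARKS}, 3), got {arr.shape}"
        )
    return arr


def _lm(positions: np.ndarray, name: str) -> np.ndarray:
    return positions[..., LANDMARK_INDEX[name], :]


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < _EPS):
        raise SingularGeometryError(f"degenerate geometry: zero-length {what}")
    return v / norm


# ---------------------------------------------------------------------------
# coordinate frames (vectorised over leading axes)


def _hand_rotation(positions: np.ndarray) -> np.ndarray:
    """Hand-frame rotation matrices (..., 3, 3), columns (X, Y, Z)."""
    m2, m5 = _lm(positions, "M2"), _lm(positions, "M5")
    rs, p5 = _lm(positions, "RS"), _lm(positions, "P5")
    z = _unit(m2 - m5, "hand Z axis (M2 - M5)")
    normal = np.cross(m2 - rs, p5 - rs)
    x_t = _unit(normal, "hand plane normal ((M2-RS) x (P5-RS))")
    y = _unit(np.cross(z, x_t), "hand Y axis (Z x X)")
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def _forearm_rotation(positions: np.ndarray) -> np.ndarray:
    el, us, rs = _lm(positions, "EL"), _lm(positions, "US"), _lm(positions, "RS")
    y = _unit(el - us, "forearm Y axis (EL - US)")
    x = _unit(np.cross(y, rs - us), "forearm X axis (Y x (RS - US))")
    z = np.cross(x, y)
    return np.stack([x, y, z], axis=-1)


def build_hand_frame(landmarks: LandmarkSet) -> CoordinateFrame:
    """Hand coordinate frame from one frame's landmarks (origin at PALM)."""
    positions = _as_position_array(landmarks)
    rot = _hand_rotation(positions)
    return CoordinateFrame(
        X=rot[..., 0], Y=rot[..., 1], Z=rot[..., 2], origin=_lm(positions, "PALM")
    )


def build_forearm_frame(landmarks: LandmarkSet) -> CoordinateFrame:
    """Forearm coordinate frame from one frame's landmarks (origin at WR)."""
    positions = _as_position_array(landmarks)
    rot = _forearm_rotation(positions)
    return CoordinateFrame(
        X=rot[..., 0], Y=rot[..., 1], Z=rot[..., 2], origin=_lm(positions, "WR")
    )


# ---------------------------------------------------------------------------
# wrist Euler angles


def _wrist_angles_from_rotations(
    hand_rot: np.ndarray, forearm_rot: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intrinsic Z–X–Y decomposition of the hand-in-forearm rotation.

    Returns (flexion, deviation, gimbal_flag); the Y angle is discarded
    (set to zero by the decomposition at gimbal lock).
    """
    rel = np.swapaxes(forearm_rot, -1, -2) @ hand_rot
    single = rel.ndim == 2
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # gimbal warning -> flag
        euler = Rotation.from_matrix(rel).as_euler("ZXY", degrees=True)
    euler = np.atleast_2d(euler)
    flexion, deviation = euler[:, 0], euler[:, 1]
    gimbal = np.abs(np.abs(deviation) - 90.0) < _GIMBAL_TOL
    if single:
        return flexion[0], deviation[0], bool(gimbal[0])
    return flexion, deviation, gimbal


def wrist_angles(
    hand: CoordinateFrame, forearm: CoordinateFrame, return_flags: bool = False
):
    """Wrist flexion/extension and radial/ulnar deviation, degrees."""
    flexion, deviation, gimbal = _wrist_angles_from_rotations(
        hand.rotation, forearm.rotation
    )
    if return_flags:
        return (flexion, deviation), {"gimbal": gimbal}
    return flexion, deviation


# ---------------------------------------------------------------------------
# digit orientation angles


def _projection_angle(
    a: np.ndarray, b: np.ndarray, scale: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Signed angle atan2(a, b) in degrees; flag where the projection vanishes."""
    degenerate = np.hypot(a, b) < 1e-9 * np.maximum(scale, 1.0)
    angle = np.degrees(np.arctan2(a, b))
    return np.where(degenerate, 0.0, angle), degenerate


def digit_orientation_angles(landmarks: LandmarkSet, hand_frame=None, return_flags=False):
    """Per-digit projection angles alpha_1..5 and phi_1..5, degrees.

    ``hand_frame`` may be a :class:`CoordinateFrame` or a rotation-matrix
    stack; if omitted it is built from the landmarks.
    """
    positions = _as_position_array(landmarks)
    if hand_frame is None:
        rot = _hand_rotation(positions)
    elif isinstance(hand_frame, CoordinateFrame):
        rot = hand_frame.rotation
    else:
        rot = np.asarray(hand_frame, dtype=float)

    alphas, phis, flags = [], [], []
    for i in range(1, 6):
        if i == 1:
            seg = _lm(positions, "M1") - _lm(positions, "D1")
        else:
            seg = _lm(positions, f"M{i}") - _lm(positions, f"P{i}")
        local = np.einsum("...ji,...j->...i", rot, seg)
        vx, vy, vz = local[..., 0], local[..., 1], local[..., 2]
        scale = np.linalg.norm(local, axis=-1)
        if i == 1:  # thumb: planes swapped relative to the fingers
            alpha, a_flag = _projection_angle(vz, vy, scale)
            phi, p_flag = _projection_angle(vx, vy, scale)
        else:
            alpha, a_flag = _projection_angle(vx, vy, scale)
            phi, p_flag = _projection_angle(vz, vy, scale)
        alphas.append(alpha)
        phis.append(phi)
        flags.append((a_flag, p_flag))

    alpha_arr = np.stack(alphas, axis=-1)
    phi_arr = np.stack(phis, axis=-1)
    if return_flags:
        degenerate = {
            f"alpha{i + 1}": flags[i][0] for i in range(5)
        } | {f"phi{i + 1}": flags[i][1] for i in range(5)}
        return alpha_arr, phi_arr, degenerate
    return alpha_arr, phi_arr


# ---------------------------------------------------------------------------
# link (interphalangeal) angles


def _vector_angle(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned angle between vectors in degrees via atan2(|u x v|, u.v)."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    degenerate = (nu < _EPS) | (nv < _EPS)
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.einsum("...i,...i->...", u, v)
    angle = np.degrees(np.arctan2(cross, dot))
    return np.where(degenerate, 0.0, angle), degenerate


def link_angles(landmarks: LandmarkSet, return_flags: bool = False):
    """Interphalangeal angles beta_2..5 and theta_1..5, degrees in [0, 180]."""
    positions = _as_position_array(landmarks)
    betas, thetas, flags = [], [], {}
    for i in range(2, 6):
        p = _lm(positions, f"P{i}")
        beta, flag = _vector_angle(
            p - _lm(positions, f"D{i}"), p - _lm(positions, f"M{i}")
        )
        betas.append(beta)
        flags[f"beta{i}"] = flag
    d1 = _lm(positions, "D1")
    theta1, flag1 = _vector_angle(
        _lm(positions, "EF1") - d1, _lm(positions, "M1") - d1
    )
    thetas.append(theta1)
    flags["theta1"] = flag1
    for i in range(2, 6):
        d = _lm(positions, f"D{i}")
        theta, flag = _vector_angle(
            _lm(positions, f"EF{i}") - d, _lm(positions, f"P{i}") - d
        )
        thetas.append(theta)
        flags[f"theta{i}"] = flag
    beta_arr = np.stack(betas, axis=-1)
    theta_arr = np.stack(thetas, axis=-1)
    if return_flags:
        return beta_arr, theta_arr, flags
    return beta_arr, theta_arr


# ---------------------------------------------------------------------------
# fingertip distances


def ef_distances(landmarks: LandmarkSet) -> np.ndarray:
    """Distances d_1..d_9 (mm): successive fingertips, then fingertip-to-palm."""
    positions = _as_position_array(landmarks)
    efs = [_lm(positions, f"EF{i}") for i in range(1, 6)]
    palm = _lm(positions, "PALM")
    successive = [
        np.linalg.norm(efs[i] - efs[i + 1], axis=-1) for i in range(4)
    ]
    to_palm = [np.linalg.norm(ef - palm, axis=-1) for ef in efs]
    return np.stack(successive + to_palm, axis=-1)


# ---------------------------------------------------------------------------
# full feature extraction


def _hand_features(positions: np.ndarray) -> np.ndarray:
    """30 features per frame for one hand; positions shape (T, 25, 3)."""
    hand_rot = _hand_rotation(positions)
    fore_rot = _forearm_rotation(positions)
    flexion, deviation, _ = _wrist_angles_from_rotations(hand_rot, fore_rot)
    alpha, phi = digit_orientation_angles(positions, hand_frame=hand_rot)
    beta, theta = link_angles(positions)
    d = ef_distances(positions)
    return np.concatenate(
        [d, flexion[:, None], deviation[:, None], alpha, phi, beta, theta], axis=1
    )


def extract_features(recording: SignRecording) -> FeatureMatrix:
    """Raw T x 60 feature matrix for a bimanual recording.

    Right-hand columns first, then left-hand columns, in the documented
    order (:data:`FEATURE_COLUMNS`), each tagged with its standardisation
    group.  Singular geometry is reported with the offending frame index.
    """
    blocks = []
    for side, seq in (("right", recording.right), ("left", recording.left)):
        try:
            blocks.append(_hand_features(seq.positions))
        except SingularGeometryError:
            # re-run frame by frame to locate the first bad frame
            for t in range(seq.n_frames):
                try:
                    _hand_features(seq.positions[t : t + 1])
                except SingularGeometryError as exc:
                    raise SingularGeometryError(
                        f"{side} hand, frame {t}: {exc}"
                    ) from exc
            raise
    values = np.concatenate(blocks, axis=1)
    return FeatureMatrix(
        values=values,
        columns=FEATURE_COLUMNS,
        groups=FEATURE_GROUP_TAGS,
        subject_id=recording.subject_id,
        sign_label=recording.sign_label,
    )
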
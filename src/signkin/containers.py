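"""Core in-memory containers: skeleton sequences, recordings, feature matrices.

Landmark model
--------------
Each hand is described by 25 named landmarks, five per digit plus five
forearm/hand reference points:

* ``EF1..EF5`` — finger/thumb end effectors (tips); digit 1 is the thumb,
  2 the index, 3 the middle, 4 the ring and 5 the pinky,
* ``M1..M5``  — metacarpophalangeal (knuckle) joints,
* ``P1..P5``  — proximal interphalangeal joints,
* ``D1..D5``  — distal interphalangeal joints,
* ``EL``      — elbow, ``WR`` — wrist, ``RS`` — radial styloid,
  ``US`` — ulnar styloid, ``PALM`` — palm centre.

Positions are 3-vectors in millimetres in the sensor frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DialectError, SignkinError

DIGITS = (1, 2, 3, 4, 5)

LANDMARK_NAMES: tuple[str, ...] = tuple(
    f"{prefix}{i}" for prefix in ("EF", "M", "P", "D") for i in DIGITS
) + ("EL", "WR", "RS", "US", "PALM")

LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARK_NAMES)}

N_LANDMARKS = len(LANDMARK_NAMES)  # 25 per hand

HANDS = ("left", "right")

#: Standardisation groups, in the fixed documented order.
FEATURE_GROUPS = (
    "ef_distance",
    "palm_distance",
    "hand_forearm",
    "digit_orientation",
    "digit_link",
)


@dataclass
class Landmark:
    """A single named landmark with a finite 3-D position in mm."""

    name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in LANDMARK_INDEX:
            raise DialectError(f"unknown landmark name {self.name!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise DialectError(f"landmark {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise DialectError(f"landmark {self.name}: non-finite position")


@dataclass
class SkeletonSequence:
    """Time-ordered landmark positions of one hand for one sign performance.

    ``positions`` has shape ``(T, 25, 3)`` with the landmark axis ordered as
    :data:`LANDMARK_NAMES`.
    """

    subject_id: str
    sign_label: str
    hand: str
    positions: np.ndarray
    timestamps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise SignkinError(f"hand must be one of {HANDS}, got {self.hand!r}")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (N_LANDMARKS, 3):
            raise SignkinError(
                f"positions must have shape (T, {N_LANDMARKS}, 3), "
                f"got {self.positions.shape}"
            )
        if self.n_frames < 4:
            raise SignkinError(
                f"sequence must have >= 4 frames for cubic-spline resampling, "
                f"got {self.n_frames}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise SignkinError("positions contain non-finite values")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.n_frames,):
                raise SignkinError("timestamps length must equal frame count")
            if not np.all(np.diff(self.timestamps) > 0):
                raise SignkinError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def landmark(self, name: str) -> np.ndarray:
        """Positions of one landmark over time, shape ``(T, 3)``."""
        return self.positions[:, LANDMARK_INDEX[name], :]

    def frame(self, t: int) -> np.ndarray:
        """All landmark positions at frame ``t``, shape ``(25, 3)``."""
        return self.positions[t]


@dataclass
class SignRecording:
    """A bimanual sign performance: left and right hand sequences."""

    subject_id: str
    sign_label: str
    left: SkeletonSequence
    right: SkeletonSequence
    repetition: int = 0

    def __post_init__(self) -> None:
        if self.left.hand != "left" or self.right.hand != "right":
            raise SignkinError("left/right sequences carry the wrong hand tag")
        if self.left.n_frames != self.right.n_frames:
            raise SignkinError(
                "left and right sequences must have equal frame counts "
                f"({self.left.n_frames} != {self.right.n_frames})"
            )
        for seq in (self.left, self.right):
            if seq.subject_id != self.subject_id or seq.sign_label != self.sign_label:
                raise SignkinError("hand sequences disagree on subject_id/sign_label")

    @property
    def n_frames(self) -> int:
        return self.left.n_frames


@dataclass
class FeatureMatrix:
    """An ``m x n`` time-series feature matrix for one sign performance.

    Columns are tagged with one of the five standardisation groups
    (:data:`FEATURE_GROUPS`).  ``role`` optionally tags the sample as
    train/validation/test for leakage enforcement.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    groups: tuple[str, ...]
    subject_id: str = ""
    sign_label: str = ""
    role: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.columns = tuple(self.columns)
        self.groups = tuple(self.groups)
        if self.values.ndim != 2:
            raise SignkinError("feature values must be a 2-D matrix")
        n = self.values.shape[1]
        if len(self.columns) != n or len(self.groups) != n:
            raise SignkinError("columns/groups length must match the matrix width")
        unknown = set(self.groups) - set(FEATURE_GROUPS)
        if unknown:
            raise SignkinError(f"unknown feature groups: {sorted(unknown)}")
        if self.role not in (None, "train", "val", "test"):
            raise SignkinError(f"invalid role tag {self.role!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Copy of this matrix with new values, metadata unchanged."""
        return replace(self, values=np.asarray(values, dtype=float))

    def with_role(self, role: Optional[str]) -> "FeatureMatrix":
        return replace(self, role=role)


@dataclass
class SubjectDataset:
    """All labelled feature matrices of one subject."""

    subject_id: str
    samples: list[tuple[FeatureMatrix, str]] = field(default_factory=list)
    label_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.label_set = tuple(self.label_set)
        for matrix, label in self.samples:
            if matrix.subject_id != self.subject_id:
                raise SignkinError(
                    f"sample subject_id {matrix.subject_id!r} does not match "
                    f"dataset subject {self.subject_id!r}"
                )
            if self.label_set and label not in self.label_set:
                raise SignkinError(f"label {label!r} not in label_set")

    def labels(self) -> list[str]:
        return [label for _, label in self.samples]

    def __len__(self) -> int:
        return len(self.samples)


def stack_features(samples: Sequence[FeatureMatrix]) -> np.ndarray:
    """Stack equally-shaped feature matrices into an ``(n, m, f)`` array."""
    if not samples:
        return np.empty((0, 0, 0))
    shapes = {s.values.shape for s in samples}
    if len(shapes) > 1:
        raise SignkinError(f"cannot stack feature matrices of shapes {shapes}")
    return np.stack([s.values for s in samples])
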
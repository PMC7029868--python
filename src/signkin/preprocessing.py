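"""Resampling to a fixed frame count and group-wise standardisation.

Every sign performance, whatever its raw duration, is interpolated to a
fixed ``m = 100`` frames with a cubic spline over normalised time [0, 1]
(not-a-knot boundary, so polynomials up to cubic are reproduced exactly),
then standardised: each entry is replaced by ``(f - mu_g) / sigma_g`` where
``g`` is the column's feature group (fingertip distances, palm distances,
hand-forearm angles, digit orientation, digit link angles).

Two standardisation scopes are supported:

* ``training_set`` (default) — moments pooled over the training subjects
  only and applied to validation/test data, so no test statistics leak
  into the model;
* ``per_instance`` — each matrix standardised by its own group moments.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FEATURE_GROUPS, FeatureMatrix, SubjectDataset
from .errors import ConfigError, SignkinError, TooShortError
from .kinematics import extract_features

TARGET_FRAMES = 100
SIGMA_FLOOR = 1e-8

GroupStats = dict[str, tuple[float, float]]


def resample_to_frames(
    matrix: FeatureMatrix,
    target_m: int = TARGET_FRAMES,
    timestamps: Optional[np.ndarray] = None,
) -> FeatureMatrix:
    """Cubic-spline resample every column to ``target_m`` uniform frames.

    Input samples sit at uniform positions on [0, 1] (or at normalised
    ``timestamps`` when given); endpoints are preserved exactly.
    """
    T = matrix.n_frames
    if T < 4:
        raise TooShortError(
            f"need >= 4 frames for cubic-spline resampling, got {T}"
        )
    if timestamps is not None:
        t = np.asarray(timestamps, dtype=float)
        if t.shape != (T,) or not np.all(np.diff(t) > 0):
            raise SignkinError("timestamps must be strictly increasing, length T")
        x = (t - t[0]) / (t[-1] - t[0])
    else:
        x = np.linspace(0.0, 1.0, T)
    query = np.linspace(0.0, 1.0, target_m)
    spline = CubicSpline(x, matrix.values, axis=0)  # not-a-knot boundary
    values = spline(query)
    values[0] = matrix.values[0]
    values[-1] = matrix.values[-1]
    return matrix.with_values(values)


def _pooled_group_stats(
    matrices: Sequence[FeatureMatrix], sigma_floor: float = SIGMA_FLOOR
) -> GroupStats:
    if not matrices:
        raise SignkinError("cannot fit group stats on an empty collection")
    groups = matrices[0].groups
    for m in matrices:
        if m.groups != groups:
            raise SignkinError("all matrices must share the same group tags")
    group_arr = np.asarray(groups)
    stats: GroupStats = {}
    for g in dict.fromkeys(groups):  # preserve column order of first occurrence
        cols = group_arr == g
        pooled = np.concatenate([m.values[:, cols].ravel() for m in matrices])
        mu = float(pooled.mean())
        sigma = float(pooled.std())
        if sigma < sigma_floor:
            warnings.warn(
                f"group {g!r} is (near-)constant; sigma floored to {sigma_floor}",
                RuntimeWarning,
                stacklevel=3,
            )
            sigma = sigma_floor
        stats[g] = (mu, sigma)
    return stats


def fit_group_stats(
    datasets: Union[Sequence[SubjectDataset], Sequence[FeatureMatrix]],
) -> GroupStats:
    """Per-group (mu, sigma) pooled over all frames, columns and samples."""
    matrices: list[FeatureMatrix] = []
    for item in datasets:
        if isinstance(item, SubjectDataset):
            matrices.extend(m for m, _ in item.samples)
        else:
            matrices.append(item)
    return _pooled_group_stats(matrices)


def standardize(
    matrix: FeatureMatrix, stats: Optional[GroupStats] = None
) -> FeatureMatrix:
    """Standardise each entry by its column group's (mu, sigma).

    With ``stats`` omitted (per-instance mode) the moments are computed
    from this matrix alone, so each group of the output has mean 0 and
    standard deviation 1.
    """
    if stats is None:
        stats = _pooled_group_stats([matrix])
    missing = set(matrix.groups) - set(stats)
    if missing:
        raise SignkinError(f"stats missing groups: {sorted(missing)}")
    mu = np.array([stats[g][0] for g in matrix.groups])
    sigma = np.array([stats[g][1] for g in matrix.groups])
    return matrix.with_values((matrix.values - mu) / sigma)


class GroupStandardizer(BaseEstimator, TransformerMixin):
    """Scikit-learn-style transformer over collections of feature matrices.

    Parameters
    ----------
    mode : {"training_set", "per_instance"}
        ``training_set`` fits pooled group moments in :meth:`fit` and
        applies them in :meth:`transform`; ``per_instance`` ignores the
        fitted state and standardises each matrix by its own moments.
    """

    def __init__(self, mode: str = "training_set"):
        self.mode = mode

    def fit(self, X: Sequence[FeatureMatrix], y=None) -> "GroupStandardizer":
        if self.mode not in ("training_set", "per_instance"):
            raise ConfigError(f"unknown standardize mode {self.mode!r}")
        if self.mode == "training_set":
            self.stats_ = fit_group_stats(list(X))
        else:
            self.stats_ = None
        return self

    def transform(self, X: Sequence[FeatureMatrix]) -> list[FeatureMatrix]:
        if not hasattr(self, "stats_"):
            raise SignkinError("GroupStandardizer is not fitted")
        return [standardize(m, self.stats_) for m in X]


# ---------------------------------------------------------------------------
# labels


def build_labels(labels: Iterable[str], label_set: Sequence[str]) -> np.ndarray:
    """One-of-N binary indicator vectors, rows summing to 1."""
    label_set = list(label_set)
    index = {label: i for i, label in enumerate(label_set)}
    labels = list(labels)
    for label in labels:
        if label not in index:
            raise SignkinError(f"unknown label {label!r}")
    eye = np.eye(len(label_set))
    return eye[[index[label] for label in labels]]


def decode_labels(vectors: np.ndarray, label_set: Sequence[str]) -> list[str]:
    """Inverse of :func:`build_labels` (argmax decoding)."""
    label_set = list(label_set)
    return [label_set[i] for i in np.argmax(np.atleast_2d(vectors), axis=1)]


# ---------------------------------------------------------------------------
# cohort assembly


def build_subject_datasets(
    recordings,
    target_frames: int = TARGET_FRAMES,
    standardize_mode: Optional[str] = None,
) -> list[SubjectDataset]:
    """Extract, resample and group features by subject.

    ``standardize_mode=None`` leaves matrices unstandardised (the
    evaluation harness fits training-set statistics per fold);
    ``"per_instance"`` standardises each matrix by its own moments.
    """
    by_subject: dict[str, list[tuple[FeatureMatrix, str]]] = {}
    labels = sorted({rec.sign_label for rec in recordings})
    for rec in recordings:
        matrix = resample_to_frames(extract_features(rec), target_frames)
        if standardize_mode == "per_instance":
            matrix = standardize(matrix)
        elif standardize_mode is not None:
            raise ConfigError(
                "standardize_mode must be None or 'per_instance' here; "
                "training-set mode is applied per fold by the evaluation module"
            )
        by_subject.setdefault(rec.subject_id, []).append((matrix, rec.sign_label))
    return [
        SubjectDataset(subject_id=s, samples=samples, label_set=tuple(labels))
        for s, samples in sorted(by_subject.items())
    ]
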
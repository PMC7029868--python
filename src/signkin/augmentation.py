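"""Training-set augmentation by window (time) warping and magnitude warping.

One augmentation pass applied to a preprocessed 100x60 feature matrix:

1. *Time warp* — the 100-frame axis is cut into 10 contiguous 10-frame
   parts; each part is resampled by cubic spline to a random length
   ``p in {5..15}``; the parts are concatenated and the whole sequence is
   resampled back to 100 frames.  The same part-length draws are applied
   to all 60 columns of a sample, preserving temporal coherence between
   joints.

2. *Magnitude warp* — per column independently, a sinusoid with random
   period ``P in [0.5, 2]`` (in units of the window length), phase
   ``phi in [0, pi]`` and amplitude ``A in [-0.2, 0.2]`` is scaled by the
   column's value range (max − min) and added to it, producing a smooth
   amplitude distortion bounded by ``0.2 x range``.

The pass is repeated 40 times per training sample by default.  Matrices
tagged as validation/test are refused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import FeatureMatrix
from .errors import ConfigError, LeakageError


@dataclass
class AugmentationConfig:
    """Warping parameters; defaults are the standard procedure."""

    n_parts: int = 10
    part_len_range: tuple[int, int] = (5, 15)
    period_range: tuple[float, float] = (0.5, 2.0)
    phase_range: tuple[float, float] = (0.0, np.pi)
    amplitude_range: tuple[float, float] = (-0.2, 0.2)
    repeats: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parts < 1 or self.repeats < 1:
            raise ConfigError("n_parts and repeats must be >= 1")
        lo, hi = self.part_len_range
        if not (1 <= lo <= hi):
            raise ConfigError("part_len_range must be [lo, hi] with lo >= 1")


def _refuse_non_training(matrix: FeatureMatrix) -> None:
    if matrix.role in ("val", "test"):
        raise LeakageError(
            f"refusing to augment a matrix tagged role={matrix.role!r}; "
            "augmentation applies to training samples only"
        )


def _resample(values: np.ndarray, n_out: int) -> np.ndarray:
    """Cubic-spline resample along axis 0 to ``n_out`` uniform points."""
    n_in = values.shape[0]
    if n_in < 2:
        return np.repeat(values, n_out, axis=0)
    x = np.linspace(0.0, 1.0, n_in)
    q = np.linspace(0.0, 1.0, n_out)
    if n_in < 4:  # spline needs 4 points; fall back to linear for tiny parts
        out = np.empty((n_out, values.shape[1]))
        for j in range(values.shape[1]):
            out[:, j] = np.interp(q, x, values[:, j])
        return out
    return CubicSpline(x, values, axis=0)(q)


def time_warp(
    matrix: FeatureMatrix,
    rng: np.random.Generator,
    config: Optional[AugmentationConfig] = None,
    part_lengths: Optional[Sequence[int]] = None,
) -> FeatureMatrix:
    """Locally stretch/compress the time axis, then resample to 100 frames.

    ``part_lengths`` overrides the random draws (used for identity checks);
    otherwise one integer per part is drawn uniformly from the inclusive
    part-length range, shared across all columns.
    """
    config = config or AugmentationConfig()
    _refuse_non_training(matrix)
    m = matrix.n_frames
    if m % config.n_parts != 0:
        raise ConfigError(
            f"frame count {m} is not divisible by n_parts={config.n_parts}"
        )
    part_len = m // config.n_parts
    if part_lengths is None:
        lo, hi = config.part_len_range
        part_lengths = rng.integers(lo, hi + 1, size=config.n_parts)
    elif len(part_lengths) != config.n_parts:
        raise ConfigError("part_lengths must have one entry per part")
    pieces = []
    for k, p in enumerate(part_lengths):
        part = matrix.values[k * part_len : (k + 1) * part_len]
        pieces.append(_resample(part, int(p)))
    warped = np.concatenate(pieces, axis=0)
    return matrix.with_values(_resample(warped, m))


def magnitude_warp(
    matrix: FeatureMatrix,
    rng: np.random.Generator,
    config: Optional[AugmentationConfig] = None,
) -> FeatureMatrix:
    """Add a random low-frequency sinusoid scaled by each column's range."""
    config = config or AugmentationConfig()
    _refuse_non_training(matrix)
    m, n = matrix.values.shape
    period = rng.uniform(*config.period_range, size=n)
    phase = rng.uniform(*config.phase_range, size=n)
    amplitude = rng.uniform(*config.amplitude_range, size=n)
    t = np.arange(m)[:, None]
    wave = np.sin(2 * np.pi * t / (period * m) + phase)
    value_range = matrix.values.max(axis=0) - matrix.values.min(axis=0)
    return matrix.with_values(matrix.values + amplitude * value_range * wave)


def augment(
    matrix: FeatureMatrix,
    config: Optional[AugmentationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[FeatureMatrix]:
    """``config.repeats`` warped copies: magnitude_warp(time_warp(x)) each.

    Deterministic given ``config.seed`` (or an explicit generator).
    """
    config = config or AugmentationConfig()
    _refuse_non_training(matrix)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [
        magnitude_warp(time_warp(matrix, rng, config), rng, config)
        for _ in range(config.repeats)
    ]


class Augmenter:
    """Callable wrapper bundling a config and a seeded generator stream."""

    def __init__(self, config: Optional[AugmentationConfig] = None):
        self.config = config or AugmentationConfig()

    def __call__(
        self, matrix: FeatureMatrix, rng: Optional[np.random.Generator] = None
    ) -> list[FeatureMatrix]:
        return augment(matrix, self.config, rng)
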
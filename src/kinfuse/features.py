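"""Speech prosody indicators computed from a voiced-frame pitch track.

Three scalar indicators summarize a fundamental-frequency (f0) contour:

* ``T`` — total variation: the sum of absolute frame-to-frame f0 differences
  over the reading (Hz);
* ``A`` — average variation: T divided by the number of consecutive
  differences, i.e. T / (N − 1) (Hz);
* ``O`` — oscillation percentage: the share of adjacent difference pairs
  whose signs are strictly opposite (a sign inversion of the contour slope),
  in [0, 100].

Reduced pitch range and flattened contour dynamics are established vocal
correlates of depressive states, which is what these indicators quantify.
The module consumes voiced frames only; unvoiced gaps are assumed removed
upstream, and no audio signal processing is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ClassIntervalPartition
from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "PitchTrack", "FeatureValues", "total_variation", "average_variation",
    "oscillation_pct", "compute_features", "assign_interval",
]


@dataclass(frozen=True)
class PitchTrack:
    """A sequence of voiced-frame fundamental frequencies in Hz."""

    values: np.ndarray
    frame_period_s: float = 0.01

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("pitch track must be a 1-D sequence")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValidationError("pitch values must be finite and positive")
        if self.frame_period_s <= 0:
            raise ValidationError("frame period must be positive")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureValues:
    """The three indicators for one recording."""

    T: float
    A: float
    O: float

    def __post_init__(self):
        if self.T < 0 or self.A < 0 or not 0 <= self.O <= 100:
            raise ValidationError("invalid feature values")


def _diffs(track: PitchTrack, minimum: int) -> np.ndarray:
    if len(track) < minimum:
        raise InsufficientDataError(
            f"need at least {minimum} voiced frames, got {len(track)}"
        )
    return np.diff(track.values)


def total_variation(track: PitchTrack) -> float:
    """Sum of absolute consecutive pitch differences (Hz)."""
    return float(np.abs(_diffs(track, 2)).sum())


def average_variation(track: PitchTrack) -> float:
    """Total variation per consecutive difference: T / (N − 1) (Hz)."""
    d = _diffs(track, 2)
    return float(np.abs(d).sum() / d.size)


def oscillation_pct(track: PitchTrack) -> float:
    """Percentage of adjacent difference pairs with strictly opposite signs.

    A zero difference carries no sign: a pair containing one counts as no
    inversion but remains in the denominator, keeping O defined (and
    conservative) on plateaued tracks.
    """
    d = _diffs(track, 3)
    signs = np.sign(d)
    inversions = signs[:-1] * signs[1:] < 0
    return float(100.0 * inversions.sum() / inversions.size)


def compute_features(track: PitchTrack) -> FeatureValues:
    """All three indicators at once (single pass over the differences)."""
    d = _diffs(track, 3)
    t = float(np.abs(d).sum())
    signs = np.sign(d)
    inv = signs[:-1] * signs[1:] < 0
    return FeatureValues(t, t / d.size, float(100.0 * inv.sum() / inv.size))


def assign_interval(value: float, partition: ClassIntervalPartition) -> int:
    """Index of the partition interval containing ``value``.

    Shared endpoints resolve to the central (class-0) interval and the outer
    flanks are unbounded, so every finite value is covered.
    """
    return partition.assign(float(value))
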
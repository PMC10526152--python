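"""Synthetic reference cohorts and pitch tracks.

Every pipeline stage is testable without external data:

* :func:`generate_cohort` draws a labeled two-class cohort whose per-class
  feature distributions are explicit (normal, or a two-component normal
  mixture for the bimodal flank structure implied by split class-1
  intervals).  The shipped default emulates the depression pilot cohort
  (11 healthy + 11 depressed subjects, features T/A/O): its distribution
  parameters are solved so that the analytic probability of each class
  falling in its central interval matches the pilot contingency proportions.
* :func:`generate_pitch` builds an f0 contour whose slope sign flips with a
  specified probability at each frame, so the oscillation indicator O
  converges to 100 × that probability; magnitudes are uniform jumps.

One explicit seed is threaded through all draws; no global generator state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import ReferenceCohort
from .exceptions import ValidationError
from .features import PitchTrack

__all__ = [
    "Normal", "Mixture", "CohortSpec", "PitchSpec",
    "DEFAULT_COHORT_SPEC", "generate_cohort", "generate_pitch",
]


def _norm_cdf(x: float, mean: float, sd: float) -> float:
    return 0.5 * (1.0 + math.erf((x - mean) / (sd * math.sqrt(2.0))))


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValidationError("sd must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size)

    def interval_probability(self, lo: float, hi: float) -> float:
        return _norm_cdf(hi, self.mean, self.sd) - _norm_cdf(lo, self.mean, self.sd)


@dataclass(frozen=True)
class Mixture:
    """Weighted mixture of normal components."""

    components: tuple[tuple[float, Normal], ...]

    def __post_init__(self):
        if not self.components:
            raise ValidationError("mixture needs at least one component")
        if any(w < 0 for w, _ in self.components):
            raise ValidationError("mixture weights must be non-negative")
        total = sum(w for w, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        weights = np.array([w for w, _ in self.components])
        idx = rng.choice(len(self.components), size=size, p=weights / weights.sum())
        out = np.empty(size)
        for i, (_, comp) in enumerate(self.components):
            mask = idx == i
            out[mask] = comp.sample(rng, int(mask.sum()))
        return out

    def interval_probability(self, lo: float, hi: float) -> float:
        return sum(w * c.interval_probability(lo, hi) for w, c in self.components)


@dataclass(frozen=True)
class CohortSpec:
    """Class sizes plus one distribution per (class, feature), and a seed."""

    class_sizes: tuple[int, ...]
    distributions: dict[str, tuple[Normal | Mixture, ...]]  # feature -> per class
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.class_sizes):
            raise ValidationError("class sizes must be >= 1")
        for feat, dists in self.distributions.items():
            if len(dists) != len(self.class_sizes):
                raise ValidationError(
                    f"feature {feat!r}: need one distribution per class"
                )

    def with_sizes(self, *sizes: int) -> "CohortSpec":
        return replace(self, class_sizes=tuple(sizes))

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


# Default spec emulating the pilot cohort. Central-interval probabilities are
# tuned analytically to the pilot contingency proportions:
#   T: P(I0|C0)=7/11, P(I0|C1)=2/11 with I0=[285.79, 422.88]
#   A: P(I0|C0)=8/11, P(I0|C1)=2/11 with I0=[14.62, 21.30]
#   O: P(I0|C0)=7/11, P(I0|C1)=8/11 with I0=[51.56, 75.18]
# (for O the depressed class concentrates in the central interval too: the
# pilot's oscillation indicator separates the classes poorly, and the
# generator reproduces that.)
DEFAULT_COHORT_SPEC = CohortSpec(
    class_sizes=(11, 11),
    distributions={
        "T": (
            Normal(354.335, 75.4520),
            Mixture(((0.5, Normal(220.0, 79.999)), (0.5, Normal(500.0, 79.999)))),
        ),
        "A": (
            Normal(17.96, 3.0452),
            Mixture(((0.5, Normal(11.0, 4.7902)), (0.5, Normal(26.0, 4.7902)))),
        ),
        "O": (
            Normal(63.37, 13.0001),
            Normal(63.37, 10.7677),
        ),
    },
    seed=0,
)


def generate_cohort(spec: CohortSpec) -> ReferenceCohort:
    """Draw a cohort deterministically from ``spec`` (seeded)."""
    rng = np.random.default_rng(spec.seed)
    rows = {"subject_id": [], "class": []}
    features = sorted(spec.distributions)
    for feat in features:
        rows[feat] = []
    sid = 1
    for h, size in enumerate(spec.class_sizes):
        rows["subject_id"].extend(f"SYN{sid + i:04d}" for i in range(size))
        rows["class"].extend([h] * size)
        sid += size
        for feat in features:
            dist = spec.distributions[feat][h]
            rows[feat].extend(dist.sample(rng, size).tolist())
    frame = pd.DataFrame(rows, columns=["subject_id", "class", *features])
    return ReferenceCohort(frame, n_classes=len(spec.class_sizes))


@dataclass(frozen=True)
class PitchSpec:
    """Recipe for a synthetic f0 contour.

    ``oscillation_prob`` is the per-frame probability that the contour's
    slope sign flips, so the expected oscillation indicator is
    100 × oscillation_prob.  Jump magnitudes are uniform on
    [jump_low, jump_high] Hz (strictly positive, so no zero differences);
    ``drift_hz`` adds a constant to every difference.
    """

    frames: int
    base_hz: float = 220.0
    drift_hz: float = 0.0
    oscillation_prob: float = 0.5
    jump_low: float = 0.5
    jump_high: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.frames < 3:
            raise ValidationError("need at least 3 frames")
        if not 0.0 <= self.oscillation_prob <= 1.0:
            raise ValidationError("oscillation_prob must lie in [0, 1]")
        if self.base_hz <= 0:
            raise ValidationError("base frequency must be positive")
        if not 0 < self.jump_low <= self.jump_high:
            raise ValidationError("jump magnitudes must satisfy 0 < low <= high")


def generate_pitch(spec: PitchSpec) -> PitchTrack:
    """Build a pitch track whose slope sign flips with the specified
    probability at each frame.

    The first difference always climbs; with oscillation probability 0 the
    track is strictly monotone, with probability 1 it strictly alternates.
    If the walk would leave the positive frequency range the whole track is
    shifted upward, which changes no difference and hence no indicator.
    """
    rng = np.random.default_rng(spec.seed)
    n_diffs = spec.frames - 1
    flips = rng.random(n_diffs - 1) < spec.oscillation_prob
    signs = np.empty(n_diffs)
    signs[0] = 1.0
    signs[1:] = np.where(flips, -1.0, 1.0)
    signs = np.cumprod(signs)
    mags = rng.uniform(spec.jump_low, spec.jump_high, n_diffs)
    diffs = signs * mags + spec.drift_hz
    values = spec.base_hz + np.concatenate([[0.0], np.cumsum(diffs)])
    floor = values.min()
    if floor < 1.0:
        values = values + (1.0 - floor)
    return PitchTrack(values)
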
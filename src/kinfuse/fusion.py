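"""Sequential fusion of diagnostic test outcomes with a questionnaire prior.

The subject carries a *belief state*: a probability distribution over
diagnostic classes (binary default: healthy / depressed), initialized from a
questionnaire such as the BDI-II (usually as a point mass on the assigned
class).  Each behavioral test contributes a calibrated pair of row-stochastic
transition matrices, one per outcome interval; observing the test's value in
interval ``k`` updates the belief by the discrete kinetic interaction rule

    f'_h = f_h + Σ_i Φ_{ih;k} f_i − Σ_i Φ_{hi;k} f_h ,

which — because rows of Φ sum to one — reduces exactly to the row-vector /
matrix product f' = f · Φ^(k).  All arithmetic is exact (``fractions``);
rounding happens only when numbers are reported.

Because the update is a matrix product, the result depends on the order in
which tests are applied.  :func:`permutation_ensemble` therefore runs every
ordering of a set of outcomes and summarizes the per-step spread with means
and sample standard deviations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Sequence

from ._util import round_half_away
from .exceptions import ConfigurationError, FeatureLookupError, ValidationError

__all__ = [
    "DiagnosticClasses", "BINARY_CLASSES", "BDI_CLASSES", "bdi_class_of_score",
    "BeliefState", "TestEvidence", "TransitionMatrixPair", "Trajectory",
    "StepSummary", "EnsembleSummary", "update_once", "update_superposed",
    "run_sequence", "permutation_ensemble",
]

MAX_ENSEMBLE_TESTS = 8  # factorial growth: 8! = 40320 orderings


def _frac(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x)  # exact binary value; callers wanting decimals pass str
    return Fraction(str(x))


@dataclass(frozen=True)
class DiagnosticClasses:
    """Ordered diagnostic class labels (index 0 is the healthy/normal class)."""

    labels: tuple[str, ...] = ("healthy", "depressed")

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ConfigurationError("need at least two diagnostic classes")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("class labels must be distinct")

    @property
    def size(self) -> int:
        return len(self.labels)


BINARY_CLASSES = DiagnosticClasses()

#: The six BDI-II severity classes, in score order.
BDI_CLASSES = DiagnosticClasses((
    "normal", "mild mood disturbance", "borderline clinical depression",
    "moderate depression", "severe depression", "extreme depression",
))

#: BDI-II total-score ranges of the six classes (upper bound inclusive).
BDI_SCORE_RANGES = ((1, 10), (11, 16), (17, 20), (21, 30), (31, 40), (41, 63))


def bdi_class_of_score(score: int) -> int:
    """Map a BDI-II total score to its severity class index (0..5)."""
    for idx, (lo, hi) in enumerate(BDI_SCORE_RANGES):
        if lo <= score <= hi:
            return idx
    raise ValidationError(f"BDI score {score} outside the tabulated ranges")


@dataclass(frozen=True)
class BeliefState:
    """Probability distribution over diagnostic classes for one subject."""

    probs: tuple[Fraction, ...]
    classes: DiagnosticClasses = BINARY_CLASSES

    def __post_init__(self):
        probs = tuple(_frac(p) for p in self.probs)
        if len(probs) != self.classes.size:
            raise ConfigurationError(
                f"belief has {len(probs)} entries for {self.classes.size} classes"
            )
        if any(p < 0 for p in probs):
            raise ConfigurationError("belief probabilities must be non-negative")
        if sum(probs) != 1:
            raise ConfigurationError(f"belief sums to {float(sum(probs))}, expected 1")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def point_mass(cls, class_index: int,
                   classes: DiagnosticClasses = BINARY_CLASSES) -> "BeliefState":
        """Certain initial diagnosis: all mass on one class."""
        probs = tuple(
            Fraction(1) if i == class_index else Fraction(0)
            for i in range(classes.size)
        )
        return cls(probs, classes)

    def as_floats(self) -> tuple[float, ...]:
        return tuple(float(p) for p in self.probs)

    def rounded(self, ndigits: int = 2) -> tuple[float, ...]:
        return tuple(round_half_away(p, ndigits) for p in self.probs)


@dataclass(frozen=True)
class TestEvidence:
    """One test's contribution: a feature name plus either a definite
    observed interval index or a probability distribution over intervals
    (the uncertain-outcome variant used by :func:`update_superposed`)."""

    __test__ = False  # domain object, not a test case, despite the name

    feature: str
    interval: int | None = None
    outcome_dist: tuple[Fraction, ...] | None = None

    def __post_init__(self):
        if self.interval is None and self.outcome_dist is None:
            raise ValidationError(
                f"evidence for {self.feature!r} needs an interval or an "
                "outcome distribution"
            )
        if self.interval is not None and self.interval < 0:
            raise ValidationError("interval index must be non-negative")
        if self.outcome_dist is not None:
            dist = tuple(_frac(w) for w in self.outcome_dist)
            if any(w < 0 for w in dist) or sum(dist) != 1:
                raise ValidationError(
                    f"outcome distribution for {self.feature!r} must be a "
                    "probability vector"
                )
            object.__setattr__(self, "outcome_dist", dist)


Matrix = tuple[tuple[Fraction, ...], ...]


@dataclass(frozen=True)
class TransitionMatrixPair:
    """Calibrated transition matrices for one feature, one per interval.

    Entry ``[r][s]`` is P(class s | class r ∩ interval): row = current class,
    column = next class; every row sums to exactly 1.
    """

    feature: str
    matrices: tuple[Matrix, ...]
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        cleaned = []
        for k, mat in enumerate(self.matrices):
            rows = tuple(tuple(_frac(x) for x in row) for row in mat)
            size = len(rows)
            for r, row in enumerate(rows):
                if len(row) != size:
                    raise ConfigurationError(
                        f"{self.feature}/interval {k}: matrix is not square"
                    )
                if any(x < 0 or x > 1 for x in row):
                    raise ConfigurationError(
                        f"{self.feature}/interval {k}: entries outside [0, 1]"
                    )
                if sum(row) != 1:
                    raise ConfigurationError(
                        f"{self.feature}/interval {k}: row {r} sums to "
                        f"{float(sum(row))}, expected exactly 1"
                    )
            cleaned.append(rows)
        object.__setattr__(self, "matrices", tuple(cleaned))

    @property
    def n_classes(self) -> int:
        return len(self.matrices[0])

    def for_interval(self, k: int) -> Matrix:
        if not 0 <= k < len(self.matrices):
            raise FeatureLookupError(
                f"{self.feature}: no matrix for interval {k} "
                f"(have {len(self.matrices)})"
            )
        return self.matrices[k]


@dataclass(frozen=True)
class Trajectory:
    """Belief path: the initial state plus one state per applied test."""

    initial: BeliefState
    steps: tuple[tuple[str, BeliefState], ...]

    @property
    def beliefs(self) -> tuple[BeliefState, ...]:
        return (self.initial,) + tuple(b for _, b in self.steps)

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.steps)

    def healthy_path(self, ndigits: int | None = 2) -> tuple[float, ...]:
        """Probability of class 0 after each test (initial state excluded)."""
        vals = tuple(b.probs[0] for _, b in self.steps)
        if ndigits is None:
            return tuple(float(v) for v in vals)
        return tuple(round_half_away(v, ndigits) for v in vals)


@dataclass(frozen=True)
class StepSummary:
    """Across-ordering statistics of the class-0 probability at one step."""

    mean_healthy: Fraction
    mean_depressed: Fraction
    sd: float


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-step means and sample standard deviations over all orderings."""

    steps: tuple[StepSummary, ...]
    n_orderings: int

    def rounded(self, ndigits: int = 2) -> tuple[tuple[float, float, float], ...]:
        return tuple(
            (round_half_away(s.mean_healthy, ndigits),
             round_half_away(s.mean_depressed, ndigits),
             round_half_away(s.sd, ndigits))
            for s in self.steps
        )


def _lookup(matrices: Mapping[str, TransitionMatrixPair] | TransitionMatrixPair,
            feature: str) -> TransitionMatrixPair:
    if isinstance(matrices, TransitionMatrixPair):
        if matrices.feature != feature:
            raise FeatureLookupError(
                f"evidence is for {feature!r} but matrices are for "
                f"{matrices.feature!r}"
            )
        return matrices
    try:
        return matrices[feature]
    except KeyError:
        raise FeatureLookupError(f"no calibrated matrices for feature {feature!r}")


def _apply_matrix(probs: Sequence[Fraction], mat: Matrix) -> tuple[Fraction, ...]:
    n = len(probs)
    return tuple(sum(probs[r] * mat[r][s] for r in range(n)) for s in range(n))


def _gain_loss_update(probs: Sequence[Fraction], mat: Matrix) -> tuple[Fraction, ...]:
    """Literal gain/loss form of the single-test interaction (η = 1)."""
    n = len(probs)
    return tuple(
        probs[h]
        + sum(mat[i][h] * probs[i] for i in range(n))
        - sum(mat[h][i] * probs[h] for i in range(n))
        for h in range(n)
    )


def update_once(belief: BeliefState,
                evidence: TestEvidence,
                matrices: Mapping[str, TransitionMatrixPair] | TransitionMatrixPair,
                ) -> BeliefState:
    """Update a belief with one test outcome observed in a definite interval.

    Computes both the gain/loss form and the matrix-product form and checks
    they agree exactly before returning (they are algebraically identical for
    row-stochastic matrices).
    """
    if evidence.interval is None:
        raise ValidationError(
            f"evidence for {evidence.feature!r} has no definite interval; "
            "use update_superposed for distributional outcomes"
        )
    pair = _lookup(matrices, evidence.feature)
    if pair.n_classes != belief.classes.size:
        raise ConfigurationError(
            f"{evidence.feature}: matrices are {pair.n_classes}-class but the "
            f"belief has {belief.classes.size} classes"
        )
    mat = pair.for_interval(evidence.interval)
    new = _apply_matrix(belief.probs, mat)
    assert new == _gain_loss_update(belief.probs, mat)
    return BeliefState(new, belief.classes)


def update_superposed(belief: BeliefState,
                      evidences: Iterable[TestEvidence],
                      matrices: Mapping[str, TransitionMatrixPair],
                      ) -> BeliefState:
    """One-shot superposition of several tests with uncertain outcomes.

    Every evidence must carry a distribution over its intervals; the belief
    moves by the summed gain/loss contributions of all (test, interval)
    pairs, weighted by the outcome probabilities (encounter rates 1).  With a
    single point-mass evidence this reduces exactly to :func:`update_once`.

    Unlike the sequential rule this superposition is *not* a composition of
    stochastic maps; with several strong outcomes it can push a component
    outside [0, 1], which is reported as a validation error.
    """
    evidences = list(evidences)
    probs = belief.probs
    n = len(probs)
    delta = [Fraction(0)] * n
    for ev in evidences:
        if ev.outcome_dist is None:
            if ev.interval is None:  # unreachable: TestEvidence validates
                raise ValidationError("evidence carries no outcome")
            dist = {ev.interval: Fraction(1)}
        else:
            dist = dict(enumerate(ev.outcome_dist))
        pair = _lookup(matrices, ev.feature)
        if pair.n_classes != n:
            raise ConfigurationError(
                f"{ev.feature}: matrices are {pair.n_classes}-class but the "
                f"belief has {n} classes"
            )
        for k, weight in dist.items():
            if weight == 0:
                continue
            moved = _apply_matrix(probs, pair.for_interval(k))
            for h in range(n):
                delta[h] += weight * (moved[h] - probs[h])
    new = tuple(probs[h] + delta[h] for h in range(n))
    if any(p < 0 or p > 1 for p in new):
        raise ValidationError(
            "superposed update left the probability simplex; apply the tests "
            "sequentially instead"
        )
    return BeliefState(new, belief.classes)


def run_sequence(initial: BeliefState,
                 evidences: Sequence[TestEvidence],
                 matrices: Mapping[str, TransitionMatrixPair],
                 ) -> Trajectory:
    """Fold :func:`update_once` over an ordered list of test outcomes."""
    steps = []
    belief = initial
    for ev in evidences:
        belief = update_once(belief, ev, matrices)
        steps.append((ev.feature, belief))
    return Trajectory(initial, tuple(steps))


def permutation_ensemble(initial: BeliefState,
                         evidences: Sequence[TestEvidence],
                         matrices: Mapping[str, TransitionMatrixPair],
                         ) -> tuple[list[Trajectory], EnsembleSummary]:
    """Run every ordering of the given test outcomes and summarize the spread.

    For step ``i`` (1-based) the summary holds the mean class-0 probability
    over all orderings (values repeated across orderings are retained) and
    the sample standard deviation (n − 1 denominator).  Statistics are
    computed on exact rationals; only reporting rounds.
    """
    evidences = list(evidences)
    if len(evidences) == 0:
        raise ValidationError("permutation ensemble needs at least one evidence")
    if len(evidences) > MAX_ENSEMBLE_TESTS:
        raise ValidationError(
            f"refusing to enumerate {len(evidences)}! orderings; at most "
            f"{MAX_ENSEMBLE_TESTS} tests are supported"
        )
    trajectories = [
        run_sequence(initial, perm, matrices)
        for perm in itertools.permutations(evidences)
    ]
    n_ord = len(trajectories)
    steps = []
    for i in range(len(evidences)):
        healthy = [t.steps[i][1].probs[0] for t in trajectories]
        mean = sum(healthy, Fraction(0)) / n_ord
        if n_ord > 1:
            var = sum((x - mean) ** 2 for x in healthy) / (n_ord - 1)
            sd = math.sqrt(float(var))
        else:
            sd = 0.0
        steps.append(StepSummary(mean, 1 - mean, sd))
    return trajectories, EnsembleSummary(tuple(steps), n_ord)
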
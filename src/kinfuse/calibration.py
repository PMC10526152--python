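"""Calibrating per-test transition matrices from a labeled reference cohort.

Pipeline, for each behavioral feature Y:

1. per-class descriptive statistics (ranges, means, population SDs);
2. a class-interval partition {I_h(Y)} of the feature's range — either
   supplied (the pilot study's confidence intervals) or estimated by an
   exhaustive midpoint-cut search in the binary case;
3. the contingency table n_hk = #{subjects of class h with Y ∈ I_k};
4. interval-conditional class probabilities P(C_h | I_k) = n_hk / Σ_i n_ik;
5. the binary transition-probability system

       n_0k = n_0k·P(C0|C0∩I_k) + n_1k·P(C0|C1∩I_k)       (k = 0, 1),

   which is under-determined: two entries are free parameters,
   λ = P(C0|C0∩I0) and μ = P(C1|C1∩I1), constrained to the admissible
   rectangle λ ∈ [max(0, 1 − n10/n00), 1], μ ∈ [max(0, 1 − n01/n11), 1];
6. a choice of (λ, μ) — the unbiased default is the midpoint of the
   admissible rectangle — yielding the row-stochastic matrix pair

       Φ^(I0) = [[λ, 1−λ], [(n00/n10)(1−λ), 1 − (n00/n10)(1−λ)]],
       Φ^(I1) = [[(n01 − n11(1−μ))/n01, n11(1−μ)/n01], [1−μ, μ]].

λ encodes trust in the confirming power of an I0 (healthy-side) outcome, μ
the same for I1; the extremes of the rectangle encode deliberate bias toward
"healthy" or "depressed".  All derived quantities are exact rationals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from ._util import format_fraction
from .exceptions import (
    AdmissibilityError,
    CalibrationError,
    ConfigurationError,
    CoverageError,
    ValidationError,
)
from .fusion import TransitionMatrixPair

__all__ = [
    "ReferenceCohort", "ClassFeatureStats", "Interval", "ClassIntervalPartition",
    "ContingencyTable", "LambdaMuBounds", "LambdaMuChoice", "FeatureCalibration",
    "CalibrationResult", "class_statistics", "fit_partition", "contingency",
    "posterior_given_interval", "lambda_mu_bounds", "midpoint_choice",
    "transition_matrices", "calibrate",
]

COHORT_COLUMNS = ("subject_id", "class")


class ReferenceCohort:
    """Labeled reference cohort: one row per subject, a diagnostic class
    label and one numeric value per behavioral feature.

    Backed by a :class:`pandas.DataFrame` with columns
    ``subject_id, class, <feature>...``; extra feature columns are allowed.
    """

    def __init__(self, frame: pd.DataFrame, n_classes: int | None = None):
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"cohort is missing columns {missing}")
        self.frame = frame.reset_index(drop=True)
        self.features = tuple(c for c in frame.columns if c not in COHORT_COLUMNS)
        if not self.features:
            raise ValidationError("cohort has no feature columns")
        for feat in self.features:
            vals = pd.to_numeric(self.frame[feat], errors="coerce")
            if vals.isna().any() or not np.all(np.isfinite(vals.to_numpy())):
                raise ValidationError(f"feature {feat!r} has non-finite values")
            self.frame[feat] = vals.astype(float)
        labels = self.frame["class"].astype(int)
        if len(labels) and labels.min() < 0:
            raise ValidationError("class labels must be non-negative integers")
        self.frame["class"] = labels
        observed = int(labels.max()) + 1 if len(labels) else 0
        self.n_classes = n_classes if n_classes is not None else max(observed, 2)
        if observed > self.n_classes:
            raise ValidationError(
                f"cohort contains class {observed - 1} but n_classes={self.n_classes}"
            )

    @classmethod
    def from_records(cls, records, n_classes: int | None = None) -> "ReferenceCohort":
        return cls(pd.DataFrame.from_records(
            records, columns=None), n_classes=n_classes)

    @property
    def n(self) -> int:
        return len(self.frame)

    def class_size(self, h: int) -> int:
        return int((self.frame["class"] == h).sum())

    @property
    def class_sizes(self) -> tuple[int, ...]:
        return tuple(self.class_size(h) for h in range(self.n_classes))

    @property
    def class_fractions(self) -> tuple[Fraction, ...]:
        """q_h = n_h / n, the prior class probabilities of the cohort."""
        if self.n == 0:
            raise CalibrationError("empty cohort has no class fractions")
        return tuple(Fraction(nh, self.n) for nh in self.class_sizes)

    def values(self, feature: str, h: int | None = None) -> np.ndarray:
        if feature not in self.features:
            raise ValidationError(f"unknown feature {feature!r}")
        sel = self.frame if h is None else self.frame[self.frame["class"] == h]
        return sel[feature].to_numpy(dtype=float)


@dataclass(frozen=True)
class ClassFeatureStats:
    """Per-class ranges, means and population SDs for one feature."""

    feature: str
    ranges: tuple[tuple[float, float], ...]   # (e'_h, e''_h) per class
    means: tuple[float, ...]
    sds: tuple[float, ...]                    # 1/n_h (population) convention
    global_range: tuple[float, float]


def class_statistics(cohort: ReferenceCohort, feature: str) -> ClassFeatureStats:
    """Exact per-class ranges, means and population standard deviations.

    The SD uses the 1/n_h (population) normalization — the convention of the
    reference-sample synchronization step, distinct from the n−1 sample SD
    used by the permutation-ensemble summaries.
    """
    ranges, means, sds = [], [], []
    for h in range(cohort.n_classes):
        vals = cohort.values(feature, h)
        if vals.size == 0:
            raise CalibrationError(
                f"class {h} is empty; cannot compute statistics for {feature!r}"
            )
        ranges.append((float(vals.min()), float(vals.max())))
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=0)))
    allv = cohort.values(feature)
    return ClassFeatureStats(
        feature, tuple(ranges), tuple(means), tuple(sds),
        (float(allv.min()), float(allv.max())),
    )


@dataclass(frozen=True)
class Interval:
    """A real interval with open/closed endpoint flags; ±inf ends are open."""

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = True

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValidationError(f"interval [{self.lo}, {self.hi}] is empty")

    def contains(self, x: float) -> bool:
        if x < self.lo or x > self.hi:
            return False
        if x == self.lo and not (self.lo_closed and math.isfinite(self.lo)):
            return False
        if x == self.hi and not (self.hi_closed and math.isfinite(self.hi)):
            return False
        return True

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi,
                "lo_closed": self.lo_closed, "hi_closed": self.hi_closed}

    @classmethod
    def from_dict(cls, d: dict) -> "Interval":
        return cls(float(d["lo"]), float(d["hi"]),
                   bool(d["lo_closed"]), bool(d["hi_closed"]))


@dataclass(frozen=True)
class ClassIntervalPartition:
    """Per-class regions I_h(Y): each class owns one interval or a union of
    two flanking intervals; together they cover the feature's range.

    Assignment resolves shared endpoints in favor of the lowest class index
    (the class-0 central interval), and widens the outermost finite endpoints
    to ±inf so that any new subject can be placed.
    """

    feature: str
    intervals: tuple[tuple[Interval, ...], ...]   # index = class = interval id

    def __post_init__(self):
        if len(self.intervals) < 2:
            raise ValidationError("partition needs at least two classes")
        for h, ivs in enumerate(self.intervals):
            if not 1 <= len(ivs) <= 2:
                raise ValidationError(
                    f"class {h}: a class region is one interval or a union of two"
                )

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def _extended(self) -> tuple[tuple[Interval, ...], ...]:
        flat = [iv for ivs in self.intervals for iv in ivs]
        lo_min = min(iv.lo for iv in flat)
        hi_max = max(iv.hi for iv in flat)
        out = []
        for ivs in self.intervals:
            ext = []
            for iv in ivs:
                lo, hi = iv.lo, iv.hi
                lo_c, hi_c = iv.lo_closed, iv.hi_closed
                if lo == lo_min:
                    lo, lo_c = -math.inf, False
                if hi == hi_max:
                    hi, hi_c = math.inf, False
                ext.append(Interval(lo, hi, lo_c, hi_c))
            out.append(tuple(ext))
        return tuple(out)

    def assign(self, value: float) -> int:
        """Interval index (= class index) owning ``value``."""
        for h, ivs in enumerate(self.intervals):
            if any(iv.contains(value) for iv in ivs):
                return h
        for h, ivs in enumerate(self._extended()):
            if any(iv.contains(value) for iv in ivs):
                return h
        raise CoverageError(
            f"{self.feature}: value {value} lies outside every interval"
        )

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "intervals": [[iv.to_dict() for iv in ivs] for ivs in self.intervals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassIntervalPartition":
        return cls(
            d["feature"],
            tuple(tuple(Interval.from_dict(x) for x in ivs)
                  for ivs in d["intervals"]),
        )


def fit_partition(cohort: ReferenceCohort, feature: str, mode: str = "estimate",
                  given: ClassIntervalPartition | None = None,
                  ) -> ClassIntervalPartition:
    """Obtain the class-interval partition for one feature.

    mode="given": return the supplied partition (endpoints from an external
    synchronization, e.g. the pilot study's confidence-interval tables).

    mode="estimate" (binary cohorts only): exhaustive search over pairs of
    cut points placed at midpoints between adjacent sorted values, choosing
    the central interval [a, b] for class 0 that maximizes the number of
    correctly partitioned subjects (class 0 inside, class 1 outside); ties
    are broken toward the widest central interval.  Class 1 receives the two
    open flanks.
    """
    if mode == "given":
        if given is None:
            raise ValidationError("mode='given' requires a partition")
        if given.feature != feature:
            raise ValidationError(
                f"partition is for {given.feature!r}, not {feature!r}"
            )
        return given
    if mode != "estimate":
        raise ValidationError(f"unknown partition mode {mode!r}")
    if cohort.n_classes != 2:
        raise CalibrationError(
            "partition estimation is implemented for binary cohorts only"
        )
    v0 = np.sort(cohort.values(feature, 0))
    v1 = np.sort(cohort.values(feature, 1))
    if v0.size == 0 or v1.size == 0:
        raise CalibrationError(f"both classes must be non-empty for {feature!r}")
    pooled = np.unique(np.concatenate([v0, v1]))
    inner = (pooled[:-1] + pooled[1:]) / 2.0
    cuts = np.concatenate([[pooled[0] - 1.0], inner, [pooled[-1] + 1.0]])
    # correct(a,b) = #class0 in [a,b] + #class1 outside; vectorized over all
    # cut pairs with searchsorted prefix counts.
    in0 = np.searchsorted(v0, cuts)   # #class0 values < cut (cuts avoid data)
    in1 = np.searchsorted(v1, cuts)
    n1 = v1.size
    best = (-1, -np.inf, 0.0, 0.0)
    for i, a in enumerate(cuts):
        # class0 inside [a, b]: in0[j] - in0[i];  class1 outside: n1 - (in1[j]-in1[i])
        j = np.arange(i, len(cuts))
        correct = (in0[j] - in0[i]) + n1 - (in1[j] - in1[i])
        width = cuts[j] - a
        k = int(np.lexsort((-width, -correct))[0])
        cand = (int(correct[k]), float(width[k]), float(a), float(cuts[j][k]))
        if (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    _, _, a, b = best
    central = Interval(a, b, True, True)
    flanks = (
        Interval(-math.inf, a, False, False),
        Interval(b, math.inf, False, False),
    )
    return ClassIntervalPartition(feature, ((central,), flanks))


@dataclass(frozen=True)
class ContingencyTable:
    """Counts n_hk: subjects of class h whose feature value lies in I_k."""

    feature: str
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        for row in self.counts:
            if len(row) != len(self.counts):
                raise ConfigurationError("contingency table must be square")
            if any(c < 0 or int(c) != c for c in row):
                raise ConfigurationError("counts must be non-negative integers")
        object.__setattr__(
            self, "counts", tuple(tuple(int(c) for c in row) for row in self.counts)
        )

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    @property
    def class_totals(self) -> tuple[int, ...]:
        return tuple(sum(row) for row in self.counts)

    def p(self, h: int, k: int) -> Fraction:
        """p_hk = P(I_k | C_h) = n_hk / n_h."""
        nh = self.class_totals[h]
        if nh == 0:
            raise CalibrationError(f"class {h} has no subjects")
        return Fraction(self.counts[h][k], nh)

    def diagonal_dominant(self) -> tuple[bool, ...]:
        """Whether n_hh > Σ_{k≠h} n_hk holds per class (the condition that
        each class's own interval captures most of its subjects)."""
        return tuple(
            2 * self.counts[h][h] > self.class_totals[h]
            for h in range(self.n_classes)
        )

    # binary-case accessors (healthy = 0, depressed = 1)
    def _binary(self) -> tuple[int, int, int, int]:
        if self.n_classes != 2:
            raise CalibrationError("operation requires a binary table")
        (n00, n01), (n10, n11) = self.counts
        return n00, n01, n10, n11


def contingency(cohort: ReferenceCohort, partition: ClassIntervalPartition,
                feature: str) -> ContingencyTable:
    """Count subjects by (class, interval) membership.

    Emits a warning (does not fail) when the diagonal-dominance condition
    n_hh > Σ_{k≠h} n_hk is violated — evidence that the feature's intervals
    poorly separate the classes.
    """
    s = partition.n_intervals
    if cohort.n_classes > s:
        raise CalibrationError(
            f"partition has {s} intervals for {cohort.n_classes} classes"
        )
    counts = [[0] * s for _ in range(cohort.n_classes)]
    if cohort.n == 0:
        warnings.warn(f"{feature}: empty cohort, all counts zero", stacklevel=2)
        return ContingencyTable(feature, tuple(tuple(r) for r in counts))
    for h in range(cohort.n_classes):
        for x in cohort.values(feature, h):
            counts[h][partition.assign(float(x))] += 1
    table = ContingencyTable(feature, tuple(tuple(r) for r in counts))
    for h, ok in enumerate(table.diagonal_dominant()):
        if not ok and table.class_totals[h] > 0:
            warnings.warn(
                f"{feature}: class {h} is not concentrated in its own interval "
                f"(n_{h}{h}={table.counts[h][h]} vs off-diagonal "
                f"{table.class_totals[h] - table.counts[h][h]})",
                stacklevel=2,
            )
    return table


def posterior_given_interval(table: ContingencyTable) -> tuple[tuple[Fraction, ...], ...]:
    """P(C_h | I_k) = n_hk / Σ_i n_ik, as an (classes × intervals) grid of
    exact fractions; every column is a probability vector."""
    s = table.n_classes
    cols = [sum(table.counts[i][k] for i in range(s)) for k in range(s)]
    for k, tot in enumerate(cols):
        if tot == 0:
            raise CalibrationError(
                f"{table.feature}: interval {k} is empty, posterior undefined"
            )
    return tuple(
        tuple(Fraction(table.counts[h][k], cols[k]) for k in range(s))
        for h in range(s)
    )


@dataclass(frozen=True)
class LambdaMuBounds:
    """Admissible rectangle for the free parameters of the binary solution."""

    feature: str
    lambda_min: Fraction
    mu_min: Fraction
    lambda_clamped: bool = False   # raw bound was negative, clamped to 0
    mu_clamped: bool = False
    degenerate: tuple[str, ...] = ()

    lambda_max: Fraction = field(default=Fraction(1), init=False)
    mu_max: Fraction = field(default=Fraction(1), init=False)

    def __post_init__(self):
        if not 0 <= self.lambda_min <= 1 or not 0 <= self.mu_min <= 1:
            raise ConfigurationError("clamped bounds must lie in [0, 1]")


def lambda_mu_bounds(table: ContingencyTable) -> LambdaMuBounds:
    """λ_min = max(0, 1 − n10/n00) and μ_min = max(0, 1 − n01/n11).

    The raw expressions come from requiring the implied matrix entries to be
    probabilities; negative raw values carry no constraint and are clamped to
    0 (flagged).  Degenerate zero counts are flagged rather than rejected.
    """
    n00, n01, n10, n11 = table._binary()
    degenerate = []
    if n00 == 0:
        lam_raw, lam_clamped = Fraction(0), False
        degenerate.append("n00=0: lambda unconstrained")
    else:
        lam_raw = 1 - Fraction(n10, n00)
        lam_clamped = lam_raw < 0
    if n10 == 0:
        degenerate.append("n10=0: lambda forced to 1")
        lam_raw, lam_clamped = Fraction(1), False
    if n11 == 0:
        mu_raw, mu_clamped = Fraction(0), False
        degenerate.append("n11=0: mu unconstrained")
    else:
        mu_raw = 1 - Fraction(n01, n11)
        mu_clamped = mu_raw < 0
    if n01 == 0:
        degenerate.append("n01=0: mu forced to 1")
        mu_raw, mu_clamped = Fraction(1), False
    return LambdaMuBounds(
        table.feature,
        max(Fraction(0), lam_raw),
        max(Fraction(0), mu_raw),
        lam_clamped,
        mu_clamped,
        tuple(degenerate),
    )


@dataclass(frozen=True)
class LambdaMuChoice:
    """A concrete (λ, μ) inside the admissible rectangle."""

    feature: str
    lam: Fraction
    mu: Fraction
    provenance: str = "user"

    def __post_init__(self):
        object.__setattr__(self, "lam", Fraction(self.lam))
        object.__setattr__(self, "mu", Fraction(self.mu))
        if not 0 <= self.lam <= 1 or not 0 <= self.mu <= 1:
            raise AdmissibilityError(
                f"{self.feature}: lambda and mu must be probabilities"
            )


def midpoint_choice(bounds: LambdaMuBounds) -> LambdaMuChoice:
    """The unbiased default: midpoints of the admissible rectangle,
    λ* = (λ_min + 1)/2 and μ* = (μ_min + 1)/2."""
    return LambdaMuChoice(
        bounds.feature,
        (bounds.lambda_min + bounds.lambda_max) / 2,
        (bounds.mu_min + bounds.mu_max) / 2,
        provenance="midpoint",
    )


def transition_matrices(table: ContingencyTable,
                        choice: LambdaMuChoice) -> TransitionMatrixPair:
    """Solve the binary transition-probability system for the given (λ, μ).

    Returns the pair (Φ^(I0), Φ^(I1)) of exact row-stochastic matrices; the
    produced entries satisfy the defining count identities
    n_hk = Σ_r n_rk·Φ^(I_k)[r][h] term by term.

    Degenerate counts: n10 = 0 leaves the depressed row of Φ^(I0)
    unconstrained — λ must be 1 and the row is set to (0, 1) (an I0 outcome
    carries no evidence to move a depressed subject); symmetrically n01 = 0
    forces μ = 1 with healthy row (1, 0) in Φ^(I1).
    """
    n00, n01, n10, n11 = table._binary()
    if choice.feature != table.feature:
        raise ConfigurationError(
            f"choice is for {choice.feature!r}, table for {table.feature!r}"
        )
    bounds = lambda_mu_bounds(table)
    lam, mu = choice.lam, choice.mu
    if not bounds.lambda_min <= lam <= 1:
        raise AdmissibilityError(
            f"{table.feature}: lambda={format_fraction(lam)} outside "
            f"[{format_fraction(bounds.lambda_min)}, 1]"
        )
    if not bounds.mu_min <= mu <= 1:
        raise AdmissibilityError(
            f"{table.feature}: mu={format_fraction(mu)} outside "
            f"[{format_fraction(bounds.mu_min)}, 1]"
        )
    notes = list(bounds.degenerate)
    if n10 == 0:
        phi0_dep = (Fraction(0), Fraction(1))
    else:
        moved = Fraction(n00, n10) * (1 - lam)
        phi0_dep = (moved, 1 - moved)
    if n01 == 0:
        phi1_heal = (Fraction(1), Fraction(0))
    else:
        stay_dep = Fraction(n11, n01) * (1 - mu)
        phi1_heal = (1 - stay_dep, stay_dep)
    phi0 = ((lam, 1 - lam), phi0_dep)
    phi1 = (phi1_heal, (1 - mu, mu))
    return TransitionMatrixPair(table.feature, (phi0, phi1), notes=tuple(notes))


@dataclass(frozen=True)
class FeatureCalibration:
    """Everything calibrated for one feature."""

    feature: str
    partition: ClassIntervalPartition
    table: ContingencyTable
    posterior: tuple[tuple[Fraction, ...], ...]
    bounds: LambdaMuBounds
    choice: LambdaMuChoice
    matrices: TransitionMatrixPair


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrations for all requested features of a cohort."""

    features: tuple[str, ...]
    per_feature: dict[str, FeatureCalibration]

    def matrices_by_feature(self) -> dict[str, TransitionMatrixPair]:
        return {f: c.matrices for f, c in self.per_feature.items()}


def calibrate(cohort: ReferenceCohort,
              features: tuple[str, ...] | None = None,
              partition_mode: str = "estimate",
              partitions: dict[str, ClassIntervalPartition] | None = None,
              choices: dict[str, LambdaMuChoice] | None = None,
              ) -> CalibrationResult:
    """End-to-end calibration: partition → counts → bounds → (λ, μ) → matrices.

    ``choices`` overrides the midpoint default per feature; admissibility is
    checked against the bounds computed from the cohort.
    """
    feats = features if features is not None else cohort.features
    per = {}
    for feat in feats:
        part = fit_partition(
            cohort, feat, mode=partition_mode,
            given=(partitions or {}).get(feat),
        )
        table = contingency(cohort, part, feat)
        post = posterior_given_interval(table)
        bounds = lambda_mu_bounds(table)
        choice = (choices or {}).get(feat) or midpoint_choice(bounds)
        mats = transition_matrices(table, choice)
        per[feat] = FeatureCalibration(feat, part, table, post, bounds, choice, mats)
    return CalibrationResult(tuple(feats), per)
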
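"""Calibration pipeline: statistics, partitions, counts, bounds, matrices."""

import itertools
from fractions import Fraction as F

import numpy as np
import pandas as pd
import pytest

from kinfuse import pilot
from kinfuse.calibration import (
    ClassIntervalPartition,
    ContingencyTable,
    Interval,
    LambdaMuChoice,
    ReferenceCohort,
    class_statistics,
    contingency,
    fit_partition,
    lambda_mu_bounds,
    midpoint_choice,
    posterior_given_interval,
    transition_matrices,
)
from kinfuse.exceptions import AdmissibilityError, CalibrationError


def make_cohort(class0, class1, feature="Y"):
    rows = []
    for i, v in enumerate(class0):
        rows.append({"subject_id": f"a{i}", "class": 0, feature: v})
    for i, v in enumerate(class1):
        rows.append({"subject_id": f"b{i}", "class": 1, feature: v})
    return ReferenceCohort(pd.DataFrame(rows), n_classes=2)


class TestClassStatistics:
    def test_constant_class_has_zero_sd(self):
        cohort = make_cohort([2, 2, 2], [5, 7])
        stats = class_statistics(cohort, "Y")
        assert stats.means[0] == 2 and stats.sds[0] == 0

    def test_population_sd_convention(self):
        # {1, 3}: mean 2, SD 1 under the 1/n normalization (n-1 would give sqrt 2)
        stats = class_statistics(make_cohort([1, 3], [10, 10]), "Y")
        assert stats.means[0] == 2 and stats.sds[0] == 1

    def test_single_subject_class_degenerate_range(self):
        stats = class_statistics(make_cohort([4], [1, 9]), "Y")
        assert stats.ranges[0] == (4, 4) and stats.sds[0] == 0
        assert stats.global_range == (1, 9)

    def test_empty_class_raises_naming_class(self):
        frame = pd.DataFrame(
            [{"subject_id": "a", "class": 0, "Y": 1.0}]
        )
        cohort = ReferenceCohort(frame, n_classes=2)
        with pytest.raises(CalibrationError, match="class 1"):
            class_statistics(cohort, "Y")


def partition_oracle(class0, class1):
    """Exhaustive search over all cut pairs, recounting naively."""
    pooled = sorted(set(class0) | set(class1))
    inner = [(a + b) / 2 for a, b in zip(pooled, pooled[1:])]
    cuts = [pooled[0] - 1.0] + inner + [pooled[-1] + 1.0]
    best = None
    for a, b in itertools.combinations_with_replacement(cuts, 2):
        correct = sum(a <= v <= b for v in class0) + sum(
            not a <= v <= b for v in class1
        )
        key = (correct, b - a)
        if best is None or key > best[0]:
            best = (key, (a, b))
    return best


class TestFitPartition:
    def test_given_mode_returns_pilot_endpoints(self):
        part = pilot.PARTITIONS["T"]
        cohort = make_cohort([300.0], [200.0], feature="T")
        out = fit_partition(cohort, "T", mode="given", given=part)
        assert out.intervals[0][0] == Interval(285.79, 422.88)

    def test_estimate_separates_separable_cohort(self):
        cohort = make_cohort([10, 11], [1, 20])
        part = fit_partition(cohort, "Y", mode="estimate")
        central = part.intervals[0][0]
        assert central.lo < 10 and central.hi > 11
        assert part.assign(10) == 0 and part.assign(11) == 0
        assert part.assign(1) == 1 and part.assign(20) == 1
        (best_correct, _), _ = partition_oracle([10, 11], [1, 20])
        assert best_correct == 4

    def test_estimate_matches_exhaustive_oracle_on_interleaved_values(self):
        class0 = [1.0, 3.0, 5.0, 7.0]
        class1 = [2.0, 4.0, 6.0, 8.0]
        cohort = make_cohort(class0, class1)
        part = fit_partition(cohort, "Y", mode="estimate")
        achieved = sum(part.assign(v) == 0 for v in class0) + sum(
            part.assign(v) == 1 for v in class1
        )
        (oracle_correct, _), _ = partition_oracle(class0, class1)
        assert achieved == oracle_correct

    def test_non_binary_estimate_unsupported(self):
        frame = pd.DataFrame([
            {"subject_id": "a", "class": 0, "Y": 1.0},
            {"subject_id": "b", "class": 1, "Y": 2.0},
            {"subject_id": "c", "class": 2, "Y": 3.0},
        ])
        cohort = ReferenceCohort(frame, n_classes=3)
        with pytest.raises(CalibrationError, match="binary"):
            fit_partition(cohort, "Y", mode="estimate")


class TestContingency:
    def test_pilot_like_cohort_reproduces_reference_counts(self):
        cohort = pilot.pilot_like_cohort()
        for feat in ("T", "A"):
            table = contingency(cohort, pilot.PARTITIONS[feat], feat)
            assert table.counts == pilot.CONTINGENCY[feat].counts
        with pytest.warns(UserWarning, match="not concentrated"):
            table = contingency(cohort, pilot.PARTITIONS["O"], "O")
        assert table.counts == pilot.CONTINGENCY["O"].counts

    def test_perfect_separation_gives_antidiagonal_zeros(self):
        cohort = make_cohort([10, 11, 12], [1, 2, 30])
        part = fit_partition(cohort, "Y", mode="estimate")
        table = contingency(cohort, part, "Y")
        assert table.counts == ((3, 0), (0, 3))

    def test_empty_cohort_warns_and_zeroes(self):
        frame = pd.DataFrame(columns=["subject_id", "class", "Y"])
        cohort = ReferenceCohort(frame, n_classes=2)
        part = ClassIntervalPartition("Y", (
            (Interval(0, 1),),
            (Interval(-np.inf, 0, False, False), Interval(1, np.inf, False, False)),
        ))
        with pytest.warns(UserWarning, match="empty"):
            table = contingency(cohort, part, "Y")
        assert table.counts == ((0, 0), (0, 0))


class TestPosterior:
    def test_reference_t_column(self):
        post = posterior_given_interval(pilot.CONTINGENCY["T"])
        assert post[0][0] == F(7, 9) and post[1][0] == F(2, 9)
        assert post[0][1] + post[1][1] == 1

    def test_diagonal_counts_give_identity_columns(self):
        post = posterior_given_interval(ContingencyTable("Y", ((5, 0), (0, 3))))
        assert post[0][0] == 1 and post[1][1] == 1

    def test_uniform_counts_give_uniform_columns(self):
        post = posterior_given_interval(ContingencyTable("Y", ((2, 2), (2, 2))))
        assert all(post[h][k] == F(1, 2) for h in range(2) for k in range(2))

    def test_empty_interval_column_rejected(self):
        with pytest.raises(CalibrationError, match="interval 1"):
            posterior_given_interval(ContingencyTable("Y", ((3, 0), (2, 0))))


class TestLambdaMuBounds:
    @pytest.mark.parametrize("feat,expected", [
        ("T", (F(5, 7), F(5, 9))),
        ("A", (F(3, 4), F(2, 3))),
        ("O", (F(0), F(0))),
    ])
    def test_reference_bounds(self, feat, expected):
        b = lambda_mu_bounds(pilot.CONTINGENCY[feat])
        assert (b.lambda_min, b.mu_min) == expected

    def test_negative_raw_bounds_are_clamped_and_flagged(self):
        b = lambda_mu_bounds(pilot.CONTINGENCY["O"])
        assert b.lambda_clamped and b.mu_clamped

    def test_degenerate_zero_counts_flagged(self):
        b = lambda_mu_bounds(ContingencyTable("Y", ((5, 2), (0, 4))))
        assert b.lambda_min == 1
        assert any("n10=0" in d for d in b.degenerate)


class TestMidpointChoice:
    @pytest.mark.parametrize("feat,expected", [
        ("T", (F(6, 7), F(7, 9))),
        ("O", (F(1, 2), F(1, 2))),
    ])
    def test_midpoints(self, feat, expected):
        choice = midpoint_choice(lambda_mu_bounds(pilot.CONTINGENCY[feat]))
        assert (choice.lam, choice.mu) == expected
        assert choice.provenance == "midpoint"

    def test_unit_bounds_stay_unit(self):
        from kinfuse.calibration import LambdaMuBounds

        choice = midpoint_choice(LambdaMuBounds("Y", F(1), F(1)))
        assert (choice.lam, choice.mu) == (1, 1)


def system_identities_hold(table, pair):
    """The defining count identities n_hk = sum_r n_rk * Phi^(Ik)[r][h]."""
    for k in range(2):
        mat = pair.for_interval(k)
        for h in range(2):
            lhs = table.counts[h][k]
            rhs = sum(table.counts[r][k] * mat[r][h] for r in range(2))
            if lhs != rhs:
                return False
    return True


class TestTransitionMatrices:
    def test_t_midpoint_reproduces_published_pair(self):
        table = pilot.CONTINGENCY["T"]
        pair = transition_matrices(table, LambdaMuChoice("T", F(6, 7), F(7, 9)))
        assert pair.matrices == pilot.PUBLISHED_MATRICES["T"].matrices

    def test_lambda_at_lower_bound_forces_certain_transition(self):
        # lambda = 5/7: a healthy-side outcome moves a depressed subject with
        # certainty, P(C0|C1∩I0) = 1
        pair = transition_matrices(
            pilot.CONTINGENCY["T"], LambdaMuChoice("T", F(5, 7), F(1))
        )
        assert pair.for_interval(0)[1] == (F(1), F(0))

    def test_mu_at_lower_bound(self):
        pair = transition_matrices(
            pilot.CONTINGENCY["T"], LambdaMuChoice("T", F(1), F(5, 9))
        )
        assert pair.for_interval(1) == ((F(0), F(1)), (F(4, 9), F(5, 9)))

    def test_out_of_bounds_lambda_quotes_the_bound(self):
        with pytest.raises(AdmissibilityError, match="5/7"):
            transition_matrices(
                pilot.CONTINGENCY["T"], LambdaMuChoice("T", F(1, 2), F(7, 9))
            )

    @pytest.mark.parametrize("feat", ["T", "A", "O"])
    def test_solved_system_identities_over_grid(self, feat):
        """For every admissible (lambda, mu) on a grid the produced matrices
        solve the original count system term by term, are row-stochastic and
        have entries in [0, 1]."""
        table = pilot.CONTINGENCY[feat]
        b = lambda_mu_bounds(table)
        for i in range(5):
            for j in range(5):
                lam = b.lambda_min + (1 - b.lambda_min) * F(i, 4)
                mu = b.mu_min + (1 - b.mu_min) * F(j, 4)
                pair = transition_matrices(table, LambdaMuChoice(feat, lam, mu))
                assert system_identities_hold(table, pair)
                for mat in pair.matrices:
                    for row in mat:
                        assert sum(row) == 1
                        assert all(0 <= x <= 1 for x in row)

    def test_degenerate_n10_rows(self):
        table = ContingencyTable("Y", ((5, 2), (0, 7)))
        pair = transition_matrices(table, LambdaMuChoice("Y", F(1), F(5, 7)))
        assert pair.for_interval(0)[1] == (F(0), F(1))
        with pytest.raises(AdmissibilityError):
            transition_matrices(table, LambdaMuChoice("Y", F(1, 2), F(5, 7)))

    def test_degenerate_n01_rows(self):
        table = ContingencyTable("Y", ((6, 0), (2, 7)))
        pair = transition_matrices(table, LambdaMuChoice("Y", F(2, 3), F(1)))
        assert pair.for_interval(1)[0] == (F(1), F(0))


def test_end_to_end_midpoint_calibration_t_and_a():
    """Counts + midpoint rule reproduce the published T and A matrices as
    exact rationals (the O interval-1 healthy row is the documented
    divergence between the published matrix and the solved system)."""
    derived = pilot.derived_matrices()
    for feat in ("T", "A"):
        assert derived[feat].matrices == pilot.PUBLISHED_MATRICES[feat].matrices
    assert derived["O"].for_interval(0) == pilot.PUBLISHED_MATRICES["O"].for_interval(0)
    pub_row = pilot.PUBLISHED_MATRICES["O"].for_interval(1)[0]
    assert derived["O"].for_interval(1)[0] == tuple(reversed(pub_row))
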
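"""Belief updates, trajectories and permutation ensembles on exact rationals."""

import math
from fractions import Fraction as F

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinfuse import pilot
from kinfuse.exceptions import (
    ConfigurationError,
    FeatureLookupError,
    ValidationError,
)
from kinfuse.fusion import (
    BeliefState,
    DiagnosticClasses,
    TestEvidence,
    TransitionMatrixPair,
    bdi_class_of_score,
    permutation_ensemble,
    run_sequence,
    update_once,
    update_superposed,
)

IDENTITY = TransitionMatrixPair(
    "X", ((((F(1), F(0)), (F(0), F(1))),) * 2)
)


def identity_matrices(features):
    return {
        f: TransitionMatrixPair(f, (((F(1), F(0)), (F(0), F(1))),) * 2)
        for f in features
    }


# -- hypothesis strategies over exact rationals ---------------------------

@st.composite
def rational_beliefs(draw, n=2):
    weights = draw(st.lists(st.integers(0, 20), min_size=n, max_size=n)
                   .filter(lambda w: sum(w) > 0))
    total = sum(weights)
    return BeliefState(tuple(F(w, total) for w in weights))


@st.composite
def rational_matrix_pairs(draw, feature="Y", n=2):
    mats = []
    for _ in range(2):
        rows = []
        for _ in range(n):
            w = draw(st.lists(st.integers(0, 9), min_size=n, max_size=n)
                     .filter(lambda w: sum(w) > 0))
            t = sum(w)
            rows.append(tuple(F(x, t) for x in w))
        mats.append(tuple(rows))
    return TransitionMatrixPair(feature, tuple(mats))


class TestUpdateOnce:
    def test_depressed_prior_with_t_in_interval_one(self, published_matrices):
        """A certain depressed prior moves to ~22% healthy after a
        depressed-side T outcome."""
        belief = BeliefState.point_mass(1)
        out = update_once(belief, TestEvidence("T", 1), published_matrices)
        assert out.probs == (F(2, 9), F(7, 9))
        assert out.rounded() == (0.22, 0.78)

    def test_identity_matrices_leave_belief_unchanged(self):
        belief = BeliefState((F(1, 3), F(2, 3)))
        out = update_once(belief, TestEvidence("X", 0), {"X": IDENTITY})
        assert out.probs == belief.probs

    def test_o_update_matches_published_third_step(self, published_matrices):
        belief = BeliefState((F(13, 54), F(41, 54)))
        out = update_once(belief, TestEvidence("O", 1), published_matrices)
        assert out.probs == (F(203, 432), F(229, 432))
        assert out.rounded() == (0.47, 0.53)

    def test_unknown_feature_raises_lookup_error(self, published_matrices):
        with pytest.raises(FeatureLookupError):
            update_once(BeliefState.point_mass(0), TestEvidence("Z", 0),
                        published_matrices)

    def test_class_count_mismatch_raises(self):
        three = BeliefState((F(1), F(0), F(0)),
                            classes=DiagnosticClasses(("a", "b", "c")))
        with pytest.raises(ConfigurationError):
            update_once(three, TestEvidence("X", 0), {"X": IDENTITY})

    @given(belief=rational_beliefs(), pair=rational_matrix_pairs())
    def test_update_preserves_simplex_exactly(self, belief, pair):
        out = update_once(belief, TestEvidence("Y", 0), {"Y": pair})
        assert sum(out.probs) == 1
        assert all(0 <= p <= 1 for p in out.probs)

    @given(belief=rational_beliefs(), pair=rational_matrix_pairs())
    def test_gain_loss_form_equals_matrix_product(self, belief, pair):
        """The kinetic gain/loss update and left matrix multiplication are
        the same map for row-stochastic matrices."""
        from kinfuse.fusion import _apply_matrix, _gain_loss_update

        mat = pair.for_interval(1)
        assert _apply_matrix(belief.probs, mat) == _gain_loss_update(
            belief.probs, mat
        )


class TestUpdateSuperposed:
    def test_point_mass_outcome_reduces_to_update_once(self, published_matrices):
        belief = BeliefState.point_mass(1)
        ev = TestEvidence("T", outcome_dist=(F(0), F(1)))
        out = update_superposed(belief, [ev], published_matrices)
        assert out.probs == update_once(
            belief, TestEvidence("T", 1), published_matrices
        ).probs

    def test_identity_matrices_unchanged_for_any_outcomes(self):
        belief = BeliefState((F(2, 5), F(3, 5)))
        mats = identity_matrices(["P", "Q"])
        evs = [TestEvidence("P", outcome_dist=(F(1, 3), F(2, 3))),
               TestEvidence("Q", outcome_dist=(F(1, 2), F(1, 2)))]
        assert update_superposed(belief, evs, mats).probs == belief.probs

    def test_matches_bruteforce_term_sums(self, published_matrices):
        """Direct evaluation of the one-shot superposition sums (gain minus
        loss over every test/interval pair) — the independent oracle."""
        belief = BeliefState.point_mass(1)
        ev = TestEvidence("T", outcome_dist=(F(1, 2), F(1, 2)))
        out = update_superposed(belief, [ev], published_matrices)

        probs = belief.probs
        expected = []
        for h in range(2):
            acc = probs[h]
            for k, w in enumerate(ev.outcome_dist):
                mat = published_matrices["T"].for_interval(k)
                gain = sum(mat[i][h] * probs[i] * w for i in range(2))
                loss = sum(mat[h][i] * probs[h] * w for i in range(2))
                acc += gain - loss
            expected.append(acc)
        assert out.probs == tuple(expected)
        assert sum(out.probs) == 1

    def test_missing_outcome_distribution_rejected(self, published_matrices):
        with pytest.raises(ValidationError):
            TestEvidence("T")  # neither interval nor distribution


class TestRunSequence:
    def test_empty_evidence_returns_initial_only(self, published_matrices):
        traj = run_sequence(BeliefState.point_mass(1), [], published_matrices)
        assert traj.steps == ()
        assert traj.beliefs == (traj.initial,)

    def test_s37_all_depressed_outcomes(self, published_matrices, subjects):
        """Depressed prior + three depressed-side outcomes: healthy
        probability climbs 0.22 -> 0.24 -> 0.47 in the T,A,O order."""
        rec = subjects["S37"]
        traj = run_sequence(
            rec.initial_belief(),
            pilot.subject_evidence(rec, ("T", "A", "O")),
            published_matrices,
        )
        assert traj.healthy_path() == (0.22, 0.24, 0.47)

    def test_s15_mixed_outcomes(self, published_matrices, subjects):
        rec = subjects["S15"]
        traj = run_sequence(
            rec.initial_belief(),
            pilot.subject_evidence(rec, ("O", "T", "A")),
            published_matrices,
        )
        assert traj.healthy_path() == (0.44, 0.66, 0.39)


class TestPermutationEnsemble:
    def test_s15_step3_mean_and_sd(self, published_matrices, subjects):
        rec = subjects["S15"]
        _, summary = permutation_ensemble(
            rec.initial_belief(), pilot.subject_evidence(rec), published_matrices
        )
        assert summary.n_orderings == 6
        rounded = summary.rounded()
        assert rounded[2][0] == 0.49
        assert rounded[2][2] == 0.13

    def test_s37_step1_sample_sd_from_exact_fractions(self, published_matrices,
                                                      subjects):
        """Step-1 healthy values are {2/9, 2/9, 1/6, 1/6, 1/2, 1/2}; their
        n-1 standard deviation is 0.1597..., reported as 0.16."""
        values = [F(2, 9), F(2, 9), F(1, 6), F(1, 6), F(1, 2), F(1, 2)]
        mean = sum(values) / 6
        sd = math.sqrt(float(sum((v - mean) ** 2 for v in values) / 5))
        assert abs(sd - 0.1597) < 5e-4

        rec = subjects["S37"]
        trajectories, summary = permutation_ensemble(
            rec.initial_belief(), pilot.subject_evidence(rec), published_matrices
        )
        assert sorted(t.steps[0][1].probs[0] for t in trajectories) == sorted(values)
        assert summary.steps[0].mean_healthy == mean
        assert summary.rounded()[0] == (0.30, 0.70, 0.16)

    def test_single_evidence_has_zero_sd(self, published_matrices):
        _, summary = permutation_ensemble(
            BeliefState.point_mass(1), [TestEvidence("T", 1)], published_matrices
        )
        assert summary.n_orderings == 1
        assert summary.steps[0].sd == 0.0

    def test_binary_means_are_complementary(self, published_matrices, subjects):
        _, summary = permutation_ensemble(
            subjects["S08"].initial_belief(),
            pilot.subject_evidence(subjects["S08"]),
            published_matrices,
        )
        for s in summary.steps:
            assert s.mean_healthy + s.mean_depressed == 1
            assert s.sd >= 0

    def test_too_many_evidences_refused(self, published_matrices):
        evs = [TestEvidence(f"F{i}", 0) for i in range(9)]
        with pytest.raises(ValidationError, match="at most"):
            permutation_ensemble(BeliefState.point_mass(0), evs, {})

    def test_order_sensitivity_and_identity_commutativity(self,
                                                          published_matrices,
                                                          subjects):
        """Mixed-interval evidence is order sensitive; identity matrices
        commute trivially."""
        rec = subjects["S15"]
        trajectories, _ = permutation_ensemble(
            rec.initial_belief(), pilot.subject_evidence(rec), published_matrices
        )
        finals = {t.steps[-1][1].probs for t in trajectories}
        assert len(finals) >= 2

        mats = identity_matrices(["T", "A", "O"])
        trajectories, _ = permutation_ensemble(
            rec.initial_belief(), pilot.subject_evidence(rec), mats
        )
        finals = {t.steps[-1][1].probs for t in trajectories}
        assert len(finals) == 1


@pytest.mark.parametrize("initial,feature,interval,expected", [
    # first-step anchors from a certain prior, all feature/interval pairs
    # appearing in the held-out subjects
    ((0, 1), "T", 1, 0.22),
    ((0, 1), "A", 1, 0.17),
    ((0, 1), "O", 1, 0.50),
    ((0, 1), "T", 0, 0.50),
    ((0, 1), "O", 0, 0.44),
    ((1, 0), "T", 1, 0.50),
    ((1, 0), "A", 1, 0.50),
    ((1, 0), "O", 1, 0.38),
])
def test_point_mass_first_step_anchors(initial, feature, interval, expected,
                                       published_matrices):
    belief = BeliefState((F(initial[0]), F(initial[1])))
    out = update_once(belief, TestEvidence(feature, interval), published_matrices)
    assert out.rounded()[0] == expected


def test_bdi_score_maps_to_severity_class():
    assert bdi_class_of_score(5) == 0
    assert bdi_class_of_score(16) == 1
    assert bdi_class_of_score(41) == 5
    with pytest.raises(ValidationError):
        bdi_class_of_score(0)
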
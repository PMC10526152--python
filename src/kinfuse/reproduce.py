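"""Recompute every reported pilot-study quantity from the embedded inputs
and check it, with exact fractions alongside rounded values.

The checks cover: the admissible (λ, μ) bounds from the contingency counts,
the midpoint-calibrated matrices (including the documented divergence of the
O/interval-1 healthy row between the published matrix and the solved count
system), the biased-extreme worked calibrations for T, all 18 published
belief trajectories, and the permutation-ensemble summaries.  Expected
values default to the embedded fixtures; passing a tampered fixture set
makes the corresponding checks fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import pilot
from ._util import format_fraction, round_half_away
from .calibration import lambda_mu_bounds, midpoint_choice, transition_matrices
from .fusion import permutation_ensemble, run_sequence

__all__ = ["CheckResult", "run_reproduction", "format_report"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    expected: str
    actual: str


def _check(name: str, expected, actual) -> CheckResult:
    return CheckResult(name, expected == actual, repr(expected), repr(actual))


def run_reproduction(fixtures=pilot) -> list[CheckResult]:
    """Recompute and verify all embedded pilot results.

    ``fixtures`` is the module (or a namespace with the same attributes)
    holding the expected values; the default is the shipped fixture set.
    """
    checks: list[CheckResult] = []

    # bounds from counts
    for feat, table in fixtures.CONTINGENCY.items():
        b = lambda_mu_bounds(table)
        checks.append(_check(
            f"bounds[{feat}]",
            tuple(map(format_fraction, fixtures.EXPECTED_BOUNDS[feat])),
            (format_fraction(b.lambda_min), format_fraction(b.mu_min)),
        ))

    # midpoint matrices vs the published ones.  The O/I1 healthy row is the
    # documented divergence: derived == published with that row reversed.
    derived = fixtures.derived_matrices()
    for feat in fixtures.FEATURES:
        pub = fixtures.PUBLISHED_MATRICES[feat].matrices
        der = derived[feat].matrices
        if feat == "O":
            expected_der = (pub[0], (tuple(reversed(pub[1][0])), pub[1][1]))
        else:
            expected_der = pub
        checks.append(_check(f"midpoint matrices[{feat}]", expected_der, der))

    # biased-extreme worked calibrations for T
    t_table = fixtures.CONTINGENCY["T"]
    checks.append(_check(
        "biased-healthy matrices[T]",
        fixtures.BIASED_HEALTHY_MATRICES.matrices,
        transition_matrices(t_table, fixtures.BIASED_HEALTHY_CHOICE).matrices,
    ))
    checks.append(_check(
        "biased-depressed matrices[T]",
        fixtures.BIASED_DEPRESSED_MATRICES.matrices,
        transition_matrices(t_table, fixtures.BIASED_DEPRESSED_CHOICE).matrices,
    ))

    # published trajectories (faithful recomputation where a slip is flagged)
    matrices = fixtures.PUBLISHED_MATRICES
    for sid, record in fixtures.SUBJECTS.items():
        for order, (printed, recomputed) in fixtures.PUBLISHED_TRAJECTORIES[sid].items():
            expected = recomputed if recomputed is not None else printed
            traj = run_sequence(
                record.initial_belief(),
                fixtures.subject_evidence(record, order),
                matrices,
            )
            checks.append(_check(
                f"trajectory[{sid}:{'>'.join(order)}]",
                tuple(expected), traj.healthy_path(),
            ))

    # ensemble summaries (recomputed reference)
    for sid, record in fixtures.SUBJECTS.items():
        _, summary = permutation_ensemble(
            record.initial_belief(), fixtures.subject_evidence(record), matrices
        )
        actual = tuple(
            (round_half_away(s.mean_healthy), round_half_away(s.sd))
            for s in summary.steps
        )
        checks.append(_check(
            f"ensemble[{sid}]", tuple(fixtures.RECOMPUTED_ENSEMBLE[sid]), actual
        ))

    return checks


def format_report(checks: list[CheckResult]) -> str:
    width = max(len(c.name) for c in checks)
    lines = []
    for c in checks:
        status = "ok  " if c.passed else "FAIL"
        lines.append(f"{status}  {c.name:<{width}}  {c.actual}")
        if not c.passed:
            lines.append(f"      {'':{width}}  expected {c.expected}")
    n_fail = sum(not c.passed for c in checks)
    lines.append(f"{len(checks) - n_fail}/{len(checks)} checks passed")
    return "\n".join(lines)
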
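"""Flat-file formats: cohort CSV, pitch CSV, calibration JSON artifact,
trajectory/ensemble JSON and TSV, kinetic-system JSON.

Exact rationals are serialized as fraction strings (``"7/9"``), never as
floats, so a calibration artifact round-trips bit-for-bit and diffs cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import format_fraction, parse_fraction, round_half_away
from .calibration import (
    CalibrationResult,
    ClassIntervalPartition,
    ContingencyTable,
    FeatureCalibration,
    LambdaMuBounds,
    LambdaMuChoice,
    ReferenceCohort,
    posterior_given_interval,
)
from .exceptions import ValidationError
from .features import PitchTrack
from .fusion import EnsembleSummary, Trajectory, TransitionMatrixPair
from .kinetic import KineticSystem

__all__ = [
    "read_cohort_csv", "write_cohort_csv", "read_pitch", "write_pitch_csv",
    "calibration_to_dict", "calibration_from_dict",
    "write_calibration_json", "read_calibration_json",
    "trajectory_to_dict", "ensemble_to_dict", "write_fusion_report",
    "write_trajectories_tsv", "read_kinetic_json", "write_kinetic_json",
]


# -- cohort CSV -----------------------------------------------------------

def read_cohort_csv(path, n_classes: int | None = None) -> ReferenceCohort:
    """Read a cohort from CSV with header ``subject_id,class,<feature>...``."""
    frame = pd.read_csv(path)
    for col in ("subject_id", "class"):
        if col not in frame.columns:
            raise ValidationError(
                f"{path}: cohort CSV must have a {col!r} column "
                f"(found {list(frame.columns)})"
            )
    return ReferenceCohort(frame, n_classes=n_classes)


def write_cohort_csv(cohort: ReferenceCohort, path) -> None:
    cohort.frame.to_csv(path, index=False)


# -- pitch tracks ---------------------------------------------------------

def read_pitch(path) -> PitchTrack:
    """Read a pitch track from a two-column CSV (``time_s,f0_hz``) or a
    plain one-number-per-line list of f0 values in Hz."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()
    if not first:
        raise ValidationError(f"{path}: empty pitch file")
    if "," in first[0]:
        frame = pd.read_csv(path)
        if "f0_hz" not in frame.columns:
            raise ValidationError(f"{path}: expected columns time_s,f0_hz")
        values = frame["f0_hz"].to_numpy(dtype=float)
        if "time_s" in frame.columns and len(frame) > 1:
            period = float(np.median(np.diff(frame["time_s"].to_numpy())))
        else:
            period = 0.01
        return PitchTrack(values, period)
    values = np.array([float(line) for line in first if line.strip()])
    return PitchTrack(values)


def write_pitch_csv(track: PitchTrack, path) -> None:
    times = np.arange(len(track)) * track.frame_period_s
    pd.DataFrame({"time_s": times, "f0_hz": track.values}).to_csv(path, index=False)


# -- calibration artifact -------------------------------------------------

def _matrix_to_strings(pair: TransitionMatrixPair) -> list[list[list[str]]]:
    return [
        [[format_fraction(x) for x in row] for row in mat]
        for mat in pair.matrices
    ]


def _matrix_from_strings(feature: str, doc, notes=()) -> TransitionMatrixPair:
    mats = tuple(
        tuple(tuple(parse_fraction(x) for x in row) for row in mat)
        for mat in doc
    )
    return TransitionMatrixPair(feature, mats, notes=tuple(notes))


def calibration_to_dict(result: CalibrationResult) -> dict:
    doc = {"features": list(result.features), "per_feature": {}}
    for feat, cal in result.per_feature.items():
        doc["per_feature"][feat] = {
            "partition": cal.partition.to_dict(),
            "counts": [list(r) for r in cal.table.counts],
            "posterior": [
                [format_fraction(x) for x in row] for row in cal.posterior
            ],
            "bounds": {
                "lambda_min": format_fraction(cal.bounds.lambda_min),
                "mu_min": format_fraction(cal.bounds.mu_min),
                "lambda_clamped": cal.bounds.lambda_clamped,
                "mu_clamped": cal.bounds.mu_clamped,
                "degenerate": list(cal.bounds.degenerate),
            },
            "choice": {
                "lambda": format_fraction(cal.choice.lam),
                "mu": format_fraction(cal.choice.mu),
                "provenance": cal.choice.provenance,
            },
            "matrices": _matrix_to_strings(cal.matrices),
            "notes": list(cal.matrices.notes),
        }
    return doc


def calibration_from_dict(doc: dict) -> CalibrationResult:
    per = {}
    for feat, d in doc["per_feature"].items():
        partition = ClassIntervalPartition.from_dict(d["partition"])
        table = ContingencyTable(feat, tuple(tuple(r) for r in d["counts"]))
        posterior = tuple(
            tuple(parse_fraction(x) for x in row) for row in d["posterior"]
        )
        bounds = LambdaMuBounds(
            feat,
            parse_fraction(d["bounds"]["lambda_min"]),
            parse_fraction(d["bounds"]["mu_min"]),
            bool(d["bounds"]["lambda_clamped"]),
            bool(d["bounds"]["mu_clamped"]),
            tuple(d["bounds"]["degenerate"]),
        )
        choice = LambdaMuChoice(
            feat,
            parse_fraction(d["choice"]["lambda"]),
            parse_fraction(d["choice"]["mu"]),
            d["choice"]["provenance"],
        )
        matrices = _matrix_from_strings(feat, d["matrices"], d.get("notes", ()))
        per[feat] = FeatureCalibration(
            feat, partition, table, posterior, bounds, choice, matrices
        )
    return CalibrationResult(tuple(doc["features"]), per)


def write_calibration_json(result: CalibrationResult, path) -> None:
    Path(path).write_text(json.dumps(calibration_to_dict(result), indent=2) + "\n")


def read_calibration_json(path) -> CalibrationResult:
    return calibration_from_dict(json.loads(Path(path).read_text()))


# -- fusion reports -------------------------------------------------------

def trajectory_to_dict(traj: Trajectory, ndigits: int = 2) -> dict:
    return {
        "order": list(traj.order),
        "initial": [format_fraction(p) for p in traj.initial.probs],
        "steps": [
            {
                "feature": feat,
                "belief": [format_fraction(p) for p in b.probs],
                "rounded": list(b.rounded(ndigits)),
            }
            for feat, b in traj.steps
        ],
    }


def ensemble_to_dict(summary: EnsembleSummary, ndigits: int = 2) -> dict:
    return {
        "n_orderings": summary.n_orderings,
        "steps": [
            {
                "mean_healthy": format_fraction(s.mean_healthy),
                "mean_depressed": format_fraction(s.mean_depressed),
                "sd": s.sd,
                "rounded": [
                    round_half_away(s.mean_healthy, ndigits),
                    round_half_away(s.mean_depressed, ndigits),
                    round_half_away(s.sd, ndigits),
                ],
            }
            for s in summary.steps
        ],
    }


def write_fusion_report(trajectories, summary, path, ndigits: int = 2) -> None:
    doc = {
        "trajectories": [trajectory_to_dict(t, ndigits) for t in trajectories],
        "ensemble": ensemble_to_dict(summary, ndigits),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_trajectories_tsv(trajectories, path, ndigits: int = 2) -> None:
    """One row per (ordering, step): flat TSV for quick inspection."""
    rows = []
    for t in trajectories:
        order = "->".join(t.order)
        for i, (feat, b) in enumerate(t.steps, start=1):
            healthy, *rest = b.rounded(ndigits)
            rows.append({
                "ordering": order,
                "step": i,
                "feature": feat,
                "healthy": healthy,
                "depressed": rest[-1] if rest else 1 - healthy,
                "healthy_exact": format_fraction(b.probs[0]),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- kinetic system -------------------------------------------------------

def read_kinetic_json(path) -> KineticSystem:
    return KineticSystem.from_dict(json.loads(Path(path).read_text()))


def write_kinetic_json(system: KineticSystem, path) -> None:
    Path(path).write_text(json.dumps(system.to_dict(), indent=2) + "\n")
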
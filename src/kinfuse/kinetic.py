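"""Discrete two-subsystem kinetic model (active-particle / functional
subsystem formalism).

A population is split into two functional subsystems, each carrying a finite
state space and a probability distribution over it.  Pairwise encounters —
within a subsystem or across the pair — move particles between states
according to transition tensors, and the distributions evolve by a discrete
master equation of gain/loss (Boltzmann-like) form:

    f_h(t + 1) = f_h(t) + Δt · J_h[f],      J_h = G_h − L_h,

    G_h = Σ_{i,j} τ_{ij} F_{hij} f_i f_j  +  Σ_{i,j} η_{ij} Φ_{hij} f_i g_j,
    L_h = f_h · [ Σ_{i,j} τ_{hj} F_{ihj} f_j  +  Σ_{i,j} η_{hj} Φ_{ihj} g_j ],

where ``F[r, s, j]`` is the probability that a candidate particle in state
``s`` falls to state ``r`` after meeting a field particle of the *same*
subsystem in state ``j``; ``Φ[r, s, j]`` is the analogue for a field particle
of the *other* subsystem; τ and η are non-negative encounter rates.  Because
Σ_r F[r, s, j] = Σ_r Φ[r, s, j] = 1, each J_h sums to zero over ``h`` and
total probability is conserved exactly.

This module is the mathematical substrate (and validation oracle) for the
specialized subject-vs-experiments fusion model in :mod:`kinfuse.fusion`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, StepSizeError

_NORM_TOL = 1e-9      # tensor row-normalization tolerance (hard reject)
_PROB_TOL = 1e-12     # probability bookkeeping tolerance


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name}: non-finite entries")
    return arr


@dataclass(frozen=True)
class StateSpace:
    """Finite ordered set of state labels for one subsystem."""

    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) < 1:
            raise ConfigurationError("StateSpace needs at least one state")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("StateSpace labels must be distinct")

    @property
    def size(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SubsystemState:
    """Probability distribution over a subsystem's states at one time index."""

    distribution: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        dist = _as_array(self.distribution, "distribution")
        if dist.ndim != 1:
            raise ConfigurationError("distribution must be a vector")
        if np.any(dist < -_PROB_TOL) or np.any(dist > 1 + _PROB_TOL):
            raise ConfigurationError("distribution entries must lie in [0, 1]")
        if abs(dist.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"distribution sums to {dist.sum():.15f}, expected 1"
            )
        object.__setattr__(self, "distribution", np.clip(dist, 0.0, 1.0))
        if self.time_index < 0:
            raise ConfigurationError("time_index must be non-negative")


def _check_transition_tensor(values: np.ndarray, name: str) -> None:
    """Entries in [0,1]; for every (candidate s, field j), Σ_r values[r,s,j] = 1."""
    if np.any(values < -_NORM_TOL) or np.any(values > 1 + _NORM_TOL):
        raise ConfigurationError(f"{name}: entries must lie in [0, 1]")
    col_sums = values.sum(axis=0)
    if np.any(np.abs(col_sums - 1.0) > _NORM_TOL):
        bad = np.unravel_index(int(np.argmax(np.abs(col_sums - 1.0))), col_sums.shape)
        raise ConfigurationError(
            f"{name}: transition probabilities over the arrival state must sum "
            f"to 1 for every (candidate, field) pair; offender at (s, j)={bad} "
            f"sums to {col_sums[bad]:.12f}"
        )


@dataclass(frozen=True)
class IntraTransitionTensor:
    """F[r, s, j]: candidate s -> r after meeting field j of the same subsystem."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_array(self.values, "IntraTransitionTensor")
        if arr.ndim != 3 or len(set(arr.shape)) != 1:
            raise ConfigurationError(
                "IntraTransitionTensor must be a cubic 3-index array"
            )
        _check_transition_tensor(arr, "IntraTransitionTensor")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class CrossTransitionTensor:
    """Φ[r, s, j]: candidate s -> r after meeting field j of the other subsystem."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_array(self.values, "CrossTransitionTensor")
        if arr.ndim != 3 or arr.shape[0] != arr.shape[1]:
            raise ConfigurationError(
                "CrossTransitionTensor must have shape (m_h, m_h, m_k)"
            )
        _check_transition_tensor(arr, "CrossTransitionTensor")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class EncounterRates:
    """Non-negative encounter rates: intra τ per subsystem, cross η per ordered pair.

    Units are "interactions per unit Δt"; the model treats them as
    dimensionless multipliers of the stepwise update.
    """

    intra: tuple[np.ndarray, np.ndarray]
    cross: tuple[np.ndarray, np.ndarray]  # (η^{12}, η^{21})

    def __post_init__(self):
        intra = tuple(_as_array(m, f"tau[{i}]") for i, m in enumerate(self.intra))
        cross = tuple(_as_array(m, f"eta[{i}]") for i, m in enumerate(self.cross))
        for name, mats in (("tau", intra), ("eta", cross)):
            for i, m in enumerate(mats):
                if m.ndim != 2:
                    raise ConfigurationError(f"{name}[{i}] must be a matrix")
                if np.any(m < 0):
                    raise ConfigurationError(f"{name}[{i}] has negative rates")
        object.__setattr__(self, "intra", intra)
        object.__setattr__(self, "cross", cross)


@dataclass(frozen=True)
class KineticSystem:
    """Complete two-subsystem system: spaces, states, tensors, rates, Δt."""

    spaces: tuple[StateSpace, StateSpace]
    states: tuple[SubsystemState, SubsystemState]
    intra: tuple[IntraTransitionTensor, IntraTransitionTensor]
    cross: tuple[CrossTransitionTensor, CrossTransitionTensor]
    rates: EncounterRates
    dt: float = 1.0

    def __post_init__(self):
        if self.dt < 0:
            raise ConfigurationError("dt must be positive")
        m = (self.spaces[0].size, self.spaces[1].size)
        for h in (0, 1):
            if self.states[h].distribution.shape != (m[h],):
                raise ConfigurationError(
                    f"states[{h}] length does not match state space size {m[h]}"
                )
            if self.intra[h].values.shape != (m[h], m[h], m[h]):
                raise ConfigurationError(
                    f"intra tensor F^({h + 1}) has shape "
                    f"{self.intra[h].values.shape}, expected {(m[h],) * 3}"
                )
            k = 1 - h
            if self.cross[h].values.shape != (m[h], m[h], m[k]):
                raise ConfigurationError(
                    f"cross tensor Phi^({h + 1},{k + 1}) has shape "
                    f"{self.cross[h].values.shape}, expected {(m[h], m[h], m[k])}"
                )
            if self.rates.intra[h].shape != (m[h], m[h]):
                raise ConfigurationError(
                    f"encounter rate tau^({h + 1}) has shape "
                    f"{self.rates.intra[h].shape}, expected {(m[h], m[h])}"
                )
            if self.rates.cross[h].shape != (m[h], m[k]):
                raise ConfigurationError(
                    f"encounter rate eta^({h + 1},{k + 1}) has shape "
                    f"{self.rates.cross[h].shape}, expected {(m[h], m[k])}"
                )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "labels": [list(s.labels) for s in self.spaces],
            "distributions": [self.states[h].distribution.tolist() for h in (0, 1)],
            "time_index": self.states[0].time_index,
            "intra_tensors": [self.intra[h].values.tolist() for h in (0, 1)],
            "cross_tensors": [self.cross[h].values.tolist() for h in (0, 1)],
            "tau": [self.rates.intra[h].tolist() for h in (0, 1)],
            "eta": [self.rates.cross[h].tolist() for h in (0, 1)],
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "KineticSystem":
        required = {
            "labels", "distributions", "intra_tensors", "cross_tensors",
            "tau", "eta",
        }
        missing = required - set(doc)
        if missing:
            raise ConfigurationError(f"kinetic system document missing {sorted(missing)}")
        spaces = tuple(StateSpace(tuple(lbls)) for lbls in doc["labels"])
        t0 = int(doc.get("time_index", 0))
        states = tuple(
            SubsystemState(np.asarray(d, dtype=float), t0)
            for d in doc["distributions"]
        )
        intra = tuple(IntraTransitionTensor(np.asarray(v)) for v in doc["intra_tensors"])
        cross = tuple(CrossTransitionTensor(np.asarray(v)) for v in doc["cross_tensors"])
        rates = EncounterRates(
            intra=tuple(np.asarray(v, dtype=float) for v in doc["tau"]),
            cross=tuple(np.asarray(v, dtype=float) for v in doc["eta"]),
        )
        return cls(spaces, states, intra, cross, rates, float(doc.get("dt", 1.0)))


def rhs(system: KineticSystem) -> tuple[np.ndarray, np.ndarray]:
    """Gain-minus-loss right-hand side J_h for both subsystems.

    Each returned vector sums to zero (probability conservation), an
    algebraic consequence of the tensor normalizations.
    """
    out = []
    for h in (0, 1):
        k = 1 - h
        f = system.states[h].distribution
        g = system.states[k].distribution
        F = system.intra[h].values
        Phi = system.cross[h].values
        tau = system.rates.intra[h]
        eta = system.rates.cross[h]
        gain = np.einsum("ij,rij,i,j->r", tau, F, f, f)
        gain += np.einsum("ij,rij,i,j->r", eta, Phi, f, g)
        loss = np.einsum("hj,ihj,j->h", tau, F, f)
        loss += np.einsum("hj,ihj,j->h", eta, Phi, g)
        out.append(gain - f * loss)
    return out[0], out[1]


def step(system: KineticSystem) -> KineticSystem:
    """One stepwise update f(t+1) = f(t) + Δt·J[f(t)] for both subsystems.

    Raises :class:`StepSizeError` when any probability leaves [0, 1] by more
    than 1e-12 (the discrete step is too large for the given rates).
    """
    j1, j2 = rhs(system)
    new_states = []
    for h, j in ((0, j1), (1, j2)):
        f_new = system.states[h].distribution + system.dt * j
        if np.any(f_new < -_PROB_TOL) or np.any(f_new > 1 + _PROB_TOL):
            raise StepSizeError(
                f"subsystem {h + 1}: step of size dt={system.dt} leaves the "
                f"probability simplex (min={f_new.min():.3e}, max={f_new.max():.3e})"
            )
        new_states.append(
            SubsystemState(np.clip(f_new, 0.0, 1.0), system.states[h].time_index + 1)
        )
    return replace(system, states=(new_states[0], new_states[1]))
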
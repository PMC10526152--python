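# Methods

## Model

`kinfuse` implements a discrete-state, discrete-time kinetic model of
interacting functional subsystems, specialized to diagnostic data fusion.

**General substrate** (`kinfuse.kinetic`).  Two subsystems, each with a
finite state space and a probability distribution over it, evolve by a
gain/loss (Boltzmann-type) master equation: candidate particles change state
on pairwise encounters, governed by transition tensors F (within a
subsystem) and Φ (across subsystems) and non-negative encounter rates τ, η.
The tensors are normalized over the arrival state, which makes each
subsystem's right-hand side sum to zero identically — total probability is
conserved by construction, and the test suite checks both the conservation
law and agreement with a literal brute-force evaluation of every term.
Time advances in unit steps, `f(t+1) = f(t) + Δt·J[f(t)]` with Δt = 1 by
default; a step that pushes any probability outside [0, 1] by more than
1e-12 is rejected as a step-size error rather than clipped.  Only two
subsystems are supported (the application needs exactly two: one subject,
one battery of experiments); tensors are dense (state spaces are tiny) and
normalization is validated at construction with tolerance 1e-9 and
hard-rejected otherwise — silent renormalization would mask calibration
bugs upstream.  The units of τ and η are "interactions per unit Δt"; since
Δt is the dimensionless step, they are treated as dimensionless multipliers.

**Specialized fusion model** (`kinfuse.fusion`).  The subject subsystem has
one member whose state space is the set of diagnostic classes (binary
default: healthy/depressed; the six BDI-II severity classes are provided
for bookkeeping).  The experiment subsystem's members never change state,
and the subject interacts with one experiment per step with encounter rate
1.  Under these assumptions the update for a test outcome observed in
interval k reduces exactly to left-multiplication of the belief row-vector
by the feature's row-stochastic matrix Φ^(I_k).  Both the gain/loss form
and the matrix-product form are implemented and asserted equal on every
call (they are algebraically identical for row-stochastic matrices).  A
one-shot superposed variant accepts outcome *distributions* for several
tests at once; it is not equivalent to the sequential rule, is not a
composition of stochastic maps, and can leave the simplex for several
strong simultaneous outcomes — that situation raises a validation error
rather than silently renormalizing.

All fusion and calibration arithmetic uses exact rationals
(`fractions.Fraction`).  Reporting rounds half away from zero to 2 decimals
(0.465 → 0.47), matching the convention of every published pilot value;
`precision` is configurable but never affects the arithmetic.

**Order dependence.**  A battery of tests is a product of stochastic
matrices and therefore order dependent.  `permutation_ensemble` enumerates
all orderings (refusing more than 8 tests — factorial growth), and
summarizes step i by the mean class-0 probability and the *sample*
(n − 1 denominator) standard deviation over orderings, computed on exact
values before rounding.  The n − 1 convention is deliberate: it is the one
that reproduces the pilot's published spread values (the n denominator
gives 0.146 where the pilot reports 0.16 for the first fused step of
subject S37).  By contrast, the per-class descriptive statistics of the
calibration stage use the population (1/n_h) standard deviation, again
following the pilot's printed definitions.  The two conventions coexist on
purpose.

## Calibration (`kinfuse.calibration`)

For each feature the pipeline is: class-interval partition → contingency
counts → interval-conditional posteriors → admissibility bounds → (λ, μ)
choice → matrices.

* **Partitions.**  The pilot's confidence intervals are shipped as
  fixtures.  When a partition must be estimated (binary cohorts only), the
  package searches exhaustively over pairs of cut points placed at midpoints
  between adjacent sorted values, maximizing the number of correctly
  partitioned subjects (class 0 inside the central interval, class 1
  outside), breaking ties toward the widest central interval.  This
  procedure is the package's own choice — the source methodology leaves the
  interval-construction step unspecified — and the shipped pilot partitions
  remain the canonical inputs.  Shared endpoints (the pilot tables print
  e.g. 285.79 as closed in both I0 and I1 of feature T) resolve to the
  central interval; the outermost finite endpoints are widened to ±inf when
  assigning new subjects, since printed outer bounds are inconsistent
  between tables and a held-out subject's value (T = 1119.51) must fall in
  the flank either way.
* **Counts and posteriors.**  n_hk counts class-h subjects with values in
  I_k; the diagonal-dominance condition n_hh > Σ_{k≠h} n_hk is checked and
  its violation warns (it genuinely fails for feature O in the pilot:
  depressed subjects concentrate in the healthy-side interval).
  P(C_h|I_k) = n_hk / Σ_i n_ik with exact fractions; empty interval columns
  are an error.
* **Bounds and matrices.**  The binary transition system is
  under-determined; with λ = P(C0|C0∩I0) and μ = P(C1|C1∩I1) free, the
  solved matrices are row-stochastic exactly when
  λ ≥ max(0, 1 − n10/n00) and μ ≥ max(0, 1 − n01/n11) (negative raw bounds
  carry no constraint and are clamped, flagged).  The midpoint of the
  admissible rectangle is the unbiased default; the extremes encode
  deliberate bias toward "healthy" or "depressed" and are reproduced as
  worked fixtures.  Degenerate counts (n10 = 0 or n01 = 0) force λ = 1
  (resp. μ = 1) and leave one row unconstrained; it is set to the
  no-evidence row ((0, 1) resp. (1, 0)) and flagged.
* **Documented divergence.**  For feature O, the bundled pilot matrix for
  interval I1 has healthy row (3/8, 5/8), while solving the count system at
  the same midpoint μ = 1/2 gives (5/8, 3/8) — the same entries in the
  opposite order.  The bundled row is not a solution of the count system
  for any admissible μ; it is retained verbatim because every published
  pilot trajectory and ensemble summary was computed with it, and the
  package's purpose includes reproducing those numbers exactly.  All
  reproduction paths therefore use the bundled (`pilot.PUBLISHED_MATRICES`)
  set, while `calibration.transition_matrices` and
  `pilot.derived_matrices()` expose the internally consistent solution; the
  acceptance suite asserts the re-derivation reproduces five of the six
  bundled matrices exactly and marks the O/I1 case as the known divergence
  (that one check fails by design).  Two further published values are
  downstream arithmetic slips, not matrix issues: the final steps of the
  A→T→O orderings for subjects S37 and S08 (published 0.42 and 0.47;
  faithful recomputation 0.47 and 0.45), which contaminate one published
  ensemble cell (S37 step III: published 0.36/0.07, recomputed 0.37/0.08).
  The package asserts the recomputed values and reports the discrepancies
  in `kinfuse reproduce`.

## Speech indicators (`kinfuse.features`)

T = Σ|Δf0| (Hz), A = T/(N−1) (Hz), O = percentage of adjacent difference
pairs with strictly opposite signs.  A zero difference carries no sign: a
pair containing one counts as no inversion but stays in the denominator,
keeping O defined and conservative on plateaued tracks (the source
definition is silent on ties; this is the package's choice, stated
prominently because it changes O on quantized tracks).  The module consumes
voiced-frame sequences only; pitch extraction from audio is out of scope,
and the pilot subjects' indicator values are consumed as given inputs
because the recordings and frame rate are unavailable.

## Synthetic data (`kinfuse.synth`)

The cohort generator draws per-class feature values from explicit
distributions: normals for central classes, two-component normal mixtures
for the bimodal flank structure implied by split depressed-side intervals.
The shipped default emulates the pilot cohort — class sizes 11 + 11, and
distribution parameters solved analytically (normal CDF) so that each
class's probability of falling in its central interval equals the pilot
contingency proportion (T: 7/11 and 2/11; A: 8/11 and 2/11; O: 7/11 and
8/11 — for O the depressed class deliberately lands *inside* the
healthy-side interval more often, reproducing the pilot's poorly separating
oscillation indicator).  Component centers for the flank mixtures (220/500
Hz for T, 11/26 Hz for A) were placed at plausible flank locations and the
common spread solved to hit the target probability.  What the generator
does **not** emulate: within-subject correlation between T, A and O (they
are drawn independently per subject, while real T and A are functionally
linked), measurement error structure, or any acoustic realism.  Passing
tests therefore demonstrate statistical correctness of the pipeline, not
clinical validity on real speech.

The pitch generator produces a contour whose slope sign flips with a
specified per-frame probability (first step always ascending), with jump
magnitudes uniform on a strictly positive range so no zero differences
occur; the oscillation indicator converges to 100 × the flip probability.
A constant upward shift keeps the track positive when the walk wanders low;
shifting changes no difference and hence no indicator.  A nonzero drift
adds to every signed step and distorts the flip probability — documented,
default 0.

One explicit integer seed drives every draw through
`numpy.random.default_rng`; there is no global generator state, and equal
specs yield identical outputs.

## Problem sizes and numerics

The pilot reproduction is desk scale (exact rational arithmetic on 2×2
matrices; all orderings of 3 tests).  The statistical tests use a
10 000-subject synthetic cohort for generator-proportion checks (tolerance
0.05), 5 000 subjects for posterior recovery (tolerance 0.03, fixed seed),
10 000-frame pitch tracks for oscillation convergence (tolerance 2
percentage points), and 100 seeds of a 60-subject cohort for end-to-end
pipeline closure.  Kinetic-core tolerances: tensor normalization 1e-9
(reject), probability bookkeeping 1e-12, conservation checks 1e-10,
vectorized-vs-brute-force agreement 1e-12 on systems with at most 4 states
per subsystem.

## Known limitations

* Matrix calibration is binary-only: for s > 2 classes the count system
  leaves s² − 2s degrees of freedom per interval and no principled
  selection rule exists; the six-class BDI space is provided for labeling
  but not calibrated.
* The model stops at fused probabilities; decision thresholds are out of
  scope.
* Encounter rates in the specialized model are fixed to 1 — the published
  pilot numbers are only consistent with that choice, and nothing in the
  calibration identifies them separately.
* The JSON schema shipped for kinetic systems documents the format; input
  validation is performed by the package's own checks.
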
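"""Sequentially update one subject's diagnosis with three test outcomes.

Subject S37 is labeled depressed by the BDI-II questionnaire (prior belief:
healthy 0, depressed 1).  All three speech indicators fall in the
depressed-side interval I1, yet each update moves a little probability mass
back toward "healthy" because the reference cohort's intervals are not
perfectly class-pure.
"""

from kinfuse import pilot
from kinfuse._util import format_fraction
from kinfuse.fusion import run_sequence

record = pilot.SUBJECTS["S37"]
trajectory = run_sequence(
    record.initial_belief(),
    pilot.subject_evidence(record, ("T", "A", "O")),
    pilot.PUBLISHED_MATRICES,
)

h, d = trajectory.initial.rounded()
print(f"prior (BDI): healthy={h:.2f} depressed={d:.2f}")
for feature, belief in trajectory.steps:
    h, d = belief.rounded()
    exact = ", ".join(format_fraction(p) for p in belief.probs)
    print(f"after {feature} (interval I{record.intervals[feature]}): "
          f"healthy={h:.2f} depressed={d:.2f}   (exact: {exact})")

print()
print("The final pair is the fused probability of each diagnostic class")
print("after all three tests, in this particular test order.")
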
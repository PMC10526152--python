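"""Order dependence: run every test ordering and summarize the spread.

The sequential update is a product of stochastic matrices, so different test
orders give different final beliefs.  For subject S15 (depressed by BDI, but
healthy-side on two of three indicators) the six orderings disagree
noticeably; the per-step mean and sample standard deviation quantify that
spread and give a single order-free summary.
"""

from kinfuse import pilot
from kinfuse.fusion import permutation_ensemble

record = pilot.SUBJECTS["S15"]
trajectories, summary = permutation_ensemble(
    record.initial_belief(),
    pilot.subject_evidence(record),
    pilot.PUBLISHED_MATRICES,
)

for traj in trajectories:
    path = " -> ".join(
        f"{feat}({belief.rounded()[0]:.2f},{belief.rounded()[1]:.2f})"
        for feat, belief in traj.steps
    )
    print(f"BDI(0,1) -> {path}")

print()
for i, (mu_h, mu_d, sd) in enumerate(summary.rounded(), start=1):
    print(f"step {i}: mean healthy {mu_h:.2f}, mean depressed {mu_d:.2f}, "
          f"sample sd {sd:.2f}")

print()
print("The step-3 row is the order-free fused diagnosis: averaged over all")
print("orderings, S15 ends near 50/50 despite the certain depressed prior.")
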
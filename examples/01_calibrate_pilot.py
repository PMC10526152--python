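"""Calibrate transition matrices from the pilot contingency counts.

For each speech indicator (T = total pitch variation, A = average variation,
O = oscillation percentage) the 22-subject reference cohort yields a 2x2
contingency table over the healthy/depressed classes and their confidence
intervals I0/I1.  The under-determined transition system leaves two free
parameters per feature — lambda (trust in an I0 outcome) and mu (trust in an
I1 outcome) — bounded below by the counts; the unbiased midpoint choice
fixes them.
"""

from kinfuse import pilot
from kinfuse._util import format_fraction
from kinfuse.calibration import lambda_mu_bounds, midpoint_choice, transition_matrices

for feat, table in pilot.CONTINGENCY.items():
    bounds = lambda_mu_bounds(table)
    choice = midpoint_choice(bounds)
    pair = transition_matrices(table, choice)
    print(f"feature {feat}: counts {table.counts}")
    print(f"  lambda in [{format_fraction(bounds.lambda_min)}, 1], "
          f"mu in [{format_fraction(bounds.mu_min)}, 1] "
          f"-> midpoint lambda={format_fraction(choice.lam)}, "
          f"mu={format_fraction(choice.mu)}")
    for k in (0, 1):
        rows = [
            "[" + ", ".join(format_fraction(x) for x in row) + "]"
            for row in pair.for_interval(k)
        ]
        print(f"  Phi(I{k}) = {rows[0]} / {rows[1]}")
    print()

print("Each matrix row is [P(stay/become healthy), P(stay/become depressed)]")
print("conditional on the current class (row 1: healthy, row 2: depressed)")
print("and on the feature value falling in the given interval.")
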
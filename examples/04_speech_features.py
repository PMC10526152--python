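"""Compute the three speech indicators from a pitch track and map them to
class intervals.

A synthetic f0 contour stands in for a real voiced-frame pitch track.  T
(total variation, Hz) and A (average variation, Hz) measure contour
dynamics; O (oscillation percentage) measures how often the contour's slope
reverses.  Each value is then assigned to the healthy-side (I0) or
depressed-side (I1) interval of the pilot partitions, which is the evidence
the fusion model consumes.
"""

from kinfuse import pilot
from kinfuse.features import assign_interval, compute_features
from kinfuse.synth import PitchSpec, generate_pitch

track = generate_pitch(
    PitchSpec(frames=400, base_hz=210.0, oscillation_prob=0.55,
              jump_low=0.5, jump_high=2.5, seed=4)
)
fv = compute_features(track)
print(f"frames: {len(track)}")
print(f"T = {fv.T:.2f} Hz   (sum of absolute frame-to-frame f0 changes)")
print(f"A = {fv.A:.2f} Hz   (T per consecutive difference)")
print(f"O = {fv.O:.2f} %    (share of slope sign inversions)")

for feat, value in (("T", fv.T), ("A", fv.A), ("O", fv.O)):
    k = assign_interval(value, pilot.PARTITIONS[feat])
    side = "healthy-side" if k == 0 else "depressed-side"
    print(f"{feat} = {value:.2f} falls in I{k} ({side})")
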
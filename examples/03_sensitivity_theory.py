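"""Closed-form sensitivity analysis for sequencing-experiment design.

Asks three planning questions: how much variant coverage is needed for a
50% or 90% chance of catching a new junction, how little read length helps,
how much coverage bias (negative-binomial size r) hurts, and what variant
frequencies are effectively visible in a real pooled sample sequenced to
320-fold with 80-base reads.
"""
import math

from svjc.sensitivity import coverage_for_sensitivity, frequency_threshold

print("variant coverage needed (E=6):")
for target, L, r in [(0.5, 40, math.inf), (0.5, 250, math.inf),
                     (0.9, 40, math.inf), (0.9, 40, 5.0)]:
    C = coverage_for_sensitivity(target, L=L, r=r)
    bias = "unbiased" if math.isinf(r) else f"r={r:g} (high bias)"
    print(f"  {target:.0%} detection, {L:>3}-base reads, {bias:<18}"
          f" -> {C:5.1f}-fold")

print("\nfrequency thresholds for an 80-base, 320-fold pooled sample "
      "(r=25):")
for sens in (0.95, 0.50, 0.05):
    thr = frequency_threshold(sens, total_coverage=320, L=80, r=25)
    print(f"  {sens:.0%} of junctions at frequency > {thr:.2%} are detected")

print("\nLonger reads barely lower the coverage requirement (5.5 -> 3.4 "
      "fold going from 40 to 250 bases) and coverage bias mostly costs the "
      "last few percent of sensitivity; total read depth is what matters.")
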
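"""Exact frequency recovery on a 1:1 tiling mixture.

Builds a 100-kb random circular genome, plants ten 1,000-bp deletions away
from repeats, emits one error-free 50-base read per position per strand from
both the reference and the variant genome, and calls junctions on the
mixture. Every deletion junction is present in exactly half of the genomes,
so every estimated frequency should be exactly 0.5 — this exercises the
target-size normalization, including breakpoint-ambiguity corrections.
"""
from svjc import mix_samples, plant_random_deletions, random_genome, \
    tiling_reads
from svjc.pipeline import call_junctions

genome = random_genome(100_000, seed=1)
variant, deletions = plant_random_deletions(genome, count=10, size=1000,
                                            seed=2)
mix = mix_samples(tiling_reads(variant, 50, src="var"),
                  tiling_reads(genome, 50, src="ref"))
result = call_junctions(mix, genome)

truth = {tuple(s1) + tuple(s2) for s1, s2 in variant.truth_junctions()}
print(f"planted deletions : {len(deletions)}")
print(f"junctions accepted: {len(result.accepted)} "
      f"(false positives: {len(result.accepted_keys() - truth)})")
print("side_1  side_2  A  n_V  n_R        frequency")
for ev in sorted(result.accepted, key=lambda e: e.junction.key()):
    s1, s2 = ev.sides
    print(f"{s1.ref_position + 1:>6}  {s2.ref_position + 1:>6}  {ev.A}  "
          f"{ev.n_V:>3}  {str(ev.n_R):<9}  {ev.F_V:.4f}")
print("\nEvery frequency is exactly 0.5000: the normalized variant and "
      "reference spanning counts (f = n / (L - (2E + A) + 1)) cancel "
      "perfectly in the 1:1 mixture, whatever the breakpoint ambiguity A.")
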
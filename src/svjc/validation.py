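"""Synthetic validation experiments for the junction caller.

These functions reproduce the package's two benchmark designs end to end:

* the *tiling* experiment — error-free reads starting at every position on
  both strands of a reference genome and of a variant genome carrying
  planted 1,000-bp deletions, mixed 1:1 so every deletion junction is
  present at exactly 50% and should be recovered with its frequency
  computed exactly;

* the *sensitivity* experiment — randomly sampled reads with the variant
  genome at low coverage topped up with reference reads, measuring the
  fraction of planted junctions recovered, with or without the
  Illumina-like error model.

Both return plain dictionaries so they can drive tests and scripts alike.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .genome import Genome, VariantGenome, plant_random_deletions, random_genome
from .pipeline import RunConfig, call_junctions
from .simulate import (CoverageSpec, ERROR_FREE, ErrorModel, mix_samples,
                       sample_reads, tiling_reads)

__all__ = ["make_genome_pair", "tiling_experiment", "sensitivity_experiment"]


def make_genome_pair(genome_size: int, n_deletions: int, deletion_size: int,
                     seed: int, read_length: int = 50
                     ) -> tuple[Genome, VariantGenome]:
    """Seeded random reference plus a variant with planted deletions whose
    breakpoints stay a read length clear of any exact repeat >= 50 bp."""
    genome = random_genome(genome_size, seed=seed)
    vg, _ = plant_random_deletions(genome, n_deletions, deletion_size,
                                   min_repeat=50, seed=seed + 1,
                                   flank=read_length)
    return genome, vg


def _truth_keys(vg: VariantGenome) -> set[tuple[int, int, int, int]]:
    return {tuple(s1) + tuple(s2) for s1, s2 in vg.truth_junctions()}


def tiling_experiment(genome_size: int = 1_000_000, n_deletions: int = 100,
                      deletion_size: int = 1000, read_length: int = 50,
                      seed: int = 0,
                      config: RunConfig = RunConfig()) -> dict:
    """Run the caller on the 1:1 error-free tiling mixture.

    Returns the number of planted junctions detected, the number of accepted
    junctions absent from the truth set, and the list of estimated
    frequencies of the detected planted junctions.
    """
    genome, vg = make_genome_pair(genome_size, n_deletions, deletion_size,
                                  seed, read_length)
    mix = mix_samples(tiling_reads(vg, read_length, src="var"),
                      tiling_reads(genome, read_length, src="ref"))
    result = call_junctions(mix, genome, config=config)
    truth = _truth_keys(vg)
    accepted = {e.junction.key(): e for e in result.accepted}
    detected = truth & set(accepted)
    return {
        "n_truth": len(truth),
        "n_detected": len(detected),
        "n_false_positive": len(set(accepted) - truth),
        "frequencies": [accepted[k].F_V for k in sorted(detected)],
        "result": result,
    }


def sensitivity_experiment(genome_size: int = 500_000, n_deletions: int = 100,
                           deletion_size: int = 1000, read_length: int = 50,
                           variant_coverage: float = 4.0,
                           total_coverage: float = 100.0,
                           errors: Optional[ErrorModel] = None,
                           n_replicates: int = 3, seed: int = 0,
                           config: RunConfig = RunConfig()) -> dict:
    """Detection fraction of planted junctions from randomly sampled reads.

    The variant genome is sequenced at ``variant_coverage`` and mixed with
    reference reads topping the pool up to ``total_coverage`` (uniform
    Poisson sampling); each replicate reseeds the read sampling only, so the
    genome pair and truth set stay fixed.
    """
    errors = errors if errors is not None else ERROR_FREE
    genome, vg = make_genome_pair(genome_size, n_deletions, deletion_size,
                                  seed, read_length)
    truth = _truth_keys(vg)
    ref_coverage = total_coverage - variant_coverage
    fractions = []
    false_positives = []
    for rep in range(n_replicates):
        rep_seed = seed + 1000 + 2 * rep
        var_reads = sample_reads(
            vg, CoverageSpec(variant_coverage, read_length), errors,
            seed=rep_seed, src="var")
        ref_reads = sample_reads(
            genome, CoverageSpec(ref_coverage, read_length), errors,
            seed=rep_seed + 1, src="ref")
        result = call_junctions(mix_samples(var_reads, ref_reads), genome,
                                config=config)
        accepted = result.accepted_keys()
        fractions.append(len(truth & accepted) / len(truth))
        false_positives.append(len(accepted - truth))
    return {
        "n_truth": len(truth),
        "fractions": fractions,
        "mean_fraction": float(np.mean(fractions)),
        "false_positives": false_positives,
    }
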
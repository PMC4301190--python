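import numpy as np
import pytest

from svjc import (mix_samples, plant_random_deletions, random_genome,
                  tiling_reads)
from svjc.pipeline import call_junctions


def truth_keys(variant_genome):
    return {tuple(s1) + tuple(s2) for s1, s2 in
            variant_genome.truth_junctions()}


@pytest.fixture(scope="session")
def ref50k():
    return random_genome(50_000, seed=101)


@pytest.fixture(scope="session")
def planted50k(ref50k):
    return plant_random_deletions(ref50k, count=10, size=1000, seed=102)


@pytest.fixture(scope="session")
def tiling_call(ref50k, planted50k):
    """Shared 1:1 tiling-mixture pipeline run (10 planted deletions)."""
    vg, _ = planted50k
    mix = mix_samples(tiling_reads(vg, 50, src="var"),
                      tiling_reads(ref50k, 50, src="ref"))
    return call_junctions(mix, ref50k)
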
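"""Junction detection: seeding, ambiguity, spanning rules, tiling exactness."""
import numpy as np
import pytest

from conftest import truth_keys
from svjc.genome import (Genome, MobileElementAnnotation, StructuralVariant,
                         apply_variants, random_genome)
from svjc.junctions import (CandidateJunction, JunctionSide, SpanningPolicy,
                            call_polymorphic_junctions, compute_ambiguity,
                            count_spanning_reads, junction_window,
                            reconstruct_junction_sequence, seed_candidates)
from svjc.mapping import KmerIndex, map_reads_batch
from svjc.pipeline import RunConfig, call_junctions
from svjc.simulate import (CoverageSpec, DEFAULT_ILLUMINA, ERROR_FREE,
                           ReadSet, mix_samples, sample_reads, tiling_reads)


def _deletion_candidate(genome, s, e, flank=50):
    cand = CandidateJunction(side_1=JunctionSide(s - 1, -1),
                             side_2=JunctionSide(e, +1))
    cand = reconstruct_junction_sequence(cand, genome, flank)
    return compute_ambiguity(cand, genome)


def _clean_breakpoints(seq, s0, e0):
    """Shift until the deletion has zero homology at both boundaries."""
    for i in range(200):
        s, e = s0 + i, e0 + i
        if seq[s] != seq[e] and seq[s - 1] != seq[e - 1]:
            return s, e
    raise AssertionError("no clean breakpoint found")


@pytest.fixture(scope="module")
def genome():
    return random_genome(20_000, seed=70)


class TestSeeding:
    def _reads_for_deletion(self, genome, s, e, offsets):
        seq = genome.sequence
        window = seq[s - 50:s] + seq[e:e + 50]
        return [(f"r{i}", window[50 - off:100 - off])
                for i, off in enumerate(offsets)]

    def test_single_split_read_is_below_seed_min(self, genome):
        s, e = _clean_breakpoints(genome.sequence, 5000, 9000)
        rs = ReadSet.from_strings(self._reads_for_deletion(genome, s, e, [25]))
        idx = KmerIndex(genome, 12)
        table = map_reads_batch(rs, idx)
        assert seed_candidates(table, rs, genome=genome) == []

    def test_two_split_reads_seed_one_candidate(self, genome):
        s, e = _clean_breakpoints(genome.sequence, 5000, 9000)
        rs = ReadSet.from_strings(
            self._reads_for_deletion(genome, s, e, [20, 30]))
        idx = KmerIndex(genome, 12)
        table = map_reads_batch(rs, idx)
        cands = seed_candidates(table, rs, genome=genome)
        assert len(cands) == 1
        assert cands[0].key() == (s - 1, -1, e, +1)
        assert cands[0].supporting_split_reads == 2

    def test_homology_shifted_breakpoints_merge(self, genome):
        # engineer 3-base homology: both boundaries preceded by same triplet
        seq = genome.sequence
        s, e = 6000, 10_000
        seq = seq[:s - 3] + "ACG" + seq[s:e - 3] + "ACG" + seq[e:]
        g = Genome("g", seq, genome.topology)
        if g.sequence[s] == g.sequence[e]:  # keep homology exactly 3
            g = Genome("g", seq[:e] + "A" + seq[e + 1:], genome.topology) \
                if seq[s] != "A" else \
                Genome("g", seq[:e] + "C" + seq[e + 1:], genome.topology)
        reads = self._reads_for_deletion(g, s, e, [20, 25, 30])
        # add the reverse-complement of one read: same junction, other strand
        from svjc._seq import revcomp
        reads.append(("rc", revcomp(reads[0][1])))
        rs = ReadSet.from_strings(reads)
        idx = KmerIndex(g, 12)
        table = map_reads_batch(rs, idx)
        cands = seed_candidates(table, rs, genome=g)
        assert len(cands) == 1
        assert cands[0].supporting_split_reads == 4

    def test_seeding_is_order_independent(self, genome):
        s, e = _clean_breakpoints(genome.sequence, 5000, 9000)
        reads = self._reads_for_deletion(genome, s, e, [18, 24, 31])
        idx = KmerIndex(genome, 12)
        keys = []
        for order in ([0, 1, 2], [2, 0, 1]):
            rs = ReadSet.from_strings([reads[i] for i in order])
            table = map_reads_batch(rs, idx)
            cands = seed_candidates(table, rs, genome=genome)
            keys.append([c.key() for c in cands])
        assert keys[0] == keys[1] != []


class TestAmbiguity:
    def test_no_shared_boundary_bases_gives_zero(self):
        g = random_genome(5000, seed=71)
        s, e = _clean_breakpoints(g.sequence, 1000, 3000)
        cand = _deletion_candidate(g, s, e)
        assert cand.A == 0

    def test_three_base_overlap_gives_three(self):
        g = random_genome(5000, seed=72)
        seq = g.sequence
        s, e = _clean_breakpoints(seq, 1000, 3000)
        # make the three bases after both breakpoints identical
        seq = seq[:e] + seq[s:s + 3] + seq[e + 3:]
        if seq[s + 3] == seq[e + 3]:
            repl = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[e + 3]]
            seq = seq[:e + 3] + repl + seq[e + 4:]
        g2 = Genome("g", seq, "circular")
        cand = _deletion_candidate(g2, s, e)
        assert cand.A == 3
        # slide-breakpoint oracle: a placement is equivalent when deleting
        # the shifted interval yields the identical variant sequence
        ref_variant = seq[:s] + seq[e:]
        placements = sum(
            seq[:s + shift] + seq[e + shift:] == ref_variant
            for shift in range(-10, 11))
        assert placements == cand.A + 1

    def test_target_size_shrinks_with_homology(self):
        g = random_genome(5000, seed=73)
        s, e = _clean_breakpoints(g.sequence, 1000, 3000)
        cand = _deletion_candidate(g, s, e)
        lo, hi = junction_window(cand, E=6)
        assert hi - lo == 12 + cand.A


@pytest.fixture(scope="module")
def setup():
    g = random_genome(4000, seed=74)
    s, e = _clean_breakpoints(g.sequence, 1000, 3000)
    cand = _deletion_candidate(g, s, e)
    idx = KmerIndex(g, 12)
    policy = SpanningPolicy()
    return g, s, e, cand, idx, policy


class TestSpanningRules:
    def _count(self, g, cand, idx, policy, reads):
        rs = ReadSet.from_strings(reads)
        table = map_reads_batch(rs, idx)
        res = count_spanning_reads(rs, [cand], table, idx, policy)
        return res[0]

    def test_read_covering_full_window_counts(self, setup):
        g, s, e, cand, idx, policy = setup
        read = g.sequence[s - 44:s] + g.sequence[e:e + 6]  # exactly E past bp
        res = self._count(g, cand, idx, policy, [("r1", read)])
        assert res.n_V == 1

    def test_read_stopping_at_E_minus_1_not_counted(self, setup):
        g, s, e, cand, idx, policy = setup
        read = g.sequence[s - 45:s] + g.sequence[e:e + 5]  # E-1 = 5 past bp
        res = self._count(g, cand, idx, policy, [("r1", read)])
        assert res.n_V == 0

    def test_mismatch_inside_extension_window_not_counted(self, setup):
        g, s, e, cand, idx, policy = setup
        right = list(g.sequence[e:e + 6])
        right[3] = {"A": "C", "C": "G", "G": "T", "T": "A"}[right[3]]
        read = g.sequence[s - 44:s] + "".join(right)
        res = self._count(g, cand, idx, policy, [("r1", read)])
        assert res.n_V == 0

    def test_reference_reads_count_for_reference_sides(self, setup):
        g, s, e, cand, idx, policy = setup
        reads = [("a", g.sequence[s - 25:s + 25]),   # spans side-1 context
                 ("b", g.sequence[e - 25:e + 25])]   # spans side-2 context
        res = self._count(g, cand, idx, policy, reads)
        assert res.n_V == 0
        assert res.n_R == [1, 1]


class TestAcceptanceThreshold:
    def test_n_min_boundary(self):
        policy = SpanningPolicy()
        mk = lambda n: __import__("svjc.junctions", fromlist=["JunctionCounts"]
                                  ).JunctionCounts(
            candidate=CandidateJunction(JunctionSide(10, -1),
                                        JunctionSide(20, +1)), n_V=n)
        two, three = mk(2), mk(3)
        out = call_polymorphic_junctions([two, three], policy)
        assert not out[0].accepted and "below threshold" in out[0].reject_reason
        assert out[1].accepted


class TestTilingInvariants:
    def test_spanning_counts_match_target_size(self, ref50k, planted50k,
                                               tiling_call):
        vg, variants = planted50k
        truth = truth_keys(vg)
        accepted = {e.junction.key(): e for e in tiling_call.accepted}
        assert set(accepted) == truth  # all found, nothing else
        for e in accepted.values():
            target = 50 - (12 + e.A) + 1
            assert e.n_V == 2 * target          # one per admissible start/strand
            assert e.n_R == [2 * target] * 2
            assert e.F_V == 0.5

    def test_reference_only_reads_give_no_junctions(self):
        g = random_genome(100_000, seed=75)
        reads = tiling_reads(g, 50)
        res = call_junctions(reads, g)
        assert res.accepted == []


class TestPrecisionOnSampledReads:
    @pytest.mark.parametrize("errors,label", [(ERROR_FREE, "error-free"),
                                              (DEFAULT_ILLUMINA, "illumina")])
    def test_no_junctions_from_pure_reference_sample(self, errors, label):
        g = random_genome(200_000, seed=76)
        reads = sample_reads(g, CoverageSpec(100.0, 50), errors, seed=77)
        res = call_junctions(reads, g)
        assert res.accepted == []


@pytest.fixture(scope="module")
def is_genome():
    """Reference with one annotated IS-like element copy."""
    rng = np.random.default_rng(78)
    from svjc._seq import random_sequence
    base = random_sequence(30_000, rng)
    element = random_sequence(800, rng)
    seq = base[:5000] + element + base[5000:]
    g = Genome("ref", seq, "circular")
    ann = MobileElementAnnotation("IS150", ((5000, 5800, "+"),))
    return g, element, ann


class TestMobileElementScenarios:
    def test_new_insertion_with_target_site_duplication(self, is_genome):
        g, element, ann = is_genome
        # insert a new element copy at 20_000 with a 5-bp target duplication
        payload = element + g.sequence[20_000:20_005]
        vg = apply_variants(g, [StructuralVariant(
            "is_insertion", 20_005, len(payload), payload=payload,
            element_family="IS150")])
        mix = mix_samples(tiling_reads(vg, 50, src="var"),
                          tiling_reads(g, 50, src="ref"))
        res = call_junctions(mix, g, annotations=[ann])
        mobs = [p for p in res.predictions
                if p.kind == "mobile_element_insertion"]
        assert len(mobs) == 1
        mob = mobs[0]
        assert mob.element_family == "IS150"
        assert mob.target_site_duplication == 5
        assert mob.interval[0] >= 19_995 and mob.interval[1] <= 20_010
        assert mob.frequency == pytest.approx(0.5, abs=1e-9)

    def test_is_mediated_deletion_is_singleton_indeterminate(self, is_genome):
        g, element, ann = is_genome
        # deletion extending from the element's right end into the flank
        vg = apply_variants(g, [StructuralVariant("deletion", 5800, 1000)])
        mix = mix_samples(tiling_reads(vg, 50, src="var"),
                          tiling_reads(g, 50, src="ref"))
        res = call_junctions(mix, g, annotations=[ann])
        kinds = {p.kind for p in res.predictions}
        assert "is_insertion_or_deletion" in kinds
        p = next(p for p in res.predictions
                 if p.kind == "is_insertion_or_deletion")
        # frequency estimated from the genomic side alone (N_R = 1)
        assert p.frequency == pytest.approx(0.5, abs=1e-9)
        assert p.evidence[0].N_R == 1

    def test_deletion_prone_anchor_promotes_to_deletion(self, is_genome):
        g, element, ann = is_genome
        vg = apply_variants(g, [StructuralVariant("deletion", 5800, 1000)])
        mix = mix_samples(tiling_reads(vg, 50, src="var"),
                          tiling_reads(g, 50, src="ref"))
        res = call_junctions(
            mix, g, annotations=[ann],
            config=RunConfig(deletion_prone_anchors=(5799,)))
        assert any(p.kind == "deletion" and
                   p.notes == "promoted via deletion-prone anchor"
                   for p in res.predictions)
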
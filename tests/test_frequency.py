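"""Frequency estimation (normalized counts, junction frequency), SV
classification, mobile-element pairing, nested corrections, artifacts."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import truth_keys
from svjc.frequency import (JunctionEvidence, SVPrediction, artifact_filters,
                            classify_junction, junction_frequency,
                            missing_coverage_intervals,
                            nested_deletion_correction, normalized_count,
                            pair_mobile_element_junctions)
from svjc.genome import MobileElementAnnotation, random_genome
from svjc.junctions import CandidateJunction, JunctionSide
from svjc.pipeline import call_junctions
from svjc.simulate import mix_samples, tiling_reads


def _evidence(p1, d1, p2, d2, n_V=10, n_R=(10, 10), L_bar=50.0, E=6, A=0,
              rep1=False, rep2=False, status="accepted"):
    cand = CandidateJunction(JunctionSide(p1, d1, in_repeat=rep1),
                             JunctionSide(p2, d2, in_repeat=rep2), A=A)
    ev = JunctionEvidence(junction=cand, n_V=n_V, n_R=list(n_R),
                          L_bar=L_bar, E=E, A=A, status=status)
    ev.f_V = normalized_count(n_V, L_bar, E, A)
    ev.f_R = [normalized_count(n, L_bar, E, A) for n in n_R]
    ev.F_V = junction_frequency([ev.f_V], ev.f_R)
    return ev


class TestNormalizedCount:
    def test_count_equal_to_target_size_gives_one(self):
        assert normalized_count(69, 80, 6, 0) == pytest.approx(1.0)

    def test_zero_count_gives_zero(self):
        assert normalized_count(0, 80, 6, 0) == 0.0

    def test_direct_substitution_with_ambiguity(self):
        assert normalized_count(30, 80, 6, 3) == pytest.approx(30 / 66)

    def test_unevaluable_read_length_raises(self):
        with pytest.raises(ValueError, match="unevaluable"):
            normalized_count(5, 12, 6, 0)
        with pytest.raises(ValueError):
            normalized_count(5, 20, 6, 9)


class TestJunctionFrequency:
    def test_equal_representation_gives_half(self):
        assert junction_frequency([2.0], [2.0, 2.0]) == pytest.approx(0.5)

    def test_one_repeat_side_omitted(self):
        assert junction_frequency([3.0], [1.0]) == pytest.approx(0.75)

    def test_no_reference_support_gives_one(self):
        assert junction_frequency([1.5], [0.0, 0.0]) == pytest.approx(1.0)

    def test_nothing_observed_is_undefined(self):
        assert junction_frequency([0.0], [0.0]) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(fv=st.floats(0.001, 100), f1=st.floats(0, 100), f2=st.floats(0, 100))
    def test_frequency_always_in_unit_interval(self, fv, f1, f2):
        F = junction_frequency([fv], [f1, f2])
        assert 0.0 <= F <= 1.0


class TestTilingMixtureRatios:
    @pytest.mark.parametrize("ref_copies,expected", [(3, 0.25), (9, 0.10)])
    def test_deterministic_mixtures_hit_exact_frequencies(
            self, ref_copies, expected, ref50k, planted50k):
        """1 variant tiling copy : N reference copies makes every junction
        frequency exact by construction."""
        vg, _ = planted50k
        pools = [tiling_reads(vg, 50, src="var")]
        base = tiling_reads(ref50k, 50, src="ref")
        pools += [base.relabeled(f"ref{i}") for i in range(ref_copies)]
        mix = mix_samples(*pools)
        res = call_junctions(mix, ref50k)
        accepted = {e.junction.key(): e for e in res.accepted}
        assert set(accepted) == truth_keys(vg)
        for e in accepted.values():
            assert e.F_V == pytest.approx(expected, abs=1e-12)


class TestClassification:
    def test_small_deletion_below_read_length(self):
        ev = _evidence(999, -1, 1040, +1)  # removes 40 bases
        p = classify_junction(ev, L_bar=80.0)
        assert p.kind == "small_indel"
        assert "deletion of 40 bp" in p.notes
        assert p.interval == (1001, 1040)

    def test_large_deletion_without_mc_is_unassigned(self):
        ev = _evidence(999, -1, 1183, +1)
        p = classify_junction(ev, L_bar=80.0)
        assert p.kind == "unassigned"

    def test_large_deletion_with_missing_coverage_is_consensus(self):
        ev = _evidence(999, -1, 2000, +1)
        p = classify_junction(ev, L_bar=80.0, mc_intervals=[(1000, 2000)])
        assert p.kind == "deletion"
        assert p.consensus and p.frequency == 1.0

    def test_singleton_is_boundary_junction_is_indeterminate(self):
        ann = MobileElementAnnotation("IS150", ((5000, 6400, "+"),))
        ev = _evidence(5000, +1, 9000, -1, rep1=True)
        p = classify_junction(ev, L_bar=80.0, annotations=[ann])
        assert p.kind == "is_insertion_or_deletion"
        assert p.element_family == "IS150"
        assert p.frequency == ev.F_V


class TestMobileElementPairing:
    ann = MobileElementAnnotation("IS150", ((5000, 6400, "+"),))

    def _pair(self, g1_pos, g2_pos, elem1=("start",), elem2=("end",),
              family2="IS150"):
        # junction 1: genomic side (d=-1) + element start side
        e1 = _evidence(5000, +1, g1_pos, -1, rep1=True)
        ann2 = MobileElementAnnotation(family2, ((5000, 6400, "+"),)) \
            if family2 != "IS150" else self.ann
        if elem2 == ("end",):
            e2 = _evidence(6399, -1, g2_pos, +1, rep1=True)
        else:  # same end as junction 1
            e2 = _evidence(5000, +1, g2_pos, +1, rep1=True)
        preds, used = pair_mobile_element_junctions([e1, e2], [self.ann])
        return preds

    def test_sides_five_apart_pair_into_insertion(self):
        preds = self._pair(10_004, 10_000)
        assert len(preds) == 1
        p = preds[0]
        assert p.kind == "mobile_element_insertion"
        assert p.target_site_duplication == 5
        assert p.frequency == pytest.approx(0.5)

    def test_sides_eleven_apart_not_paired(self):
        assert self._pair(10_011, 10_000) == []

    def test_same_element_end_not_paired(self):
        assert self._pair(10_004, 10_000, elem2=("start",)) == []

    def test_pooled_frequency_equals_unpooled_for_identical_counts(self):
        e1 = _evidence(5000, +1, 10_004, -1, rep1=True)
        e2 = _evidence(6399, -1, 10_000, +1, rep1=True)
        preds, _ = pair_mobile_element_junctions([e1, e2], [self.ann])
        assert preds[0].frequency == pytest.approx(e1.F_V)


class TestNestedDeletionCorrection:
    def _del(self, lo, hi, freq):
        return SVPrediction(kind="deletion", interval=(lo, hi),
                            frequency=freq)

    def test_inner_down_weighted_by_outer(self):
        outer = self._del(100, 2000, 0.4)
        inner = self._del(100, 800, 0.5)
        nested_deletion_correction([outer, inner])
        assert inner.frequency == pytest.approx(0.3)
        assert outer.frequency == pytest.approx(0.4)

    def test_without_containing_deletion_unchanged(self):
        a = self._del(100, 800, 0.5)
        b = self._del(5000, 6000, 0.2)
        nested_deletion_correction([a, b])
        assert a.frequency == 0.5 and b.frequency == 0.2

    def test_containing_sum_of_one_zeroes_inner(self):
        outer1 = self._del(100, 3000, 0.6)
        outer2 = self._del(100, 2000, 0.4)
        inner = self._del(100, 800, 0.5)
        nested_deletion_correction([outer1, outer2, inner])
        assert inner.frequency == pytest.approx(0.5 * (1 - 1.0))

    def test_overfull_containing_sum_clamps_and_warns(self):
        outer1 = self._del(100, 3000, 0.7)
        outer2 = self._del(100, 2000, 0.6)
        inner = self._del(100, 800, 0.5)
        with pytest.warns(UserWarning, match="clamping"):
            nested_deletion_correction([outer1, outer2, inner])
        assert inner.frequency == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(freqs=st.lists(st.floats(0.01, 0.3), min_size=2, max_size=5))
    def test_anchored_family_total_stays_bounded(self, freqs):
        """Mutually exclusive anchored deletions keep a coherent total."""
        preds = [self._del(100, 500 + 300 * i, f)
                 for i, f in enumerate(sorted(freqs))]
        nested_deletion_correction(preds)
        assert all(p.frequency >= 0 for p in preds)
        assert sum(p.frequency for p in preds) <= sum(freqs) + 1e-9


class TestArtifactFilters:
    def test_both_repeat_sides_flagged_unestimable(self):
        ev = _evidence(5000, +1, 9000, -1, rep1=True, rep2=True)
        artifact_filters([ev])
        assert ev.status == "unestimable"

    def test_outward_pair_at_fragment_size_flagged(self):
        ev = _evidence(1000, +1, 1199, -1)  # outward, 200 bp apart
        artifact_filters([ev], fragment_size=260, L_bar=80.0)
        assert ev.status == "artifact"
        assert "chimera" in ev.reject_reason

    def test_canonical_deletion_junction_unflagged(self):
        ev = _evidence(1000, -1, 2000, +1)
        artifact_filters([ev], fragment_size=260, L_bar=80.0)
        assert ev.status == "accepted"


def test_missing_coverage_interval_extraction():
    cov = np.ones(1000, dtype=int)
    cov[100:200] = 0   # long gap
    cov[500:520] = 0   # below the 50-bp threshold
    assert missing_coverage_intervals(cov, 50) == [(100, 200)]
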
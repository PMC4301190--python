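"""Junction frequency estimation and structural-variant classification.

The frequency of a new junction in a pooled population sample is estimated
by comparing spanning-read counts for the variant junction against the
counts spanning each reference location it joins, after normalizing every
count by its target size — the number of start positions from which a read
of the average input length L̄ can qualify as spanning:

    f = n / (L̄ − (2E + A) + 1)                                (per count)
    F_V = mean(f_V) / (mean(f_R) + mean(f_V))                 (per junction)

A side that falls in a repeat (e.g. an IS element) is uninformative for the
frequency and is omitted from the reference mean (N_R drops from 2 to 1);
when both sides are repeats no frequency can be estimated. New mobile
element insertions are predicted from *pairs* of junctions whose genomic
sides meet within 10 bases in the proper orientation and whose other sides
hit opposite boundaries of the same element family; their counts are pooled
(N_V = 2, N_R = 2). Nested deletions sharing an anchored endpoint have their
inner raw frequencies multiplied by one minus the summed frequencies of all
containing deletions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import MobileElementAnnotation
from .junctions import (CandidateJunction, JunctionCounts, JunctionSide,
                        SpanningPolicy)

__all__ = [
    "JunctionEvidence",
    "SVPrediction",
    "normalized_count",
    "junction_frequency",
    "build_evidence",
    "artifact_filters",
    "pair_mobile_element_junctions",
    "classify_junction",
    "nested_deletion_correction",
    "missing_coverage_intervals",
    "predict_svs",
]


def normalized_count(n: float, L_bar: float, E: int, A: int) -> float:
    """Eq.-style normalized spanning count: n / (L̄ − (2E + A) + 1)."""
    target = L_bar - (2 * E + A) + 1
    if L_bar <= 2 * E + A:
        raise ValueError(
            f"junction unevaluable: mean read length {L_bar} <= 2E+A = "
            f"{2 * E + A}")
    return n / target


def junction_frequency(f_V: Sequence[float],
                       f_R: Sequence[float]) -> Optional[float]:
    """Frequency of the variant junction among the genomes in the sample.

    ``f_R`` holds one normalized count per informative reference location
    (0, 1 or 2 of them); returns None when nothing was observed at all.
    """
    if len(f_V) == 0:
        raise ValueError("at least one variant junction count is required")
    mv = float(np.mean(f_V))
    mr = float(np.mean(f_R)) if len(f_R) else 0.0
    if mv + mr == 0:
        return None
    return mv / (mr + mv)


@dataclass
class JunctionEvidence:
    """One junction's counts, normalized counts and estimated frequency."""

    junction: CandidateJunction
    n_V: int
    n_R: list[int]
    L_bar: float
    E: int
    A: int
    f_V: float = 0.0
    f_R: list[float] = field(default_factory=list)
    F_V: Optional[float] = None
    status: str = "rejected"  # accepted | rejected | artifact | unestimable
    reject_reason: str = ""

    @property
    def N_R(self) -> int:
        return len(self.f_R)

    @property
    def sides(self) -> tuple[JunctionSide, JunctionSide]:
        return (self.junction.side_1, self.junction.side_2)


def build_evidence(counts: JunctionCounts, L_bar: float,
                   policy: SpanningPolicy) -> JunctionEvidence:
    c = counts.candidate
    ev = JunctionEvidence(junction=c, n_V=counts.n_V, n_R=list(counts.n_R),
                          L_bar=L_bar, E=policy.E, A=c.A)
    try:
        ev.f_V = normalized_count(counts.n_V, L_bar, policy.E, c.A)
        ev.f_R = [normalized_count(n, L_bar, policy.E, c.A)
                  for n in counts.n_R]
    except ValueError as exc:
        ev.status = "unestimable"
        ev.reject_reason = str(exc)
        return ev
    if c.side_1.in_repeat and c.side_2.in_repeat:
        ev.status = "unestimable"
        ev.reject_reason = "both sides in repeat regions"
    else:
        ev.F_V = junction_frequency([ev.f_V], ev.f_R)
        if ev.F_V is None:
            ev.status = "rejected"
            ev.reject_reason = "no spanning reads for either alternative"
        else:
            ev.status = "accepted" if counts.accepted else "rejected"
            ev.reject_reason = counts.reject_reason
    return ev


# ---------------------------------------------------------------------------
# Artifact filters
# ---------------------------------------------------------------------------

def artifact_filters(evidence: list[JunctionEvidence],
                     fragment_size: int = 260,
                     L_bar: Optional[float] = None) -> list[JunctionEvidence]:
    """Flag junctions that cannot be genuine mutations.

    Both-sides-in-repeat junctions (e.g. an IS inserted into another IS)
    are unestimable; outward-oriented same-locus junctions at roughly the
    sequenced fragment size are flagged as library-preparation chimera
    suspects. Nothing is dropped — flags only.
    """
    for ev in evidence:
        s1, s2 = ev.sides
        if s1.in_repeat and s2.in_repeat:
            ev.status = "unestimable"
            ev.reject_reason = "both sides in repeat regions"
            continue
        if ev.status not in ("accepted",):
            continue
        if (not s1.in_repeat and not s2.in_repeat
                and s1.continuation == +1 and s2.continuation == -1):
            span = s2.ref_position - s1.ref_position + 1
            lbar = L_bar if L_bar is not None else ev.L_bar
            if lbar <= span <= fragment_size:
                ev.status = "artifact"
                ev.reject_reason = (
                    "outward-oriented same-locus junction at fragment-size "
                    "distance (library chimera suspect)")
    return evidence


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class SVPrediction:
    kind: str  # mobile_element_insertion | deletion | small_indel |
    #            is_insertion_or_deletion | unassigned
    interval: tuple[int, int]  # 1-based inclusive reference span
    frequency: Optional[float]
    evidence: list[JunctionEvidence] = field(default_factory=list)
    element_family: str = ""
    consensus: bool = False
    target_site_duplication: int = 0
    notes: str = ""


def _element_boundary(side: JunctionSide,
                      annotations: Sequence[MobileElementAnnotation],
                      tol: int = 5) -> Optional[tuple[str, str]]:
    """(family, 'start'|'end') if the side sits at an element boundary."""
    for ann in annotations:
        for (s, e, strand) in ann.copies:
            if abs(side.ref_position - s) <= tol and side.continuation == +1:
                return (ann.family, "start")
            if abs(side.ref_position - (e - 1)) <= tol \
                    and side.continuation == -1:
                return (ann.family, "end")
    return None


def pair_mobile_element_junctions(
        evidence: list[JunctionEvidence],
        annotations: Sequence[MobileElementAnnotation],
        max_distance: int = 10) -> tuple[list[SVPrediction],
                                         set[int]]:
    """Merge qualifying junction pairs into mobile-element insertions.

    Each junction must have one genomic side and one side at an element
    boundary; the two genomic sides must lie within ``max_distance`` bases
    in the proper orientation (flanks pointing away from each other, possibly
    overlapping by the target-site duplication) and the element sides must
    hit opposite boundaries of the same family. Counts are pooled so that
    N_V = 2 and N_R = 2 in the frequency estimate.
    """
    items = []  # (index, genomic side, element family, boundary)
    for i, ev in enumerate(evidence):
        if ev.status != "accepted":
            continue
        s1, s2 = ev.sides
        flags = (s1.in_repeat, s2.in_repeat)
        if flags == (True, False):
            elem, gen = s1, s2
        elif flags == (False, True):
            elem, gen = s2, s1
        else:
            continue
        hit = _element_boundary(elem, annotations)
        if hit is None:
            continue
        items.append((i, gen, hit[0], hit[1]))

    predictions = []
    used: set[int] = set()
    for a in range(len(items)):
        i, gen_i, fam_i, b_i = items[a]
        if i in used:
            continue
        for b in range(a + 1, len(items)):
            j, gen_j, fam_j, b_j = items[b]
            if j in used or fam_i != fam_j or b_i == b_j:
                continue
            if gen_i.continuation == gen_j.continuation:
                continue
            minus = gen_i if gen_i.continuation == -1 else gen_j
            plus = gen_j if gen_i.continuation == -1 else gen_i
            if abs(minus.ref_position - plus.ref_position) > max_distance:
                continue
            ev_i, ev_j = evidence[i], evidence[j]
            freq = junction_frequency([ev_i.f_V, ev_j.f_V],
                                      ev_i.f_R + ev_j.f_R)
            tsd = max(0, minus.ref_position - plus.ref_position + 1)
            lo = min(plus.ref_position, minus.ref_position)
            hi = max(plus.ref_position, minus.ref_position)
            predictions.append(SVPrediction(
                kind="mobile_element_insertion",
                interval=(lo + 1, hi + 1), frequency=freq,
                evidence=[ev_i, ev_j], element_family=fam_i,
                target_site_duplication=tsd))
            used.update((i, j))
            break
    return predictions, used


def missing_coverage_intervals(coverage: np.ndarray,
                               min_length: int = 50) -> list[tuple[int, int]]:
    """Maximal zero-coverage intervals of at least ``min_length`` bases."""
    zero = coverage == 0
    if not zero.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], zero.view(np.int8),
                                                   [0]])))
    out = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo >= min_length:
            out.append((int(lo), int(hi)))
    return out


def classify_junction(ev: JunctionEvidence, L_bar: float,
                      annotations: Sequence[MobileElementAnnotation] = (),
                      mc_intervals: Sequence[tuple[int, int]] = (),
                      deletion_prone_anchors: Sequence[int] = (),
                      anchor_tol: int = 5) -> SVPrediction:
    """Assign one junction to a mutation type.

    Junctions only predict mutations conservatively: small indels spanning
    less than the average read length, consensus deletions whose span lacks
    read coverage entirely, and indeterminate single IS-boundary junctions
    (IS insertion or IS-mediated deletion). Everything else is reported
    unassigned for manual evaluation.
    """
    s1, s2 = ev.sides
    if s1.in_repeat and s2.in_repeat:
        return SVPrediction(kind="unassigned",
                            interval=(s1.ref_position + 1,
                                      s2.ref_position + 1),
                            frequency=None, evidence=[ev],
                            notes="both sides in repeats")
    if s1.in_repeat or s2.in_repeat:
        elem = s1 if s1.in_repeat else s2
        gen = s2 if s1.in_repeat else s1
        hit = _element_boundary(elem, annotations)
        family = hit[0] if hit else ""
        boundary_pos = elem.ref_position
        for anchor in deletion_prone_anchors:
            if abs(boundary_pos - anchor) <= anchor_tol:
                lo, hi = sorted((gen.ref_position, boundary_pos))
                return SVPrediction(
                    kind="deletion", interval=(lo + 1, hi + 1),
                    frequency=ev.F_V, evidence=[ev], element_family=family,
                    notes="promoted via deletion-prone anchor")
        return SVPrediction(
            kind="is_insertion_or_deletion",
            interval=(gen.ref_position + 1, gen.ref_position + 1),
            frequency=ev.F_V, evidence=[ev], element_family=family)

    d = (s1.continuation, s2.continuation)
    if d == (-1, +1):
        span = s2.ref_position - s1.ref_position - 1
        if 0 < span < L_bar:
            return SVPrediction(kind="small_indel",
                                interval=(s1.ref_position + 2,
                                          s2.ref_position),
                                frequency=ev.F_V, evidence=[ev],
                                notes=f"deletion of {span} bp")
        for lo, hi in mc_intervals:
            if (s1.ref_position < lo and hi <= s2.ref_position
                    and (hi - lo) >= 0.5 * span):
                return SVPrediction(kind="deletion",
                                    interval=(s1.ref_position + 2,
                                              s2.ref_position),
                                    frequency=1.0, evidence=[ev],
                                    consensus=True,
                                    notes="supported by missing coverage")
        return SVPrediction(kind="unassigned",
                            interval=(s1.ref_position + 1,
                                      s2.ref_position + 1),
                            frequency=ev.F_V, evidence=[ev])
    if d == (+1, -1):
        span = s2.ref_position - s1.ref_position + 1
        if span < L_bar:
            return SVPrediction(kind="small_indel",
                                interval=(s1.ref_position + 1,
                                          s2.ref_position + 1),
                                frequency=ev.F_V, evidence=[ev],
                                notes=f"duplication/insertion of {span} bp")
    return SVPrediction(kind="unassigned",
                        interval=(min(s1.ref_position, s2.ref_position) + 1,
                                  max(s1.ref_position, s2.ref_position) + 1),
                        frequency=ev.F_V, evidence=[ev])


def nested_deletion_correction(predictions: list[SVPrediction],
                               anchor_tol: int = 5) -> list[SVPrediction]:
    """Down-weight nested deletions sharing an anchored endpoint.

    When deletions extend from the same anchor (e.g. one end of an IS
    element) to different distances, the inner deletion only exists within
    the subpopulation lacking every containing deletion, so its raw
    frequency is multiplied by one minus the summed frequencies of all
    deletions that completely contain it.
    """
    dels = [p for p in predictions
            if p.kind in ("deletion", "small_indel", "is_insertion_or_deletion")
            and p.frequency is not None]
    raw = {id(p): p.frequency for p in dels}
    for p in dels:
        containing = []
        for q in dels:
            if q is p:
                continue
            share_anchor = (abs(q.interval[0] - p.interval[0]) <= anchor_tol
                            or abs(q.interval[1] - p.interval[1]) <= anchor_tol)
            contains = (q.interval[0] <= p.interval[0]
                        and q.interval[1] >= p.interval[1]
                        and q.interval != p.interval)
            if share_anchor and contains:
                containing.append(q)
        if containing:
            total = sum(raw[id(q)] for q in containing)
            if total > 1:
                warnings.warn("containing-deletion frequencies sum above 1; "
                              "clamping inner frequency to 0")
                total = 1.0
            p.frequency = raw[id(p)] * (1.0 - total)
    return predictions


def predict_svs(evidence: list[JunctionEvidence], L_bar: float,
                annotations: Sequence[MobileElementAnnotation] = (),
                mc_intervals: Sequence[tuple[int, int]] = (),
                deletion_prone_anchors: Sequence[int] = (),
                fragment_size: int = 260) -> list[SVPrediction]:
    """Full classification pass over accepted junction evidence."""
    artifact_filters(evidence, fragment_size=fragment_size, L_bar=L_bar)
    me_preds, used = pair_mobile_element_junctions(evidence, annotations)
    predictions = list(me_preds)
    for i, ev in enumerate(evidence):
        if i in used or ev.status != "accepted":
            continue
        predictions.append(classify_junction(
            ev, L_bar, annotations, mc_intervals, deletion_prone_anchors))
    return nested_deletion_correction(predictions)
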
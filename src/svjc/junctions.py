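"""Candidate junction detection and spanning-read counting.

A structural mutation joins two reference locations that are disjoint in the
reference genome. Reads crossing the new breakpoint produce split-read
alignments: two partial alignments, disjoint on the reference, that jointly
cover the read. Candidates are seeded from at least ``seed_min`` (default 2)
such reads, merged under a canonical breakpoint placement, and then all
reads that could not be fully explained by the reference are re-mapped
against the reconstructed junction sequences to count spanning reads.

A spanning read must cross the breakpoint past all ambiguous bases (``A``,
the micro-homology shared by the two reference contexts, within which reads
match reference and junction equally well) and continue to match perfectly
for ``E`` further bases on each side; it must also align better to the
junction than anywhere in the reference (ties go to the reference).
Reference-location spanning reads are counted with the same window rule at
each side's original context, making the frequency estimate symmetric.

Sides are ``(position, continuation)`` pairs: ``position`` is the last
reference base retained before the breakpoint and ``continuation`` is -1
when the reference context extends toward lower coordinates and +1 toward
higher. A junction is an unordered pair of sides; the canonical form orders
them by (position, continuation) and places the breakpoint leftmost within
the homology window.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import encode, revcomp
from .genome import Genome
from .mapping import (AlignmentTable, KmerIndex, MappingPolicy,
                      map_reads_batch)
from .simulate import ReadSet

__all__ = [
    "JunctionSide",
    "CandidateJunction",
    "SpanningPolicy",
    "JunctionCounts",
    "seed_candidates",
    "reconstruct_junction_sequence",
    "compute_ambiguity",
    "count_spanning_reads",
    "call_polymorphic_junctions",
]


@dataclass(frozen=True)
class JunctionSide:
    ref_position: int
    continuation: int  # -1 toward lower coordinates, +1 toward higher
    in_repeat: bool = False

    def key(self) -> tuple[int, int]:
        return (self.ref_position, self.continuation)


@dataclass(frozen=True)
class SpanningPolicy:
    """Spanning-read and seeding thresholds (defaults are the algorithm's)."""

    E: int = 6               # perfect extension bases past the ambiguity
    n_min: int = 3           # minimum spanning reads to accept a junction
    seed_min: int = 2        # minimum split reads to form a candidate
    max_overlap: int = 12    # max read-interval overlap of a split pair
    end_slack: int = 4       # unaligned bases tolerated at read ends
    min_indel_span: int = 2  # junctions predict indels of >= this many bases;
    #                          smaller apparent deletions are alignment gaps
    #                          (e.g. single-base sequencing errors), not SV
    max_candidates: int = 5000

    def __post_init__(self):
        if self.E < 1 or self.n_min < 1 or self.seed_min < 2:
            raise ValueError("invalid spanning policy")


@dataclass
class CandidateJunction:
    side_1: JunctionSide
    side_2: JunctionSide
    junction_sequence: str = ""
    breakpoint_index: int = 0  # index in junction_sequence of side_2's first base
    A: int = 0
    homology_forward: int = 0   # ambiguous bases at/after the breakpoint
    homology_backward: int = 0  # ambiguous bases before the breakpoint
    supporting_split_reads: int = 0
    truncated_flank: bool = False

    def key(self) -> tuple[int, int, int, int]:
        return self.side_1.key() + self.side_2.key()


@dataclass
class JunctionCounts:
    """Spanning-read counts for one candidate junction."""

    candidate: CandidateJunction
    n_V: int = 0
    n_R: list[int] = field(default_factory=list)  # per informative ref side
    sides_counted: list[int] = field(default_factory=list)  # 1-based side ids
    accepted: bool = False
    reject_reason: str = ""


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _canonical_pair(s1: JunctionSide, s2: JunctionSide
                    ) -> tuple[JunctionSide, JunctionSide]:
    return (s1, s2) if s1.key() <= s2.key() else (s2, s1)


def canonicalize_sides(genome: Genome, p1: int, d1: int, p2: int, d2: int,
                       max_scan: int = 100) -> tuple[int, int, int, int]:
    """Slide the breakpoint leftmost within its micro-homology window.

    Reads sampled from the two strands place the breakpoint at opposite
    ends of the homology window; sliding to the canonical (leftmost, in the
    ordered junction's reading direction) placement makes all reads of one
    junction merge to a single key.
    """
    seq = genome.sequence
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    if (p1, d1) > (p2, d2):
        (p1, d1), (p2, d2) = (p2, d2), (p1, d1)
    for _ in range(max_scan):
        # last base contributed by the left flank, in junction orientation
        i1 = p1 % n if genome.is_circular else p1
        if not (0 <= i1 < n):
            break
        left_last = seq[i1] if d1 == -1 else comp[seq[i1]]
        # base that precedes side_2's first base in its reference context
        j = (p2 - d2) % n if genome.is_circular else p2 - d2
        if not (0 <= j < n):
            break
        pre2 = seq[j] if d2 == +1 else comp[seq[j]]
        if left_last != pre2:
            break
        p1 += d1
        p2 -= d2
    if (p1, d1) > (p2, d2):
        (p1, d1), (p2, d2) = (p2, d2), (p1, d1)
    return p1, d1, p2, d2


def _side_from_prefix(strand, read_start, read_end, ref_start, ref_end,
                      t) -> tuple[int, int]:
    """Side left behind by the alignment covering the read before offset t."""
    if strand == 0:
        return (ref_start + (t - 1 - read_start), -1)
    return (ref_start + (read_end - t), +1)


def _side_from_suffix(strand, read_start, read_end, ref_start, ref_end,
                      t) -> tuple[int, int]:
    """Side entered by the alignment covering the read from offset t on."""
    if strand == 0:
        return (ref_start + (t - read_start), +1)
    return (ref_start + (read_end - 1 - t), -1)


def seed_candidates(table: AlignmentTable, reads: ReadSet,
                    policy: SpanningPolicy = SpanningPolicy(),
                    genome: Optional[Genome] = None
                    ) -> list[CandidateJunction]:
    """Build merged candidate junctions from split-read alignment pairs.

    A read seeds a junction when two of its alignments cover disjoint parts
    of the read (overlap at most ``max_overlap`` for breakpoint homology,
    no gap), jointly reach both read ends (within ``end_slack``), and the
    read has no perfect full-length reference placement. Candidates carry
    the number of distinct supporting reads; identical junctions merge under
    the canonical ordering.
    """
    if len(table) == 0:
        return []
    counts = np.bincount(table.read, minlength=len(reads))
    multi = np.nonzero(counts >= 2)[0]
    if len(multi) == 0:
        return []
    order = np.argsort(table.read, kind="stable")
    sorted_read = table.read[order]
    starts = np.searchsorted(sorted_read, multi, "left")
    ends = np.searchsorted(sorted_read, multi, "right")

    support: dict[tuple, set[int]] = {}
    canon_cache: dict[tuple, tuple] = {}
    n = len(genome) if genome is not None else None
    for ridx, lo, hi in zip(multi, starts, ends):
        rows = order[lo:hi]
        ell = int(reads.lengths[ridx])
        # skip reads fully explained by the reference
        if any(table.mismatches[r] == 0 and table.read_start[r] == 0
               and table.read_end[r] == ell for r in rows):
            continue
        alns = sorted(
            ((int(table.read_start[r]), int(table.read_end[r]),
              int(table.strand[r]), int(table.ref_start[r]),
              int(table.ref_end[r])) for r in rows))
        for i in range(len(alns)):
            for j in range(len(alns)):
                if i == j:
                    continue
                rs1, re1, st1, gs1, ge1 = alns[i]
                rs2, re2, st2, gs2, ge2 = alns[j]
                if rs1 > rs2 or (rs1 == rs2 and re1 >= re2):
                    continue
                overlap = re1 - rs2
                if overlap < 0 or overlap > policy.max_overlap:
                    continue
                if rs1 > policy.end_slack or re2 < ell - policy.end_slack:
                    continue
                if st1 == st2 and max(gs1, gs2) < min(ge1, ge2):
                    continue  # same reference bases twice: not a junction
                t = rs2
                p1, d1 = _side_from_prefix(st1, rs1, re1, gs1, ge1, t)
                p2, d2 = _side_from_suffix(st2, rs2, re2, gs2, ge2, t)
                if n is not None:
                    p1 %= n
                    p2 %= n
                    raw = (p1, d1, p2, d2)
                    if raw not in canon_cache:
                        canon_cache[raw] = canonicalize_sides(
                            genome, p1, d1, p2, d2)
                    key = canon_cache[raw]
                else:
                    s1, s2 = _canonical_pair(JunctionSide(p1, d1),
                                             JunctionSide(p2, d2))
                    key = s1.key() + s2.key()
                kp1, kd1, kp2, kd2 = key
                if (kd1, kd2) == (-1, +1) and \
                        kp2 - kp1 - 1 < policy.min_indel_span:
                    continue  # sub-threshold deletion: a gap, not a junction
                support.setdefault(key, set()).add(int(ridx))

    cands = []
    for (p1, d1, p2, d2), readset in support.items():
        if len(readset) < policy.seed_min:
            continue
        cands.append(CandidateJunction(
            side_1=JunctionSide(p1, d1), side_2=JunctionSide(p2, d2),
            supporting_split_reads=len(readset)))
    cands.sort(key=lambda c: (-c.supporting_split_reads, c.key()))
    if len(cands) > policy.max_candidates:
        cands = cands[:policy.max_candidates]
    return cands


# ---------------------------------------------------------------------------
# Junction sequence reconstruction and ambiguity
# ---------------------------------------------------------------------------

def _fetch_oriented(genome: Genome, pos: int, length: int,
                    direction: int, leaving: bool) -> tuple[str, bool]:
    """Reference sequence next to a side.

    ``leaving=False``: the ``length`` bases approaching the breakpoint and
    ending at ``pos`` (read left-to-right toward the junction).
    ``leaving=True``: the ``length`` bases past the breakpoint starting at
    ``pos`` (the side used as the right half of the junction).
    Returns (sequence, truncated_flag).
    """
    n = len(genome)
    if direction == -1:
        lo, hi = pos - length + 1, pos + 1
        seq = genome.fetch(lo, hi) if genome.is_circular or lo >= 0 \
            else genome.fetch(0, hi)
        truncated = len(seq) < length
        return (seq, truncated) if not leaving else (revcomp(seq), truncated)
    lo, hi = pos, pos + length
    seq = genome.fetch(lo, hi)
    truncated = len(seq) < length
    return (revcomp(seq), truncated) if not leaving else (seq, truncated)


def reconstruct_junction_sequence(candidate: CandidateJunction, genome: Genome,
                                  flank: int) -> CandidateJunction:
    """Fill in the junction sequence: ``flank`` bases approaching side_1's
    breakpoint followed by ``flank`` bases leaving side_2's breakpoint."""
    left, tl = _fetch_oriented(genome, candidate.side_1.ref_position, flank,
                               candidate.side_1.continuation, leaving=False)
    right, tr = _fetch_oriented(genome, candidate.side_2.ref_position, flank,
                                candidate.side_2.continuation, leaving=True)
    candidate.junction_sequence = left + right
    candidate.breakpoint_index = len(left)
    candidate.truncated_flank = tl or tr
    return candidate


def _continuation_past(genome: Genome, side: JunctionSide, length: int) -> str:
    """The reference bases that follow the side's last retained base, in the
    junction's reading orientation (what a reference-supporting read sees)."""
    if side.continuation == -1:
        return genome.fetch(side.ref_position + 1, side.ref_position + 1 + length)
    return revcomp(genome.fetch(side.ref_position - length,
                                side.ref_position))


def _context_before(genome: Genome, side: JunctionSide, length: int) -> str:
    """The reference bases that precede the side's first base when the side
    is read as the right half of a junction."""
    if side.continuation == +1:
        return genome.fetch(side.ref_position - length, side.ref_position)
    return revcomp(genome.fetch(side.ref_position + 1,
                                side.ref_position + 1 + length))


def compute_ambiguity(candidate: CandidateJunction, genome: Genome,
                      max_scan: int = 100) -> CandidateJunction:
    """Breakpoint micro-homology: bases adjacent to the breakpoint where the
    junction matches both original reference contexts equally well.

    ``A = homology_forward + homology_backward``; with canonical (leftmost)
    placement the backward component is zero by construction, but it is
    computed anyway so non-canonical candidates are handled.
    """
    bp = candidate.breakpoint_index
    seq = candidate.junction_sequence
    if not seq:
        raise ValueError("reconstruct the junction sequence first")
    cont1 = _continuation_past(genome, candidate.side_1, max_scan)
    right = seq[bp:bp + max_scan]
    hf = 0
    while hf < min(len(cont1), len(right)) and right[hf] == cont1[hf]:
        hf += 1
    pre2 = _context_before(genome, candidate.side_2, max_scan)
    left = seq[max(0, bp - max_scan):bp]
    hb = 0
    while (hb < min(len(pre2), len(left))
           and left[-1 - hb] == pre2[-1 - hb]):
        hb += 1
    candidate.homology_forward = hf
    candidate.homology_backward = hb
    candidate.A = hf + hb
    return candidate


def side_reference_window(candidate: CandidateJunction, which: int,
                          E: int) -> tuple[int, int]:
    """Reference interval a read must span perfectly to support this side's
    original (unmutated) context: the ambiguity window plus E on each side.

    Returns a half-open interval; for continuation -1 sides it runs upward
    through the breakpoint, for +1 sides downward. ``which`` is 1 or 2.
    """
    side = candidate.side_1 if which == 1 else candidate.side_2
    hf, hb = candidate.homology_forward, candidate.homology_backward
    before, after = hb + E, hf + E  # bases kept before bp / extending past it
    if which == 1:
        if side.continuation == -1:
            lo = side.ref_position + 1 - before
            hi = side.ref_position + 1 + after
        else:
            lo = side.ref_position - after
            hi = side.ref_position + before
    else:
        if side.continuation == +1:
            lo = side.ref_position - before
            hi = side.ref_position + after
        else:
            lo = side.ref_position + 1 - after
            hi = side.ref_position + 1 + before
    return lo, hi


def junction_window(candidate: CandidateJunction, E: int) -> tuple[int, int]:
    """Interval of the junction sequence a spanning read must match
    perfectly (half-open, local coordinates)."""
    bp = candidate.breakpoint_index
    return (bp - candidate.homology_backward - E,
            bp + candidate.homology_forward + E)


# ---------------------------------------------------------------------------
# Spanning-read counting
# ---------------------------------------------------------------------------

def _window_perfect_rows(table: AlignmentTable, reads: ReadSet,
                         target_enc: np.ndarray, win_lo: int, win_hi: int
                         ) -> np.ndarray:
    """Row indices of alignments covering [win_lo, win_hi) with no mismatch
    inside the window. ``target_enc`` is the encoded target sequence (the
    reference's extended array or a junction sequence)."""
    cover = (table.ref_start <= win_lo) & (table.ref_end >= win_hi)
    rows = np.nonzero(cover)[0]
    if len(rows) == 0:
        return rows
    clean = table.mismatches[rows] == 0
    out = [rows[clean]]
    check = rows[~clean]
    if len(check):
        wlen = win_hi - win_lo
        target = target_enc[win_lo:win_hi]
        good = []
        for r in check:
            if table.strand[r] == 0:
                off = win_lo - table.ref_start[r] + table.read_start[r]
                frag = reads.matrix[table.read[r], off:off + wlen]
                if np.array_equal(frag, target):
                    good.append(r)
            else:
                # original read offset of ref position p is
                # read_end - 1 - (p - ref_start)
                hi_off = table.read_end[r] - (win_lo - table.ref_start[r])
                frag = reads.matrix[table.read[r], hi_off - wlen:hi_off]
                comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
                if np.array_equal(comp[frag[::-1]], target):
                    good.append(r)
        out.append(np.array(good, dtype=rows.dtype))
    return np.concatenate(out)


def count_spanning_reads(reads: ReadSet, candidates: list[CandidateJunction],
                         ref_table: AlignmentTable, ref_index: KmerIndex,
                         policy: SpanningPolicy,
                         mapping_policy: MappingPolicy = MappingPolicy(),
                         side_informative=None) -> list[JunctionCounts]:
    """Count variant (n_V) and per-reference-side (n_R) spanning reads.

    Re-maps every read lacking a perfect full-length reference placement
    against the reconstructed junction sequences; a read supports a junction
    when its junction alignment beats its best reference alignment (matched
    bases; ties to reference) and matches the junction perfectly across the
    ambiguity window plus E on each side. Reference-side counts apply the
    same window rule on the reference.

    ``side_informative(candidate, which)`` may veto reference-side counting
    for sides in repeats.
    """
    E = policy.E
    genome = ref_index.genome
    n = ref_index.n
    results = [JunctionCounts(candidate=c) for c in candidates]
    if len(reads) == 0 or not candidates:
        return results

    # per-read best reference alignment quality and full-perfect flag
    best_ref = np.zeros(len(reads), dtype=np.int64)
    if len(ref_table):
        np.maximum.at(best_ref, ref_table.read, ref_table.matched)
    perfect_full = np.zeros(len(reads), dtype=bool)
    if len(ref_table):
        pf = ((ref_table.mismatches == 0)
              & (ref_table.read_start == 0)
              & (ref_table.read_end == reads.lengths[ref_table.read]))
        perfect_full[ref_table.read[pf]] = True

    # junction "genome": concatenated junction sequences with N separators
    sep = "N" * (ref_index.k + 1)
    offsets = []
    pieces = []
    pos = 0
    for c in candidates:
        offsets.append(pos)
        pieces.append(c.junction_sequence)
        pos += len(c.junction_sequence) + len(sep)
        pieces.append(sep)
    jgenome = Genome(id="junctions", sequence="".join(pieces),
                     topology="linear")
    jindex = KmerIndex(jgenome, k=ref_index.k)
    offsets = np.array(offsets, dtype=np.int64)

    sub_rows = np.nonzero(~perfect_full)[0]
    sub = ReadSet([reads.names[i] for i in sub_rows], reads.matrix[sub_rows],
                  reads.lengths[sub_rows])
    jtable = map_reads_batch(sub, jindex, mapping_policy)
    jenc = jgenome.encoded()
    ref_enc_ext = np.concatenate([genome.encoded(), genome.encoded()[:600]]) \
        if genome.is_circular else genome.encoded()

    # Each re-mapped read is assigned to a single best location: among the
    # junction alignments achieving its maximum matched-base count, the
    # junction with the most split-read support wins (candidates arrive
    # support-sorted, so the lowest index). Without unique assignment, a
    # locus that is locally self-reverse-complementary can make reads of a
    # real junction also match a chimeric candidate perfectly and fake its
    # spanning support.
    if len(jtable):
        jid = np.searchsorted(offsets, jtable.ref_start, "right") - 1
        best_junction = np.zeros(len(sub), dtype=np.int64)
        np.maximum.at(best_junction, jtable.read, jtable.matched)
        eligible = jtable.matched == best_junction[jtable.read]
        assign = np.full(len(sub), -1, dtype=np.int64)
        erows = np.nonzero(eligible)[0]
        order = np.lexsort((jid[erows], jtable.read[erows]))[::-1]
        # reversed order: the last write per read is its lowest junction id
        assign[jtable.read[erows[order]]] = jid[erows[order]]
    for ci, (cand, res) in enumerate(zip(candidates, results)):
        win_lo, win_hi = junction_window(cand, E)
        glo, ghi = offsets[ci] + win_lo, offsets[ci] + win_hi
        if len(jtable) == 0:
            continue
        rows = np.nonzero(jid == ci)[0]
        if len(rows) == 0:
            continue
        t = jtable.select(rows)
        ok = _window_perfect_rows(t, sub, jenc, glo, ghi)
        if len(ok):
            t2 = t.select(ok)
            better = (t2.matched > best_ref[sub_rows[t2.read]]) \
                & (assign[t2.read] == ci)
            res.n_V = len(np.unique(t2.read[better]))

    # reference-side counts
    for ci, (cand, res) in enumerate(zip(candidates, results)):
        for which in (1, 2):
            if side_informative is not None and \
                    not side_informative(cand, which):
                continue
            lo, hi = side_reference_window(cand, which, E)
            if genome.is_circular:
                wlen = hi - lo
                lo %= n
                hi = lo + wlen
            if lo < 0 or hi > len(ref_enc_ext):
                continue  # breakpoint at a linear end: side unevaluable
            ok = _window_perfect_rows(ref_table, reads, ref_enc_ext, lo, hi)
            res.n_R.append(int(len(np.unique(ref_table.read[ok]))))
            res.sides_counted.append(which)
    return results


def call_polymorphic_junctions(counts: list[JunctionCounts],
                               policy: SpanningPolicy) -> list[JunctionCounts]:
    """Accept junctions with n_V >= n_min; others retained with a reason."""
    for res in counts:
        if res.n_V >= policy.n_min:
            res.accepted = True
        else:
            res.accepted = False
            res.reject_reason = (
                f"spanning reads {res.n_V} below threshold {policy.n_min}")
    return counts
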
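"""Read-to-reference mapping with the contract junction calling needs.

The junction algorithm does not need a general-purpose aligner; it needs
every maximal local (partial) alignment of at least ``m = ceil(6 + 0.2 L)``
bases reported, including secondary placements inside repeats, on either
strand. The internal engine is an exact k-mer seed (default k=12) index over
the forward genome plus vectorized ungapped extension (maximal-scoring
segment, match +1 / mismatch -3) over whole batches of reads at once.
Alternatively, alignments can be ingested from SAM produced by an external
mapper (soft clips and supplementary records define the split pairs).

Alignments are reported in original read orientation; reference coordinates
are 0-based half-open on the forward strand. On circular genomes alignments
may run past the origin (``ref_end`` > genome length means wrap-around).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pysam

from ._seq import N_CODE, encode
from .genome import Genome
from .simulate import ReadSet

__all__ = [
    "MappingPolicy",
    "ReadAlignment",
    "AlignmentTable",
    "KmerIndex",
    "build_index",
    "map_read",
    "map_reads_batch",
    "read_sam",
]

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_SENTINEL = 5  # reference padding code; never equals any read base


def min_match_length(read_length: int) -> int:
    """Minimum reported alignment length, ceil(6 + 0.2 L)."""
    return math.ceil(6 + 0.2 * read_length)


@dataclass(frozen=True)
class MappingPolicy:
    """Alignment reporting policy.

    ``min_match`` defaults to ceil(6 + 0.2 L) per read; ``max_hits`` caps the
    number of placements reported per read (repeats), resolved
    deterministically by score then coordinate.
    """

    max_hits: int = 16
    mismatch_penalty: int = 3
    min_match_override: Optional[int] = None

    def min_match(self, read_length: int) -> int:
        if self.min_match_override is not None:
            return self.min_match_override
        return min_match_length(read_length)


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int

    @property
    def length(self) -> int:
        return self.read_end - self.read_start

    @property
    def is_perfect(self) -> bool:
        return self.mismatches == 0


class AlignmentTable:
    """Column-oriented batch of alignments (numpy arrays, one row each)."""

    FIELDS = ("read", "strand", "read_start", "read_end",
              "ref_start", "ref_end", "mismatches", "matched")

    def __init__(self, **cols: np.ndarray):
        n = len(cols["read"])
        for f in self.FIELDS:
            assert len(cols[f]) == n
            setattr(self, f, cols[f])
        self.n = n

    @classmethod
    def empty(cls) -> "AlignmentTable":
        return cls(**{f: np.zeros(0, dtype=np.int64) for f in cls.FIELDS})

    def __len__(self) -> int:
        return self.n

    def select(self, mask_or_idx) -> "AlignmentTable":
        return AlignmentTable(
            **{f: getattr(self, f)[mask_or_idx] for f in self.FIELDS})

    @classmethod
    def concat(cls, tables: list["AlignmentTable"]) -> "AlignmentTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return cls.empty()
        return cls(**{f: np.concatenate([getattr(t, f) for t in tables])
                      for f in cls.FIELDS})

    def to_read_alignments(self, names: list[str]) -> list[ReadAlignment]:
        out = []
        for i in range(self.n):
            out.append(ReadAlignment(
                read_id=names[self.read[i]],
                read_start=int(self.read_start[i]),
                read_end=int(self.read_end[i]),
                ref_start=int(self.ref_start[i]),
                ref_end=int(self.ref_end[i]),
                strand="+" if self.strand[i] == 0 else "-",
                mismatches=int(self.mismatches[i])))
        return out


class KmerIndex:
    """Exact k-mer lookup over the forward strand of a genome.

    Circular genomes are indexed with a pad of the first bases appended so
    reads straddling the origin map contiguously; positions are reported in
    this extended coordinate system and canonicalized by the mapper.
    """

    def __init__(self, genome: Genome, k: int = 12, pad: Optional[int] = None):
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31]")
        if len(genome) < k:
            raise ValueError("genome shorter than k")
        self.genome = genome
        self.k = k
        self.n = len(genome)
        enc = genome.encoded()
        if genome.is_circular:
            if pad is None:
                pad = min(self.n, 600)
            enc = np.concatenate([enc, enc[:pad]])
        self.pad = pad if genome.is_circular else 0
        self.enc_ext = enc
        codes, valid = _kmer_codes(enc, k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order].astype(np.int64)

    def lookup(self, kmer: str) -> np.ndarray:
        """Reference positions of one exact k-mer (canonical coordinates)."""
        enc = encode(kmer)
        if len(enc) != self.k or (enc >= 4).any():
            raise ValueError("query must be a k-long ACGT string")
        code = 0
        for b in enc:
            code = code * 4 + int(b)
        lo = np.searchsorted(self.sorted_codes, code, "left")
        hi = np.searchsorted(self.sorted_codes, code, "right")
        hits = np.unique(self.sorted_pos[lo:hi] % self.n)
        return hits


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling base-4 codes over an encoded sequence; invalid where any base
    in the window is not ACGT."""
    n = len(enc)
    if n < k:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    bad = (enc >= 4).astype(np.int32)
    for j in range(k):
        codes = codes * 4 + enc[j:j + m].astype(np.int64)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    window_bad = bad_cum[k:] - bad_cum[:-k]
    return codes, window_bad == 0


def build_index(genome: Genome, k: int = 12) -> KmerIndex:
    return KmerIndex(genome, k=k)


def map_reads_batch(reads: ReadSet, index: KmerIndex,
                    policy: MappingPolicy = MappingPolicy(),
                    chunk_size: int = 100_000,
                    exhaustive: bool = False) -> AlignmentTable:
    """Map every read on both strands; returns all qualifying alignments.

    By default reads that match the reference perfectly over their whole
    length take a fast anchored path that reports every perfect full-length
    placement (including all repeat copies) and skips the search for
    additional partial placements, which such reads cannot contribute to
    junction calling anyway. ``exhaustive=True`` forces full seeding for
    every read, reporting all maximal local alignments.
    """
    tables = []
    for lo in range(0, len(reads), chunk_size):
        hi = min(lo + chunk_size, len(reads))
        sub = ReadSet(reads.names[lo:hi], reads.matrix[lo:hi],
                      reads.lengths[lo:hi])
        t = _map_chunk(sub, index, policy, exhaustive)
        t.read += lo
        tables.append(t)
    return AlignmentTable.concat(tables)


def _rc_matrix(matrix: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    out = np.full_like(matrix, N_CODE)
    for ell in np.unique(lengths):
        rows = np.nonzero(lengths == ell)[0]
        out[np.ix_(rows, np.arange(ell))] = np.flip(
            _COMP[matrix[np.ix_(rows, np.arange(ell))]], axis=1)
    return out


def _perfect_full_pass(qmat, lengths, strand, gref, index, W):
    """All perfect full-length placements anchored on the first k-mer."""
    k = index.k
    nreads = qmat.shape[0]
    anchors = np.zeros(nreads, dtype=np.int64)
    ok = lengths >= k
    for j in range(k):
        anchors = anchors * 4 + qmat[:, j].astype(np.int64)
        ok &= qmat[:, j] < 4
    rows = np.nonzero(ok)[0]
    lo = np.searchsorted(index.sorted_codes, anchors[rows], "left")
    hi = np.searchsorted(index.sorted_codes, anchors[rows], "right")
    counts = hi - lo
    hit_rows = np.repeat(rows, counts)
    hit_ref = index.sorted_pos[np.repeat(lo, counts) + _ragged_arange(counts)]
    if len(hit_rows) == 0:
        return AlignmentTable.empty()
    # candidate start = hit_ref (anchor is at read position 0)
    idx = hit_ref[:, None] + np.arange(W)[None, :] + W
    refseg = gref[idx]
    q = qmat[hit_rows]
    in_read = np.arange(W)[None, :] < lengths[hit_rows][:, None]
    perfect = (((q == refseg) & (q < 4)) | ~in_read).all(axis=1)
    hit_rows = hit_rows[perfect]
    hit_ref = hit_ref[perfect]
    ell = lengths[hit_rows].astype(np.int64)
    n = index.n
    start = hit_ref.astype(np.int64)
    if index.genome.is_circular:
        start = start % n
    table = AlignmentTable(
        read=hit_rows.astype(np.int64),
        strand=np.full(len(hit_rows), strand, dtype=np.int64),
        read_start=np.zeros(len(hit_rows), dtype=np.int64),
        read_end=ell, ref_start=start, ref_end=start + ell,
        mismatches=np.zeros(len(hit_rows), dtype=np.int64), matched=ell)
    _, uniq = np.unique(table.read * (2 * np.int64(n)) + table.strand * n
                        + table.ref_start, return_index=True)
    return table.select(np.sort(uniq))


def _map_chunk(reads: ReadSet, index: KmerIndex,
               policy: MappingPolicy, exhaustive: bool) -> AlignmentTable:
    k = index.k
    W = reads.width
    nreads = len(reads)
    if nreads == 0 or W < k:
        return AlignmentTable.empty()
    lengths = reads.lengths
    # reference array padded with sentinels on both ends so any diagonal in
    # [-W, len(ext)) can be gathered without bounds checks
    gref = np.full(len(index.enc_ext) + 2 * W, _SENTINEL, dtype=np.uint8)
    gref[W:W + len(index.enc_ext)] = index.enc_ext

    qmats = {0: reads.matrix, 1: _rc_matrix(reads.matrix, lengths)}
    parts = []
    todo = np.ones(nreads, dtype=bool)
    if not exhaustive:
        for strand in (0, 1):
            t = _perfect_full_pass(qmats[strand], lengths, strand, gref,
                                   index, W)
            if len(t):
                todo[t.read] = False
                parts.append(t)
    rows = np.nonzero(todo)[0] if not exhaustive else np.arange(nreads)
    if len(rows):
        for strand in (0, 1):
            t = _map_strand(qmats[strand][rows], lengths[rows], strand, gref,
                            index, policy, W)
            t.read = rows[t.read]
            parts.append(t)
    table = AlignmentTable.concat(parts)
    return _cap_hits(table, policy.max_hits)


def _map_strand(qmat, lengths, strand, gref, index, policy, W):
    k = index.k
    nreads = qmat.shape[0]
    m_per_read = np.ceil(6 + 0.2 * lengths).astype(np.int64) \
        if policy.min_match_override is None \
        else np.full(nreads, policy.min_match_override, dtype=np.int64)
    # seed lookup
    nq = W - k + 1
    codes = np.zeros((nreads, nq), dtype=np.int64)
    bad = (qmat >= 4).astype(np.int32)
    bad_cum = np.cumsum(bad, axis=1)
    window_bad = bad_cum[:, k - 1:].copy()
    window_bad[:, 1:] -= bad_cum[:, :nq - 1]
    for j in range(k):
        codes = codes * 4 + qmat[:, j:j + nq].astype(np.int64)
    valid = window_bad == 0
    rows, qpos = np.nonzero(valid)
    qcodes = codes[rows, qpos]
    lo = np.searchsorted(index.sorted_codes, qcodes, "left")
    hi = np.searchsorted(index.sorted_codes, qcodes, "right")
    counts = np.minimum(hi - lo, policy.max_hits * 4)
    total = int(counts.sum())
    if total == 0:
        return AlignmentTable.empty()
    hit_read = np.repeat(rows, counts)
    hit_qpos = np.repeat(qpos, counts)
    offs = _ragged_arange(counts)
    hit_slot = np.repeat(lo, counts) + offs
    hit_ref = index.sorted_pos[hit_slot]
    diag = hit_ref - hit_qpos  # may be slightly negative at linear ends

    # unique candidate (read, diag) pairs with seed-count filter
    key = hit_read.astype(np.int64) * (len(index.enc_ext) + 2 * W) \
        + (diag + W)
    ukey, first, seed_counts = np.unique(key, return_index=True,
                                         return_counts=True)
    cand_read = hit_read[first]
    cand_diag = diag[first]
    # a true minimal side of m bases carries m-k+1 seeds; requiring >= 2
    # discards most chance 1-seed diagonals unless m is too close to k
    need2 = (m_per_read[cand_read] - k + 1) >= 2
    keep = (seed_counts >= 2) | ~need2
    cand_read = cand_read[keep]
    cand_diag = cand_diag[keep]
    if len(cand_read) == 0:
        return AlignmentTable.empty()

    # gather reference segments along each candidate diagonal
    idx = (cand_diag[:, None] + np.arange(W)[None, :]) + W
    refseg = gref[idx]
    q = qmat[cand_read]
    col = np.arange(W)[None, :]
    in_read = col < lengths[cand_read][:, None]
    match = (q == refseg) & (q < 4) & in_read
    penalty = policy.mismatch_penalty
    score = np.where(match, 1, -penalty).astype(np.int32)
    score[~in_read] = -penalty

    best, best_s, best_e = _kadane(score)
    mm_cum = np.cumsum((~match) & in_read, axis=1)
    ncand = len(cand_read)
    r = np.arange(ncand)
    mm = mm_cum[r, best_e - 1] - np.where(best_s > 0,
                                          mm_cum[r, best_s - 1], 0)
    length = best_e - best_s
    matched = length - mm
    keep = matched >= m_per_read[cand_read]
    if not keep.any():
        return AlignmentTable.empty()
    cand_read = cand_read[keep]
    cand_diag = cand_diag[keep]
    best_s, best_e = best_s[keep], best_e[keep]
    mm = mm[keep]
    matched = matched[keep]
    ell = lengths[cand_read].astype(np.int64)

    ref_start = cand_diag + best_s
    ref_end = cand_diag + best_e
    if strand == 0:
        rs, re_ = best_s.astype(np.int64), best_e.astype(np.int64)
    else:  # intervals on the reverse-complemented query -> original read coords
        rs, re_ = ell - best_e, ell - best_s
    # canonicalize circular coordinates
    n = index.n
    if index.genome.is_circular:
        shift = (ref_start // n) * n
        ref_start = ref_start - shift
        ref_end = ref_end - shift
    table = AlignmentTable(
        read=cand_read.astype(np.int64), strand=np.full(len(cand_read), strand,
                                                        dtype=np.int64),
        read_start=rs, read_end=re_,
        ref_start=ref_start.astype(np.int64), ref_end=ref_end.astype(np.int64),
        mismatches=mm.astype(np.int64), matched=matched.astype(np.int64))
    # duplicate placements can arise on circular genomes from the pad copy
    _, uniq = np.unique(
        (table.read * 2 + table.strand) * (np.int64(n) * (W + 1))
        + (table.ref_start % n) * (W + 1) + table.read_start,
        return_index=True)
    return table.select(np.sort(uniq))


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """[0..c0), [0..c1), ... concatenated."""
    total = int(counts.sum())
    starts = np.cumsum(counts) - counts
    return np.arange(total) - np.repeat(starts, counts)


def _kadane(score: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise maximal-scoring contiguous segment; returns (score, start, end)."""
    nrow, ncol = score.shape
    cur = np.zeros(nrow, dtype=np.int64)
    cur_start = np.zeros(nrow, dtype=np.int64)
    best = np.full(nrow, -1, dtype=np.int64)
    best_s = np.zeros(nrow, dtype=np.int64)
    best_e = np.ones(nrow, dtype=np.int64)
    for j in range(ncol):
        s = score[:, j].astype(np.int64)
        cur += s
        reset = cur < s
        cur[reset] = s[reset]
        cur_start[reset] = j
        better = cur > best
        best[better] = cur[better]
        best_s[better] = cur_start[better]
        best_e[better] = j + 1
    return best, best_s, best_e


def _cap_hits(table: AlignmentTable, max_hits: int) -> AlignmentTable:
    """Keep at most max_hits placements per read, best matched first, then
    deterministic by coordinate."""
    if len(table) == 0:
        return table
    order = np.lexsort((table.ref_start, table.strand, -table.matched,
                        table.read))
    sorted_read = table.read[order]
    # rank within each read group
    new_group = np.concatenate([[True], sorted_read[1:] != sorted_read[:-1]])
    idx_in_group = np.arange(len(order)) - \
        np.maximum.accumulate(np.where(new_group, np.arange(len(order)), 0))
    keep = order[idx_in_group < max_hits]
    return table.select(np.sort(keep))


def map_read(read_seq: str, index: KmerIndex,
             policy: MappingPolicy = MappingPolicy(),
             read_id: str = "read") -> list[ReadAlignment]:
    """Map one read; returns all qualifying alignments (possibly empty)."""
    rs = ReadSet.from_strings([(read_id, read_seq)])
    if len(read_seq) < policy.min_match(len(read_seq)):
        return []
    table = map_reads_batch(rs, index, policy)
    return table.to_read_alignments([read_id])


def read_sam(path, genome: Genome) -> list[ReadAlignment]:
    """Ingest primary + supplementary/secondary SAM records as alignments.

    Soft clips define the aligned read interval; reverse-strand intervals are
    converted back to original read orientation. Unmapped records are
    skipped; coordinates beyond the genome raise.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.reference_end is None or rec.reference_end > len(genome):
                raise ValueError(
                    f"alignment for {rec.query_name} extends past genome end")
            qstart, qend = rec.query_alignment_start, rec.query_alignment_end
            qlen = rec.infer_read_length() or (qend - qstart)
            if rec.is_reverse:
                read_start, read_end = qlen - qend, qlen - qstart
            else:
                read_start, read_end = qstart, qend
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(ReadAlignment(
                read_id=rec.query_name, read_start=read_start,
                read_end=read_end, ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+", mismatches=int(nm)))
    return out
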
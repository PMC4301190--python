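"""Reference and variant genomes, exact repeats, and planted structural variants.

This module provides the substrate for the whole pipeline: a :class:`Genome`
holding a chromosome sequence, discovery of exact repeats (which make
junction breakpoints unmappable and must be avoided when planting truth
variants), application of structural variants with a reference<->variant
coordinate map, and the annotations describing mobile-element (IS) families.

Coordinates are 0-based half-open everywhere inside the package; anything
written for users (TSV, GenomeDiff-flavored output) is 1-based inclusive.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import encode, random_sequence, revcomp

__all__ = [
    "Genome",
    "RepeatRegion",
    "StructuralVariant",
    "MobileElementAnnotation",
    "VariantGenome",
    "random_genome",
    "find_exact_repeats",
    "plant_random_deletions",
    "apply_variants",
    "canonical_deletion_sides",
    "read_fasta",
    "write_fasta",
    "write_truth_table",
    "read_truth_table",
    "load_mobile_elements",
]


@dataclass(frozen=True)
class Genome:
    """A single chromosome with circular or linear topology."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps around the origin when circular.

        On a linear genome the slice is truncated at the ends.
        """
        n = len(self.sequence)
        if not self.is_circular:
            return self.sequence[max(0, start):min(n, end)]
        length = end - start
        if length > n:
            raise ValueError("fetch longer than genome")
        start %= n
        if start + length <= n:
            return self.sequence[start:start + length]
        return self.sequence[start:] + self.sequence[:start + length - n]

    def encoded(self) -> np.ndarray:
        return encode(self.sequence)


def random_genome(length: int, seed: int, id: str = "synthetic",
                  topology: str = "circular") -> Genome:
    """Uniform-random ACGT genome; circular by default so tiling coverage is
    exactly uniform."""
    rng = np.random.default_rng(seed)
    return Genome(id=id, sequence=random_sequence(length, rng), topology=topology)


@dataclass(frozen=True)
class RepeatRegion:
    """One copy of an exact repeat: [start, end) duplicated at partner_start."""

    start: int
    end: int
    partner_start: int
    length: int
    strand: str = "+"  # orientation of the partner copy relative to this one


@dataclass(frozen=True)
class StructuralVariant:
    """A planted mutation applied to a reference genome.

    ``start`` is the 0-based reference position of the first deleted base
    (deletions) or the reference base before which the payload is spliced
    (insertions).
    """

    kind: str  # deletion | is_insertion | small_insertion
    start: int
    size: int
    payload: str = ""
    element_family: str = ""

    def __post_init__(self):
        if self.kind not in ("deletion", "is_insertion", "small_insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "deletion" and self.size <= 0:
            raise ValueError("deletion size must be positive")
        if self.kind != "deletion" and len(self.payload) != self.size:
            raise ValueError("insertion payload length must equal size")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval removed by this variant (empty for insertions)."""
        if self.kind == "deletion":
            return (self.start, self.start + self.size)
        return (self.start, self.start)


@dataclass(frozen=True)
class MobileElementAnnotation:
    """All copies of one mobile-element (IS) family in the reference."""

    family: str
    copies: tuple[tuple[int, int, str], ...]  # (start, end, strand), 0-based half-open

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in self.copies)


# ---------------------------------------------------------------------------
# Exact repeat finding
# ---------------------------------------------------------------------------

def find_exact_repeats(genome: Genome, min_length: int,
                       both_strands: bool = False,
                       max_pairs: int = 5_000_000) -> list[RepeatRegion]:
    """Find all maximal exact repeats of at least ``min_length`` bases.

    Anchors every duplicated ``min_length``-mer and merges anchors along
    diagonals into maximal matches, so each reported region has an exact
    duplicate elsewhere in the genome. Forward-strand matches only by
    default; ``both_strands`` additionally reports reverse-complement
    duplicates (strand '-').
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    seq = genome.sequence
    n = len(seq)
    if n == 0:
        raise ValueError("empty genome")
    k = min_length
    if n < k:
        return []

    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        positions[seq[i:i + k]].append(i)

    regions: set[RepeatRegion] = set()

    # forward-forward matches: group anchor pairs by diagonal (j - i)
    diag_pairs: dict[int, list[int]] = defaultdict(list)
    npairs = 0
    for pos_list in positions.values():
        if len(pos_list) < 2:
            continue
        for a in range(len(pos_list)):
            for b in range(a + 1, len(pos_list)):
                i, j = pos_list[a], pos_list[b]
                diag_pairs[j - i].append(i)
                npairs += 1
                if npairs > max_pairs:
                    raise ValueError(
                        "repeat structure too dense (anchor pair cap exceeded)")
    for diag, starts in diag_pairs.items():
        starts.sort()
        run_start = starts[0]
        prev = starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            length = prev - run_start + k
            regions.add(RepeatRegion(run_start, run_start + length,
                                     run_start + diag, length))
            regions.add(RepeatRegion(run_start + diag, run_start + diag + length,
                                     run_start, length))
            if i is not None:
                run_start = prev = i

    if both_strands:
        rc_positions: dict[str, list[int]] = defaultdict(list)
        for kmer, pos_list in positions.items():
            rc_positions[revcomp(kmer)] = pos_list
        anti_pairs: dict[int, list[int]] = defaultdict(list)
        for kmer, pos_list in positions.items():
            partners = rc_positions.get(kmer)
            if not partners:
                continue
            for i in pos_list:
                for j in partners:
                    if j < i:  # count each unordered pair once
                        continue
                    # seq[i:i+k] == revcomp(seq[j:j+k]); extending the match by
                    # one base moves i up and j down: constant anti-diagonal i+j
                    anti_pairs[i + j].append(i)
        for anti, starts in anti_pairs.items():
            starts = sorted(set(starts))
            run_start = prev = starts[0]
            for i in starts[1:] + [None]:
                if i is not None and i == prev + 1:
                    prev = i
                    continue
                length = prev - run_start + k
                j_start = anti - prev  # partner of the last anchor
                if not (run_start == j_start and length == k and anti == 2 * run_start):
                    regions.add(RepeatRegion(run_start, run_start + length,
                                             j_start, length, strand="-"))
                    regions.add(RepeatRegion(j_start, j_start + length,
                                             run_start, length, strand="-"))
                if i is not None:
                    run_start = prev = i

    return sorted(regions, key=lambda r: (r.start, r.end, r.partner_start))


def _repeat_mask(genome: Genome, repeats: Iterable[RepeatRegion]) -> np.ndarray:
    mask = np.zeros(len(genome), dtype=bool)
    for r in repeats:
        mask[r.start:r.end] = True
    return mask


# ---------------------------------------------------------------------------
# Planting variants
# ---------------------------------------------------------------------------

def plant_random_deletions(genome: Genome, count: int, size: int,
                           min_repeat: int = 50, seed: int = 0,
                           flank: int = 50,
                           max_tries_per_deletion: int = 1000
                           ) -> tuple["VariantGenome", list[StructuralVariant]]:
    """Plant ``count`` non-overlapping deletions of exactly ``size`` bases at
    uniform-random admissible positions.

    A position is admissible when the deleted interval plus ``flank`` bases on
    each side contains no base of any exact repeat of ``min_repeat`` or more
    bases (so every new junction is uniquely mappable by reads of length
    <= flank), stays ``flank`` bases away from the origin, and keeps at least
    ``2 * flank`` bases between neighboring deletions (so the reference
    context around each junction is unmutated for a full read length).
    """
    n = len(genome)
    rng = np.random.default_rng(seed)
    repeats = find_exact_repeats(genome, min_repeat)
    forbidden = _repeat_mask(genome, repeats)

    lo, hi = flank, n - size - flank
    if hi <= lo:
        raise ValueError("genome too short to host deletions of this size")
    chosen: list[int] = []
    occupied: list[tuple[int, int]] = []  # deletion intervals incl. spacing buffer
    for _ in range(count):
        for attempt in range(max_tries_per_deletion):
            s = int(rng.integers(lo, hi))
            e = s + size
            if forbidden[s - flank:e + flank].any():
                continue
            if any(s - 2 * flank < oe and os_ < e + 2 * flank
                   for os_, oe in occupied):
                continue
            chosen.append(s)
            occupied.append((s, e))
            break
        else:
            raise ValueError(
                f"could not place deletion {len(chosen) + 1}/{count}: no "
                f"admissible position outside repeats >= {min_repeat} bp with "
                f"{flank}-bp mappable flanks after {max_tries_per_deletion} tries")
    variants = sorted(
        (StructuralVariant("deletion", s, size) for s in chosen),
        key=lambda v: v.start)
    return apply_variants(genome, variants), variants


def apply_variants(genome: Genome,
                   variants: list[StructuralVariant]) -> "VariantGenome":
    """Apply sorted, non-overlapping variants; keeps a coordinate map."""
    prev_end = 0
    for v in variants:
        s, e = v.ref_span
        if s < prev_end:
            raise ValueError("variants must be sorted and non-overlapping")
        if e > len(genome) or s < 0:
            raise ValueError("variant outside genome bounds")
        prev_end = max(e, s)

    pieces: list[str] = []
    segments: list[tuple[int, int, int]] = []  # (ref_start, ref_end, var_start)
    cursor = 0  # reference position
    var_pos = 0
    seq = genome.sequence
    for v in variants:
        s, e = v.ref_span
        if s > cursor:
            pieces.append(seq[cursor:s])
            segments.append((cursor, s, var_pos))
            var_pos += s - cursor
        if v.kind == "deletion":
            cursor = e
        else:
            pieces.append(v.payload)
            var_pos += len(v.payload)
            cursor = s
    if cursor < len(seq):
        pieces.append(seq[cursor:])
        segments.append((cursor, len(seq), var_pos))
        var_pos += len(seq) - cursor

    variant_genome = Genome(id=genome.id + "_variant", sequence="".join(pieces),
                            topology=genome.topology)
    return VariantGenome(genome=variant_genome, reference=genome,
                         variants=tuple(variants), segments=tuple(segments))


def canonical_deletion_sides(reference_sequence: str, start: int, end: int
                             ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Canonical (leftmost) junction sides for deleting [start, end).

    When the two deletion boundaries share homologous bases the breakpoint can
    be placed anywhere within the homology window; the canonical placement
    slides it as far left as possible so that independently derived junctions
    merge. Returns ((pos, dir), (pos, dir)) with dir = -1 for a side whose
    reference context continues toward lower coordinates and +1 toward higher.
    """
    seq = reference_sequence
    shift = 0
    while start - 1 - shift >= 0 and seq[start - 1 - shift] == seq[end - 1 - shift]:
        shift += 1
    return ((start - 1 - shift, -1), (end - shift, +1))


@dataclass(frozen=True)
class VariantGenome:
    """A mutated genome plus the coordinate map back to its reference."""

    genome: Genome
    reference: Genome
    variants: tuple[StructuralVariant, ...]
    segments: tuple[tuple[int, int, int], ...]  # (ref_start, ref_end, var_start)

    @property
    def sequence(self) -> str:
        return self.genome.sequence

    def __len__(self) -> int:
        return len(self.genome)

    def ref_to_variant(self, pos: int) -> Optional[int]:
        """Variant coordinate of a reference base, or None if deleted."""
        for rs, re_, vs in self.segments:
            if rs <= pos < re_:
                return vs + (pos - rs)
        return None

    def variant_to_ref(self, pos: int) -> Optional[int]:
        """Reference coordinate of a variant base, or None if inserted."""
        for rs, re_, vs in self.segments:
            if vs <= pos < vs + (re_ - rs):
                return rs + (pos - vs)
        return None

    def truth_junctions(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Canonical junction side pairs created by the planted deletions."""
        out = []
        for v in self.variants:
            if v.kind == "deletion":
                out.append(canonical_deletion_sides(
                    self.reference.sequence, v.start, v.start + v.size))
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path, topology: str = "linear") -> Genome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return Genome(id=record.id, sequence=str(record.seq).upper(), topology=topology)


def write_fasta(genome: Genome, path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id,
                       description=f"topology={genome.topology}")
    SeqIO.write([record], str(path), "fasta")


def write_truth_table(variants: list[StructuralVariant], path) -> None:
    """TSV truth file; user-facing coordinates are 1-based."""
    with open(path, "w") as fh:
        fh.write("kind\tref_start_1based\tsize\tpayload\tfamily\n")
        for v in variants:
            fh.write(f"{v.kind}\t{v.start + 1}\t{v.size}\t"
                     f"{v.payload or '.'}\t{v.element_family or '.'}\n")


def read_truth_table(path) -> list[StructuralVariant]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            kind, start1, size, payload, family = line.rstrip("\n").split("\t")
            out.append(StructuralVariant(
                kind=kind, start=int(start1) - 1, size=int(size),
                payload="" if payload == "." else payload,
                element_family="" if family == "." else family))
    return out


def load_mobile_elements(path) -> list[MobileElementAnnotation]:
    """TSV with columns family, start_1based, end_1based, strand (one copy
    per row); returns one annotation per family."""
    fams: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            family, s1, e1, strand = line.rstrip("\n").split("\t")[:4]
            fams[family].append((int(s1) - 1, int(e1), strand))
    return [MobileElementAnnotation(family=f, copies=tuple(sorted(c)))
            for f, c in sorted(fams.items())]
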
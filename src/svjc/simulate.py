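"""Read simulation: tiling read sets, random sampling with controlled
coverage dispersion, an Illumina-like error model, and sample mixing.

Reads live in a :class:`ReadSet`: a padded uint8 matrix plus per-read
lengths and names. Names encode provenance as ``src|pos|strand|serial`` so
downstream evaluation can recover exactly which genome and position every
read came from.

Coverage dispersion follows the negative-binomial picture used by the
sensitivity model: when the NB size parameter ``r`` is finite, read starts
are sampled from a block-constant gamma intensity field (gamma shape ``r``,
mean 1), which makes the marginal per-position read-depth NB(mean C, size r);
``r = inf`` gives plain Poisson sampling with uniform starts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam

from ._seq import N_CODE, decode, encode
from .genome import Genome, VariantGenome

__all__ = [
    "ErrorModel",
    "ERROR_FREE",
    "DEFAULT_ILLUMINA",
    "CoverageSpec",
    "ReadSet",
    "tiling_reads",
    "sample_reads",
    "mix_samples",
    "write_fastq",
    "read_fastq",
]


@dataclass(frozen=True)
class ErrorModel:
    """Illumina-like per-base error model.

    The substitution rate rises toward the 3' end of the read, mimicking the
    worsening of Illumina cycles. Two parameterizations are supported:
    either ``substitution_rate`` (the mean) with a linear ramp of slope
    ratio ``substitution_ramp`` from 5' to 3', or an explicit
    ``substitution_profile`` of (begin, middle, end) anchor rates joined
    piecewise-linearly. Indel rates are flat per base.

    The default profile (0.002, 0.004, 0.012) with 0.001
    insertions/deletions per base follows the long-standing defaults of the
    Mason Illumina read simulator.
    """

    substitution_rate: float = 0.004
    substitution_ramp: float = 3.0
    insertion_rate: float = 0.001
    deletion_rate: float = 0.001
    quality: int = 35
    substitution_profile: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        rates = [self.substitution_rate, self.insertion_rate,
                 self.deletion_rate]
        if self.substitution_profile is not None:
            rates += list(self.substitution_profile)
        for r in rates:
            if not 0.0 <= r <= 0.1:
                raise ValueError("error rates must be in [0, 0.1]")

    @property
    def is_error_free(self) -> bool:
        sub_free = (self.substitution_rate == 0
                    if self.substitution_profile is None
                    else not any(self.substitution_profile))
        return sub_free and self.insertion_rate == 0 \
            and self.deletion_rate == 0

    def position_sub_rates(self, read_length: int) -> np.ndarray:
        if self.substitution_profile is not None:
            begin, middle, end = self.substitution_profile
            if read_length == 1:
                return np.array([middle])
            x = np.linspace(0.0, 1.0, read_length)
            return np.interp(x, [0.0, 0.5, 1.0], [begin, middle, end])
        if self.substitution_rate == 0:
            return np.zeros(read_length)
        start = 2 * self.substitution_rate / (1 + self.substitution_ramp)
        end = start * self.substitution_ramp
        if read_length == 1:
            return np.array([self.substitution_rate])
        return np.linspace(start, end, read_length)


ERROR_FREE = ErrorModel(0.0, 1.0, 0.0, 0.0)
DEFAULT_ILLUMINA = ErrorModel(substitution_profile=(0.002, 0.004, 0.012),
                              insertion_rate=0.001, deletion_rate=0.001)


@dataclass(frozen=True)
class CoverageSpec:
    """Target mean fold-coverage, NB dispersion (size) and read length."""

    mean_coverage: float
    read_length: int
    dispersion: float = math.inf  # NB size parameter r; inf = Poisson

    def __post_init__(self):
        if self.mean_coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not (self.dispersion > 0):
            raise ValueError("dispersion r must be positive (or inf)")


class ReadSet:
    """A batch of reads as a padded uint8 matrix plus names and lengths."""

    def __init__(self, names: list[str], matrix: np.ndarray, lengths: np.ndarray):
        self.names = names
        self.matrix = matrix
        self.lengths = np.asarray(lengths, dtype=np.int32)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def width(self) -> int:
        return self.matrix.shape[1] if len(self.names) else 0

    def mean_length(self) -> float:
        return float(self.lengths.mean()) if len(self.names) else 0.0

    def sequence(self, i: int) -> str:
        return decode(self.matrix[i, :self.lengths[i]])

    def iter_reads(self) -> Iterator[tuple[str, str]]:
        for i in range(len(self.names)):
            yield self.names[i], self.sequence(i)

    @classmethod
    def from_strings(cls, reads: Iterable[tuple[str, str]]) -> "ReadSet":
        names, seqs = [], []
        for name, seq in reads:
            names.append(name)
            seqs.append(seq)
        if not names:
            return cls([], np.zeros((0, 0), dtype=np.uint8), np.zeros(0))
        width = max(len(s) for s in seqs)
        matrix = np.full((len(seqs), width), N_CODE, dtype=np.uint8)
        lengths = np.zeros(len(seqs), dtype=np.int32)
        for i, s in enumerate(seqs):
            matrix[i, :len(s)] = encode(s)
            lengths[i] = len(s)
        return cls(names, matrix, lengths)

    @classmethod
    def concat(cls, sets: list["ReadSet"]) -> "ReadSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return cls([], np.zeros((0, 0), dtype=np.uint8), np.zeros(0))
        width = max(s.width for s in sets)
        mats = []
        for s in sets:
            if s.width < width:
                pad = np.full((len(s), width - s.width), N_CODE, dtype=np.uint8)
                mats.append(np.hstack([s.matrix, pad]))
            else:
                mats.append(s.matrix)
        names = [n for s in sets for n in s.names]
        return cls(names, np.vstack(mats),
                   np.concatenate([s.lengths for s in sets]))

    def relabeled(self, src: str) -> "ReadSet":
        """Replace the source field of every read name (for mixture bookkeeping)."""
        names = [f"{src}|" + n.split("|", 1)[1] for n in self.names]
        return ReadSet(names, self.matrix, self.lengths)


def _resolve_sequence(genome) -> Genome:
    return genome.genome if isinstance(genome, VariantGenome) else genome


def tiling_reads(genome, read_length: int, src: Optional[str] = None) -> ReadSet:
    """One error-free read per start position per strand.

    On a circular genome every position is covered exactly ``2*read_length``
    fold; a linear genome has reads only at fully contained windows, so edge
    coverage tapers.
    """
    g = _resolve_sequence(genome)
    n = len(g)
    if read_length > n:
        raise ValueError("read length exceeds genome length")
    src = src or g.id
    enc = g.encoded()
    if g.is_circular:
        ext = np.concatenate([enc, enc[:read_length]])
        starts = np.arange(n)
    else:
        ext = enc
        starts = np.arange(n - read_length + 1)
    fwd = ext[starts[:, None] + np.arange(read_length)[None, :]]
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    rev = np.ascontiguousarray(np.flip(comp[fwd], axis=1))
    matrix = np.vstack([fwd, rev])
    names = ([f"{src}|{p}|+|{i}" for i, p in enumerate(starts)]
             + [f"{src}|{p}|-|{i + len(starts)}" for i, p in enumerate(starts)])
    lengths = np.full(matrix.shape[0], read_length, dtype=np.int32)
    return ReadSet(names, matrix, lengths)


def _sample_starts(n: int, spec: CoverageSpec, circular: bool,
                   rng: np.random.Generator, block: int = 1000) -> np.ndarray:
    """Random read start positions realizing the coverage spec."""
    L = spec.read_length
    hi = n if circular else n - L + 1
    lam_total = spec.mean_coverage * hi / L
    if math.isinf(spec.dispersion):
        count = rng.poisson(lam_total)
        return rng.integers(0, hi, size=count)
    r = spec.dispersion
    nblocks = (hi + block - 1) // block
    weights = rng.gamma(shape=r, scale=1.0 / r, size=nblocks)
    block_sizes = np.full(nblocks, block)
    block_sizes[-1] = hi - block * (nblocks - 1)
    counts = rng.poisson(lam_total / hi * weights * block_sizes)
    starts = np.concatenate([
        rng.integers(0, bs, size=c) + b * block
        for b, (c, bs) in enumerate(zip(counts, block_sizes))]) if counts.sum() \
        else np.zeros(0, dtype=np.int64)
    return starts


def sample_reads(genome, spec: CoverageSpec, errors: ErrorModel = ERROR_FREE,
                 seed: int = 0, src: Optional[str] = None,
                 intensity_block: int = 1000) -> ReadSet:
    """Randomly sampled single-end reads at the requested coverage.

    Start positions are uniform (Poisson counts) or gamma-modulated (NB
    marginal coverage); strands are random; the error model is applied per
    base. Expected read count is ``C * G / L``.
    """
    g = _resolve_sequence(genome)
    n = len(g)
    L = spec.read_length
    if L > n:
        raise ValueError("read length exceeds genome length")
    src = src or g.id
    rng = np.random.default_rng(seed)
    starts = _sample_starts(n, spec, g.is_circular, rng,
                            block=intensity_block)
    count = len(starts)
    if count == 0:
        return ReadSet([], np.zeros((0, 0), dtype=np.uint8), np.zeros(0))
    strands = rng.integers(0, 2, size=count)  # 0='+', 1='-'
    enc = g.encoded()
    ext = np.concatenate([enc, enc[:L]]) if g.is_circular else enc
    matrix = ext[starts[:, None] + np.arange(L)[None, :]].copy()
    rev_rows = strands == 1
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    matrix[rev_rows] = np.flip(comp[matrix[rev_rows]], axis=1)
    lengths = np.full(count, L, dtype=np.int32)

    if not errors.is_error_free:
        sub_rates = errors.position_sub_rates(L)
        mask = rng.random(matrix.shape) < sub_rates[None, :]
        if mask.any():
            shifts = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
            matrix[mask] = (matrix[mask] + shifts) % 4
        indel_rate = errors.insertion_rate + errors.deletion_rate
        if indel_rate > 0:
            n_events = rng.binomial(L, indel_rate, size=count)
            for i in np.nonzero(n_events)[0]:
                seq = list(matrix[i, :lengths[i]])
                for _ in range(n_events[i]):
                    pos = int(rng.integers(0, len(seq)))
                    if rng.random() < errors.insertion_rate / indel_rate:
                        seq.insert(pos, int(rng.integers(0, 4)))
                    elif len(seq) > 1:
                        del seq[pos]
                if len(seq) > matrix.shape[1]:
                    pad = np.full((count, len(seq) - matrix.shape[1]),
                                  N_CODE, dtype=np.uint8)
                    matrix = np.hstack([matrix, pad])
                row = np.full(matrix.shape[1], N_CODE, dtype=np.uint8)
                row[:len(seq)] = seq
                matrix[i] = row
                lengths[i] = len(seq)

    strand_char = np.where(strands == 0, "+", "-")
    names = [f"{src}|{p}|{s}|{i}"
             for i, (p, s) in enumerate(zip(starts, strand_char))]
    return ReadSet(names, matrix, lengths)


def mix_samples(*read_sets: ReadSet) -> ReadSet:
    """Concatenate read pools; provenance stays in the read names."""
    return ReadSet.concat(list(read_sets))


def write_fastq(reads: ReadSet, path, quality: int = 35) -> None:
    q = chr(33 + quality)
    with open(path, "w") as fh:
        for i, name in enumerate(reads.names):
            seq = reads.sequence(i)
            fh.write(f"@{name}\n{seq}\n+\n{q * len(seq)}\n")


def read_fastq(path) -> ReadSet:
    with pysam.FastxFile(str(path)) as fh:
        return ReadSet.from_strings((e.name, e.sequence.upper()) for e in fh)
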
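"""End-to-end polymorphic junction calling.

``call_junctions`` runs the whole procedure on an in-memory read set and
reference genome: map all reads, seed candidate junctions from split reads,
reconstruct junction sequences and ambiguities, count spanning reads for
the variant and reference alternatives, estimate frequencies and classify
mutations. ``run_pipeline`` wraps it with file I/O for the CLI.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .genome import (Genome, MobileElementAnnotation, RepeatRegion,
                     find_exact_repeats, load_mobile_elements, read_fasta)
from .junctions import (CandidateJunction, SpanningPolicy,
                        call_polymorphic_junctions, compute_ambiguity,
                        count_spanning_reads, reconstruct_junction_sequence,
                        seed_candidates)
from .frequency import (JunctionEvidence, SVPrediction, build_evidence,
                        missing_coverage_intervals, predict_svs)
from .mapping import AlignmentTable, KmerIndex, MappingPolicy, map_reads_batch
from .simulate import ReadSet, read_fastq

__all__ = ["RunConfig", "CallResult", "call_junctions", "run_pipeline",
           "unique_coverage"]


@dataclass(frozen=True)
class RunConfig:
    """Caller parameters; the defaults are the algorithm's published ones
    (E=6 extension bases, at least 3 spanning reads, 2 split reads to seed
    a candidate)."""

    E: int = 6
    n_min: int = 3
    seed_min: int = 2
    k: int = 12
    min_repeat: int = 50
    fragment_size: int = 260
    mc_min_length: int = 50
    max_candidates: int = 5000
    L_bar_override: Optional[float] = None
    deletion_prone_anchors: tuple[int, ...] = ()
    seed: int = 0

    def spanning_policy(self) -> SpanningPolicy:
        return SpanningPolicy(E=self.E, n_min=self.n_min,
                              seed_min=self.seed_min,
                              max_candidates=self.max_candidates)


@dataclass
class CallResult:
    evidence: list[JunctionEvidence]
    predictions: list[SVPrediction]
    L_bar: float
    coverage: np.ndarray
    mc_intervals: list[tuple[int, int]]
    config: RunConfig
    genome_id: str

    @property
    def accepted(self) -> list[JunctionEvidence]:
        return [e for e in self.evidence if e.status == "accepted"]

    def accepted_keys(self) -> set[tuple[int, int, int, int]]:
        return {e.junction.key() for e in self.accepted}

    def evidence_table(self) -> pd.DataFrame:
        rows = []
        for e in self.evidence:
            s1, s2 = e.sides
            rows.append({
                "side_1_pos": s1.ref_position + 1,
                "side_1_dir": "<" if s1.continuation == -1 else ">",
                "side_1_repeat": int(s1.in_repeat),
                "side_2_pos": s2.ref_position + 1,
                "side_2_dir": "<" if s2.continuation == -1 else ">",
                "side_2_repeat": int(s2.in_repeat),
                "A": e.A,
                "split_reads": e.junction.supporting_split_reads,
                "n_V": e.n_V,
                "n_R": ",".join(str(n) for n in e.n_R) or ".",
                "L_bar": e.L_bar,
                "f_V": round(e.f_V, 4),
                "f_R": ",".join(f"{f:.4f}" for f in e.f_R) or ".",
                "frequency": (round(e.F_V, 4) if e.F_V is not None else "."),
                "status": e.status,
                "reject_reason": e.reject_reason or ".",
            })
        return pd.DataFrame(rows)

    def write_evidence_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# svjc {_version} junction evidence; L_bar="
                     f"{self.L_bar:.2f} E={self.config.E} "
                     f"n_min={self.config.n_min} seed={self.config.seed}\n")
            self.evidence_table().to_csv(fh, sep="\t", index=False)

    def write_genomediff(self, path) -> None:
        """GenomeDiff-flavored output: mutation lines then JC/MC evidence."""
        lines = ["#=GENOME_DIFF\t1.0",
                 f"#=CREATED_BY\tsvjc {_version}",
                 f"#=PARAMETERS\tE={self.config.E} n_min={self.config.n_min} "
                 f"seed_min={self.config.seed_min} L_bar={self.L_bar:.2f} "
                 f"seed={self.config.seed}"]
        counter = 1
        jc_ids: dict[int, int] = {}
        evid_lines = []
        for i, e in enumerate(self.evidence):
            s1, s2 = e.sides
            jc_ids[i] = counter + 1000
            freq = f"{e.F_V:.4f}" if e.F_V is not None else "NA"
            evid_lines.append(
                f"JC\t{jc_ids[i]}\t.\t{self.genome_id}\t"
                f"{s1.ref_position + 1}\t{-s1.continuation}\t"
                f"{self.genome_id}\t{s2.ref_position + 1}\t"
                f"{s2.continuation}\t{e.A}\t"
                f"frequency={freq}\tn_V={e.n_V}\tstatus={e.status}")
        ev_index = {id(e): i for i, e in enumerate(self.evidence)}
        for p in self.predictions:
            refs = ",".join(str(jc_ids[ev_index[id(e)]]) for e in p.evidence
                            if id(e) in ev_index)
            freq = f"{p.frequency:.4f}" if p.frequency is not None else "NA"
            if p.kind == "mobile_element_insertion":
                lines.append(
                    f"MOB\t{counter}\t{refs}\t{self.genome_id}\t"
                    f"{p.interval[0]}\t{p.element_family}\t1\t"
                    f"{p.target_site_duplication}\tfrequency={freq}")
            elif p.kind in ("deletion", "small_indel"):
                size = p.interval[1] - p.interval[0] + 1
                lines.append(
                    f"DEL\t{counter}\t{refs}\t{self.genome_id}\t"
                    f"{p.interval[0]}\t{size}\tfrequency={freq}")
            else:
                lines.append(
                    f"UN\t{counter}\t{refs}\t{self.genome_id}\t"
                    f"{p.interval[0]}\t{p.interval[1]}\tkind={p.kind}\t"
                    f"frequency={freq}")
            counter += 1
        for lo, hi in self.mc_intervals:
            lines.append(f"MC\t{counter + 2000}\t.\t{self.genome_id}\t"
                         f"{lo + 1}\t{hi}\t0\t0")
        with open(path, "w") as fh:
            fh.write("\n".join(lines + evid_lines) + "\n")


def unique_coverage(table: AlignmentTable, reads: ReadSet, n: int) -> np.ndarray:
    """Per-position read-depth from uniquely placed reads."""
    if len(table) == 0:
        return np.zeros(n, dtype=np.int64)
    placements = np.bincount(table.read, minlength=len(reads))
    rows = np.nonzero(placements[table.read] == 1)[0]
    diff = np.zeros(n + 1, dtype=np.int64)
    start = table.ref_start[rows] % n
    end = start + (table.ref_end[rows] - table.ref_start[rows])
    wrap = end > n  # circular reads cover [start, n) plus [0, end - n)
    np.add.at(diff, start, 1)
    np.add.at(diff, np.minimum(end, n), -1)
    if wrap.any():
        diff[0] += int(wrap.sum())
        np.add.at(diff, end[wrap] - n, -1)
    return np.cumsum(diff[:n])


def _repeat_flag_masks(genome: Genome, repeats: Sequence[RepeatRegion],
                       annotations: Sequence[MobileElementAnnotation]
                       ) -> np.ndarray:
    mask = np.zeros(len(genome), dtype=bool)
    for r in repeats:
        mask[r.start:r.end] = True
    for ann in annotations:
        for s, e, _ in ann.copies:
            mask[s:e] = True
    return mask


def call_junctions(reads: ReadSet, genome: Genome,
                   config: RunConfig = RunConfig(),
                   repeats: Optional[Sequence[RepeatRegion]] = None,
                   annotations: Sequence[MobileElementAnnotation] = (),
                   ) -> CallResult:
    """Run the full polymorphic junction caller on one sample."""
    if len(reads) == 0:
        raise ValueError("no reads supplied")
    policy = config.spanning_policy()
    mapping_policy = MappingPolicy()
    L_bar = config.L_bar_override or reads.mean_length()

    index = KmerIndex(genome, k=config.k)
    table = map_reads_batch(reads, index, mapping_policy)

    if repeats is None:
        repeats = find_exact_repeats(genome, config.min_repeat)
    repeat_mask = _repeat_flag_masks(genome, repeats, annotations)

    candidates = seed_candidates(table, reads, policy, genome=genome)
    flank = int(np.ceil(reads.lengths.max())) if len(reads) else 50
    prepared = []
    for cand in candidates:
        cand = reconstruct_junction_sequence(cand, genome, flank)
        cand = compute_ambiguity(cand, genome)
        s1 = dataclasses.replace(
            cand.side_1, in_repeat=bool(repeat_mask[cand.side_1.ref_position]))
        s2 = dataclasses.replace(
            cand.side_2, in_repeat=bool(repeat_mask[cand.side_2.ref_position]))
        cand.side_1, cand.side_2 = s1, s2
        prepared.append(cand)

    def side_informative(cand: CandidateJunction, which: int) -> bool:
        side = cand.side_1 if which == 1 else cand.side_2
        return not side.in_repeat

    counts = count_spanning_reads(reads, prepared, table, index, policy,
                                  mapping_policy,
                                  side_informative=side_informative)
    counts = call_polymorphic_junctions(counts, policy)
    evidence = [build_evidence(c, L_bar, policy) for c in counts]

    coverage = unique_coverage(table, reads, len(genome))
    mc = missing_coverage_intervals(coverage, config.mc_min_length)
    predictions = predict_svs(
        [e for e in evidence], L_bar, annotations, mc,
        config.deletion_prone_anchors, config.fragment_size)
    return CallResult(evidence=evidence, predictions=predictions,
                      L_bar=L_bar, coverage=coverage, mc_intervals=mc,
                      config=config, genome_id=genome.id)


def run_pipeline(reference_path, reads_paths, output_dir,
                 config: RunConfig = RunConfig(),
                 mobile_elements_path=None,
                 topology: str = "circular") -> CallResult:
    """File-based pipeline entry point used by the CLI."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(reference_path, topology=topology)
    pools = [read_fastq(p) for p in reads_paths]
    reads = ReadSet.concat(pools)
    if len(reads) == 0:
        raise ValueError("no reads found in input FASTQ files")
    annotations = (load_mobile_elements(mobile_elements_path)
                   if mobile_elements_path else ())
    result = call_junctions(reads, genome, config=config,
                            annotations=annotations)
    result.write_evidence_table(out / "junction_evidence.tsv")
    result.write_genomediff(out / "predictions.gd")
    np.savetxt(out / "coverage_histogram.tsv",
               np.stack([np.arange(result.coverage.max() + 1),
                         np.bincount(result.coverage)], axis=1),
               fmt="%d", delimiter="\t",
               header="coverage\tpositions", comments="")
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"svjc {_version}\nreference={reference_path}\n")
        fh.write(f"reads={','.join(str(p) for p in reads_paths)}\n")
        fh.write(f"n_reads={len(reads)}\nL_bar={result.L_bar:.3f}\n")
        for f, v in dataclasses.asdict(config).items():
            fh.write(f"{f}={v}\n")
        fh.write(f"accepted_junctions={len(result.accepted)}\n")
    return result
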
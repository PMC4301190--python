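# Methods

This note documents the models and procedures implemented in `svjc`, the
defaults and why they were chosen, what the synthetic data emulate (and do
not), and the numerical decisions a maintainer would want written down.

## Junction calling

**Mapping contract.** The junction algorithm needs every maximal local
alignment of at least `m = ceil(6 + 0.2·L)` bases reported, including
secondary placements in repeats, on both strands. The internal engine is an
exact k-mer index (k = 12) with vectorized ungapped extension: the maximal
scoring segment along each seeded diagonal under match +1 / mismatch −3,
keeping alignments with at least `m` matched bases, capped at 16 placements
per read (ranked by matched bases, ties broken by coordinate — never
randomly). Reads that match the reference perfectly over their full length
take a fast anchored path that reports every perfect placement and skips
the search for additional partial ones; such reads cannot contribute to
junction evidence, so pipeline results are unaffected. A consequence of
ungapped extension is that an indel inside a read splits its alignment in
two; see the `min_indel_span` rule below. SAM ingestion (primary +
supplementary records, soft clips defining the read interval) is available
as an alternative front end. k = 12 requires `m ≥ 12`, i.e. reads of ~30
bases or more with the default `m`; shorter toy reads need a smaller k.

**Seeding.** A read seeds a candidate junction when two of its alignments
are disjoint on the reference, cover the read jointly (reaching both ends
within 4 bases — slack for substitutions near read ends), overlap on the
read by at most 12 bases (breakpoint micro-homology), and have no gap
between them. At least 2 distinct reads (`seed_min`) are required. The
candidate list is capped at 5,000 by split-read support to bound memory.

**Canonical breakpoint placement.** Within a micro-homology window the
breakpoint can be placed at A + 1 equivalent positions, and reads from the
two strands naturally report opposite ends of the window. Every derived
junction is slid to the leftmost placement (in the ordered junction's
reading direction) against the genome before merging, so all reads of one
junction agree on a single key; the ambiguity count `A` is then the length
of the forward homology at the canonical placement (plus any backward
component for non-canonical input). The planted-truth generator uses the
same canonicalization, so evaluation is by exact key equality.

**Spanning counts.** The junction sequence is reconstructed with one read
length of flank on each side (orientation-aware, reverse-complementing
sides that continue toward higher coordinates on the left or lower on the
right). Reads lacking a perfect full-length reference placement are
re-mapped against the concatenated junction sequences. A read counts for
`n_V` when its junction alignment covers the window of `2E + A` bases
around the breakpoint with zero mismatches inside it and has strictly more
matched bases than the read's best reference alignment — ties go to the
reference, the conservative choice. Reference-side counts `n_R` apply the
identical window rule at each side's original context (the window is the
image of the junction window under the side's coordinate map), so the
numerator and denominator of the frequency are symmetric. Each read counts
at most once per junction; a side inside a repeat or annotated mobile
element is skipped (uninformative). A side whose reference window would
run past a linear contig end is dropped (N_R decreases) and the junction
flagged.

**`min_indel_span` = 2.** Split pairs whose sides imply an apparent
deletion shorter than 2 bases never seed candidates. Junction evidence is
only used to predict indels of ≥ 2 bases; single-base events belong to a
point-mutation caller, and under an ungapped mapper every 1-bp deletion
*sequencing error* would otherwise become a split pair (three reads sharing
an error position at high coverage would fake a junction). With this rule
the simulated error-model runs produce zero false junctions at 100-fold
coverage.

## Frequency estimation

Counts are normalized by the target size `L̄ − (2E + A) + 1`, with L̄ the
mean length of all input reads computed once per run and recorded in output
headers. The junction frequency is `mean(f_V) / (mean(f_R) + mean(f_V))`.
Mobile-element insertions are predicted from junction pairs whose genomic
sides lie within 10 bases pointing away from each other (possibly
overlapping by the target-site duplication) and whose element sides hit
opposite boundaries of one family; their counts are pooled (N_V = 2,
N_R = 2). Junctions estimated at `L̄ ≤ 2E + A` are flagged unevaluable
rather than given a frequency.

Classification is deliberately conservative: both-sides-genomic junctions
become small indels only when the implied span is below L̄; a larger span
is promoted to a consensus (frequency 1.0) deletion only when the spanned
region shows missing coverage — a maximal interval of ≥ 50 bp with zero
uniquely-mapped read depth covering at least half the span. Singleton
junctions touching an IS boundary are reported indeterminately as
"IS insertion or IS-mediated deletion" with the junction's frequency,
except when the boundary matches a user-supplied deletion-prone anchor
(a generalization of loci like the *E. coli* ribose operon, where an
adjacent IS element mediates frequent deletions), in which case they are
promoted to deletions. Everything else stays "unassigned" for manual
review. Outward-oriented same-locus junctions with spans between L̄ and
the configured DNA fragment size (default 260 bp) are flagged as suspected
library-preparation chimeras; both-sides-in-repeat junctions are flagged
unestimable. Flagged items are retained in output, never dropped.

Nested deletions sharing an anchored endpoint (within 5 bp) have the inner
frequency multiplied by one minus the summed raw frequencies of all
strictly containing deletions, clamping at zero with a warning if the sum
exceeds one. Frequencies are reported to 4 decimals; no confidence
intervals are attached.

## Sensitivity model

Per breakpoint-overlapping read, the twice-mapped probability is
`0.6 − 11/L` (both ends ≥ 6 + 0.2L) and the spanning probability
`1 − (2E−1)/L`, neglecting A, which is typically 0–3 and shrinks the
window only slightly. Twice-mapped reads are treated as a subset of
spanning reads — on error-free data a read with ≥ 6 + 0.2L exactly
matching bases per side necessarily satisfies the E = 6 perfect-extension
rule — so given k overlapping reads, X ~ Binomial(k, p_twice) and the
spanning-only remainder is Bernoulli-thinned from k − X with probability
`(p_span − p_twice)/(1 − p_twice)`. Detection requires X ≥ 2 and
X + Y ≥ 3. k follows Poisson(C) or NB(mean C, size r); the sum over k is
truncated at the 1 − 10⁻¹² quantile. Coverage inversion uses Brent's
method to |ΔC| < 0.01 fold; frequency thresholds divide the required
variant coverage by the sample's total coverage. The model is verified in
the test suite against a direct Monte-Carlo simulation of the same
Bernoulli process (10⁶ replicates on a 12-point grid, 3-SE agreement).

The confidence band on an observed detected fraction uses exact
(Clopper–Pearson) binomial limits at the model probability and the number
of planted junctions.

**Coverage fitting.** The NB fit to a read-depth histogram drops bins below
the 2.5th and above the 97.5th percentile of the raw distribution (deleted
regions and collapsed repeats otherwise dominate the tails) and maximizes
the likelihood renormalized over the retained support (Nelder–Mead on
log-mean, log-r). A fitted r above 10⁶ is reported as Poisson. Parameter
recovery (r = 5 recovered within [3.5, 7] from 10⁶ positions) is part of
the test suite.

## Synthetic data

The generators define the validation conditions:

* **Genomes** are uniform-random ACGT, circular by default so tiling
  coverage is exactly uniform. Planted deletions (default 100 × 1,000 bp)
  are uniform over admissible positions: the deleted interval plus one
  read length of flank contains no base of an exact repeat ≥ 50 bp
  (repeats found by maximal-exact-match enumeration, forward strand by
  default with a both-strands option), stays one flank clear of the
  origin, and keeps two flanks between neighboring deletions so every
  junction context is unmutated for a full read length.
* **Tiling reads**: one error-free read per position per strand, giving
  exactly 2L-fold coverage; a 1:1 variant/reference mixture puts every
  planted junction at exactly 50%.
* **Sampled reads**: single-end, uniform starts with Poisson totals, or —
  for finite NB size r — starts modulated by a block-constant gamma
  intensity field (shape r, mean 1, block 1,000 bp by default), which
  makes the marginal per-position depth NB(C, r). Pairs from real
  protocols are treated as independent reads throughout the package.
* **Error model**: substitutions follow a piecewise-linear per-cycle
  profile rising from 0.2% through 0.4% mid-read to 1.2% at the 3′ end,
  with insertion and deletion probabilities of 0.1% per base — the
  long-standing defaults of the Mason Illumina simulator, which this
  generator emulates. A two-parameter mean + ramp form is available for
  custom models. Qualities are constant Phred 35 placeholders.

What the synthetic data do **not** emulate: real base-quality
distributions (so quality-aware trimming and alignment are untested), GC-
or context-dependent coverage bias beyond the gamma field, PCR/optical
duplicates, chimeric library artifacts, paired-end insert-size signal, and
real repeat families at genomic density. Passing the synthetic benchmarks
therefore demonstrates the correctness of the junction arithmetic and the
calibration of the sensitivity model under the stated sampling assumptions,
not end-to-end performance on a particular instrument's data.

## Benchmark scales and determinism

The validation experiments run at desk scale: tiling exactness on a 1-Mb
genome (tests use 0.5 Mb) with 100 planted deletions, and the stochastic
sensitivity experiment on a 0.5-Mb genome (tests 0.4 Mb) with 100
deletions, 3 replicates, 4-fold variant + 96-fold reference coverage,
50-base reads. Detection of a junction depends only on local read
sampling, so these scales measure the same quantities as a full-size
bacterial genome while keeping each run in the minutes range on one CPU.
At 4-fold variant coverage the analytic model puts detection at 39.8%
(error-free); individual 3-replicate means scatter around that with a
standard error near 3 percentage points. All randomness flows from
explicit integer seeds; two runs with the same configuration are
byte-identical, and read names carry `source|position|strand|serial`
provenance so realized per-junction coverage can be recomputed exactly.

## Known limitations

* No gapped alignment: reads with indels contribute reduced evidence, and
  indel-containing spanning reads are lost (reflected in the error-model
  sensitivity, ~31% vs ~40% error-free at 4-fold variant coverage).
* Junctions whose sides both fall in repeats are detected but carry no
  frequency; inversions/translocations are reported unassigned, not
  classified.
* Read-depth (duplication/amplification) evidence, GC-bias correction of
  frequencies, and confidence intervals on frequencies are out of scope.
* The missing-coverage definition is minimal (zero unique depth over
  ≥ 50 bp); it is meant for consensus-deletion support on simulated data,
  not as a full coverage-evidence module.
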
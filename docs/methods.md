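# Methods

## Intron regions

The unit of analysis is the *intron region*: a maximal genomic interval
that lies inside at least one transcript's span and inside no exon of any
isoform of the gene. Because a base inside a transcript's span that is not
exonic in any isoform is intronic in every isoform spanning it, the
interval-arithmetic implementation (span union minus exon union, per gene)
is exactly the base-wise "intronic in all spanning isoforms" definition;
the test suite verifies this equivalence against a base-wise brute-force
oracle on random annotations.

Design choices where the definition is open:

* Regions are derived per gene from that gene's own transcripts. Exons of a
  different gene overlapping the locus do **not** subtract from a host
  gene's intron region — genes transcribed from within another gene's
  intron are a downstream *classification* outcome and must survive
  derivation. Same-strand overlapping genes are processed independently
  with a logged warning; opposite-strand overlap is naturally independent
  because all counting is strand-matched (strand-specific libraries).
* No minimum region length is imposed at derivation; length filtering is a
  counting/classification concern.
* Region ids are `gene_id:E<1-based genomic index>` and are stable across
  modules.

Coordinates are 0-based half-open internally; GTF is read 1-based
inclusive; BED is 0-based half-open.

## Read classes and counting

All counting is strand-matched after reorienting reads to the fragment
strand (sample-sheet `strandedness`: `forward` or `reverse`). Alignments
are filtered to primary records with mapping quality ≥ 10 (inclusive).

* **Body**: any aligned block overlaps the region by ≥ 1 nt. Gaps (`N`,
  `D`) are not footprint. A read may count in several regions but at most
  once per region; density = body reads / region length.
* **EI / IE**: a single gapless block covers at least one base on each side
  of the exon→intron (EI) or intron→exon (IE) boundary. On the minus
  strand the EI boundary is at the higher genomic coordinate. The 50-nt
  windows (25 exon + 25 intron) locate the boundary; the default
  *straddle* test is the strictest reading of "reads spanning the unspliced
  splice sites". A `boundary_mode = overlap` switch instead counts any
  block overlapping the 50-nt window, for sensitivity analyses.
* **EE**: a split read whose leftmost and rightmost aligned bases fall in
  the 50-nt exonic flanks (12 nt for short-read libraries with ≥ 24-nt
  reads) and one of whose inter-block gaps equals the region exactly — the
  spliced junction as a splice-aware aligner reports it. No gap tolerance:
  annotated junctions are emitted exactly. EE counts are reported but do
  not gate classification.
* Paired-end mates count as independent alignments (no fragment dedup).

## Classification

Thresholds (all defaults in `classify.Thresholds`, mirrored in the YAML
config):

| parameter | default | units / operator |
|---|---|---|
| per-replicate body floor | 1 read | inclusive ≥ |
| mean body density | 0.005 reads/nt | strict > |
| EI/IE pseudocount | 0.1 reads | added per replicate |
| EI/IE high threshold | 1.0 | strict > |
| ribosome occupancy | 5 reads/replicate | inclusive ≥, mean |
| PAS probability | 0.999 | inclusive ≥ |
| enrichment pseudocount | 1 read / region length | both compartments |
| tail-gap minimum | 15 nt | inclusive ≥ |

Strict-vs-inclusive operators mirror the printed rules they implement.
Mean EI/IE is computed as `(sum(counts) + n·0.1)/n` rather than averaging
per-replicate pseudocounted values: the two are algebraically identical but
the former keeps the exact-threshold case (mean 1.0) float-exact, so a mean
exactly at the threshold falls on the low side as specified. Quadrants are
assigned from projection-compartment EI/IE only; whole-cell values are
computed and reported but not used for assignment.

Low/low (quadrant iv) resolution applies PAS evidence first, then ribosome
occupancy, then falls through to free-intron candidate. Regions where both
kinds of evidence are present are resolved as PAS (the order follows the
narrative in which the evidence layers were applied) and flagged
`dual_evidence`. A PAS on the first or last intronic base is treated as a
boundary (annotated 3′ end) and not intronic. Regions detectable in
projection but not whole cell are flagged `projection_only`, never dropped.
Enrichment uses log base 2 (recorded in output); transcript-level
differential-expression thresholds (q < 0.01, fold change > 1.5) are
carried as config constants only — the estimator itself is out of scope.

## Circularly permuted reads and branchpoints

Search is restricted to free-intron-candidate regions by default (a
`genome_wide_circ` flag lifts this); each region is extended by the anchor
length and indexed by unique 20-mers in transcript orientation. For each
unaligned read, the first and last 20 bases must each hit exactly one
position, in one region, on one strand — multi-hit anchors are rejected —
and in *permuted* order: the read-5′ anchor downstream of the read-3′
anchor. Breakpoint refinement slides the split over the unanchored middle,
scoring matches of the left part (extended right from the read-start
anchor, ending at the putative branchpoint/donor) plus the right part
(extended left from the read-end anchor, starting at the putative
acceptor); the best split must leave ≤ 2 mismatches. Ties are broken by
(1) acceptor equal to the annotated intron start, then (2) smallest
distance to the 3′SS, then smallest split — the first rule resolves the
one-base ambiguity created when a branchpoint sequencing error happens to
match the base preceding the acceptor, which otherwise produces a minority
junction shifted by one base (visible as low-support secondary junctions
in the output, ranked below the modal one). Junction mismatches are counted
within ±5 nt of the donor (the window is configurable; only its order of
magnitude matters for the diagnostic).

Per region, junctions are aggregated by (donor, acceptor) and ranked by
support; the branchpoint base is the strand-corrected genome base at the
donor, with a `canonical` flag for adenosine. The code deliberately does
not decide whether the stable species is a tailed lariat or a 2′–5′
circle — it reports the evidence (junction, support, tail gap) only.

**Tail gap.** The detector measures the zero-coverage run ending at the
transcript-orientation 3′ terminus and flags it when ≥ 15 nt (below the
20–30 nt the phenomenon produces, so edge effects do not mask true tails)
*and* the rest of the region has mean coverage ≥ 1 (entirely silent regions
are not flagged). Limitation: any 3′-truncated coverage profile triggers
the flag — e.g. a host intron whose snoRNA sits in the 5′ half — so the
flag is evidence to be read together with the junction call, not a
classifier by itself.

**Consensus matrices** are built around three anchors (5′SS offset window
−3..+8, branchpoint −8..+2, 3′SS −10..+3, transcript orientation) from
strand-corrected genomic sequence; off-chromosome positions pad with N and
N is excluded from counts. Information content per column is
`2 + Σ_b f_b log2 f_b` bits (0·log 0 = 0), so identical inputs give 2 bits
and uniform composition 0 bits.

## Conservation

Windows of 50 nt at 10-nt steps are tiled from the region start, fully
inside the region; a trailing partial window is dropped (deviation from
`bedtools makewindows`, which emits a short last window — dropping keeps
the median robust to a half-filled window), except that a region shorter
than one window becomes a single whole-region window. Window means average
covered bases only (uncovered bases are missing, as in
bigWigAverageOverBed); fully uncovered windows are dropped, and a region
with no covered window reports a missing median. Classes are compared by
empirical CDFs of region medians; no statistical test is computed. Tracks
are read from bedGraph (or bigWig when pyBigWig is available); fixed- and
variable-step wiggle are not parsed.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 5 biological replicates
per compartment, 100-nt reads, 300-nt exons, 400-nt introns, 100 fragments
per species per replicate per compartment (Poisson replicate noise), GT/AG
intron ends, and for free circular introns a branchpoint C preceded by C
(the CC context) 25 nt from the 3′SS, a 25-nt uncovered 3′ tail, a 2′–5′
read-through rate of 0.05, a branchpoint mismatch probability of 0.3 in
permuted reads, and a 4:1 projection:whole-cell abundance ratio. Ribosome
profiling uses 3 replicates of 30-nt reads at Poisson mean 10 on cassette
exons (comfortably above the ≥ 5 floor without sitting on the threshold).
Locus sizes keep every scenario feature (alternative splice-site
extensions, intronic subgene, snoRNA, cassette exon, circle body ≥ read
length) geometrically feasible at desk scale.

Reads are emitted directly as ground-truth alignments; only permuted reads
go to FASTQ, so the anchor search is exercised on raw sequence while
counting logic is tested independently of any third-party aligner.
Sequencing error outside the branchpoint is off by default. Not emulated:
coverage biases (GC, positional), quality scores, rRNA/mitochondrial
contamination, multimapping, or paired-end fragment structure (mates are
single alignments). Passing tests therefore demonstrate the correctness of
the derivation/counting/classification/branchpoint logic under clean
alignments — not robustness to alignment artifacts in real libraries.

## Numerical and degenerate-input choices

* Detectability/quadrant comparisons are strict `>` for "high" and
  inclusive `≥` for floors, exactly as tabulated above; permuting replicate
  order changes nothing.
* Windows clipped at chromosome bounds are flagged, not dropped; regions
  shorter than 50 nt get overlapping EI/IE windows and an `overlapping`
  flag.
* A gene whose transcripts are all single-exon yields zero regions, not an
  error. An empty sample sheet fails validation before any stage runs.
* All randomness in the simulator flows from one integer seed; identical
  seeds give byte-identical FASTA/GTF/SAM/FASTQ/BED outputs, and pipeline
  reruns with the same config and seed give byte-identical tables (the
  manifest carries the only timestamp).

## Problem sizes used by the test and acceptance runs

Oracle equivalence uses 200 random annotations (≤ 50 genes, ≤ 5 isoforms,
≤ 10 exons each) and 10,000 alignments against 100 regions; branchpoint
recovery uses 200 simulated free-circle loci (half on each strand) at
expression 200 and read-through 0.05, evaluated on loci with ≥ 3 permuted
reads; tail-gap rates use 10 free-circle and 10 retained loci; conservation
windowing uses 100 random regions over a sparse track. These sizes give
stable rates (hundreds to thousands of Bernoulli trials per quantity)
while the whole suite runs in seconds.
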
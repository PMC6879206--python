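"""Synthetic reference and compartment-labelled read simulator.

Generates a toy genome, an annotation of canonical isoforms, and
alignment-level sequencing data with a known truth table, so every pipeline
stage is testable without external downloads. Each scenario builds one
two-exon gene whose single intron region exercises one phenomenon:

* SPLICED_ONLY — fully spliced mRNA, no intronic signal;
* RETAINED_INTRON — unspliced transcripts in both compartments;
* DETAINED_INTRON — unspliced transcripts in whole cell only (nuclear);
* FREE_CIRCULAR_INTRON — a stable excised intron covering the intron body
  in both compartments (projection-enriched), with an uncovered 3' tail, a
  C/G branchpoint preceded by C, and rare reverse-transcriptase
  read-through across the 2'-5' junction emitting circularly permuted
  reads (with branchpoint-base errors) to the unaligned FASTQ;
* INTRONIC_GENE_WITH_PAS — an independent same-strand gene inside the
  intron, with a confident intronic polyadenylation-site call;
* SNORNA_HOST — an intron-hosted snoRNA, whole-cell biased;
* CASSETTE_EXON — an unannotated cassette exon with ribosome occupancy;
* ALT_5SS / ALT_3SS / ALT_TSS / ALT_PAS — unannotated alternative events
  producing EI- or IE-boundary reads.

Reads are emitted directly as ground-truth alignments (SAM); only permuted
reads go to FASTQ, to exercise the anchor search itself. All randomness
derives from a single integer seed; the same seed gives byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .annotation import GenomeAnnotation, Interval, IntronRegion
from .circjunction import revcomp

EXON_LEN = 300
SPACER_LEN = 300
RIBO_READ_LEN = 30
N_JUNK_READS = 5           # unmappable decoys per FASTQ replicate
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class Scenario(str, Enum):
    SPLICED_ONLY = "SPLICED_ONLY"
    RETAINED_INTRON = "RETAINED_INTRON"
    DETAINED_INTRON = "DETAINED_INTRON"
    FREE_CIRCULAR_INTRON = "FREE_CIRCULAR_INTRON"
    INTRONIC_GENE_WITH_PAS = "INTRONIC_GENE_WITH_PAS"
    SNORNA_HOST = "SNORNA_HOST"
    CASSETTE_EXON = "CASSETTE_EXON"
    ALT_5SS = "ALT_5SS"
    ALT_3SS = "ALT_3SS"
    ALT_TSS = "ALT_TSS"
    ALT_PAS = "ALT_PAS"


@dataclass
class ScenarioSpec:
    """Study conditions for one simulated locus."""

    scenario: Scenario
    expression: int = 100          # fragments per compartment per replicate
    n_replicates: int = 5
    read_len: int = 100
    intron_len: int = 400
    bp_offset_from_3ss: int = 25   # branchpoint distance to the 3'SS
    bp_base: str = "C"
    readthrough_rate: float = 0.05
    bp_mismatch_prob: float = 0.3
    tail_len: int = 25             # uncovered nt at the intron 3' end
    strand: str = "+"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.scenario = Scenario(self.scenario)
        for rate in (self.readthrough_rate, self.bp_mismatch_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must be in [0,1], got {rate}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.bp_offset_from_3ss >= self.intron_len:
            raise ValueError("bp_offset_from_3ss must be < intron_len")
        if self.intron_len < 300:
            raise ValueError("intron_len must be >= 300 for scenario features")
        if self.scenario is Scenario.FREE_CIRCULAR_INTRON:
            b = self.intron_len - self.bp_offset_from_3ss
            if b - 1 < 2 or b + 1 > self.intron_len - 2:
                raise ValueError("branchpoint motif conflicts with splice-site "
                                 "motifs: intron too short for bp offset")
            if self.intron_len - self.tail_len < self.read_len:
                raise ValueError("intron too short: circle body shorter than read")
        if self.expression < 1:
            raise ValueError("expression must be >= 1")


@dataclass
class Locus:
    spec: ScenarioSpec
    gene_id: str
    chrom: str
    strand: str
    exonL: Interval                # genomic-left exon
    intron: Interval
    exonR: Interval

    @property
    def exon1(self) -> Interval:   # transcript 5' exon
        return self.exonL if self.strand == "+" else self.exonR

    @property
    def exon2(self) -> Interval:
        return self.exonR if self.strand == "+" else self.exonL

    @property
    def region_id(self) -> str:
        return f"{self.gene_id}:E1"

    @property
    def gstart(self) -> int:
        return self.exonL[0]

    @property
    def gend(self) -> int:
        return self.exonR[1]

    def intron_tx(self, a: int, b: int) -> Interval:
        """Genomic interval of intron-local transcript-orientation [a, b)."""
        s, e = self.intron
        if self.strand == "+":
            return (s + a, s + b)
        return (e - b, e - a)

    def intron_tx_pos(self, t: int) -> int:
        s, e = self.intron
        return s + t if self.strand == "+" else e - 1 - t

    def bp_genomic(self) -> int:
        b = self.spec.intron_len - self.spec.bp_offset_from_3ss
        return self.intron_tx_pos(b)


@dataclass
class Reference:
    genome_path: str
    gtf_path: str
    truth_path: str
    conservation_path: str
    chrom: str
    chrom_length: int
    loci: list[Locus]
    truth: pd.DataFrame
    genome_seq: str = ""

    def sequence(self) -> str:
        if not self.genome_seq:
            import pyfaidx
            fa = pyfaidx.Fasta(self.genome_path)
            self.genome_seq = str(fa[self.chrom][:]).upper()
        return self.genome_seq

    def regions(self) -> list[IntronRegion]:
        return [IntronRegion(region_id=lc.region_id, gene_id=lc.gene_id,
                             chrom=lc.chrom, strand=lc.strand,
                             start=lc.intron[0], end=lc.intron[1])
                for lc in self.loci]


@dataclass
class SimBundle:
    sample_sheet: str
    sam_paths: dict[tuple[str, int], str]
    fastq_path: str
    pas_bed: str
    ribo_sheet: str
    ribo_sam_paths: dict[int, str]


# ---------------------------------------------------------------------------
# truth


_TRUTH = {
    Scenario.SPLICED_ONLY: (False, False, "", ""),
    Scenario.RETAINED_INTRON: (True, True, "iii", "RETAINED"),
    Scenario.DETAINED_INTRON: (False, True, "", ""),
    Scenario.FREE_CIRCULAR_INTRON: (True, True, "iv", "FREE_INTRON_CANDIDATE"),
    Scenario.INTRONIC_GENE_WITH_PAS: (True, True, "iv", "INTRONIC_GENE_OR_ALT_TERMINAL"),
    Scenario.SNORNA_HOST: (True, True, "iv", "FREE_INTRON_CANDIDATE"),
    Scenario.CASSETTE_EXON: (True, True, "iv", "CASSETTE_EXON"),
    Scenario.ALT_5SS: (True, True, "i", "ALT_5SS_OR_ALT_PAS"),
    Scenario.ALT_PAS: (True, True, "i", "ALT_5SS_OR_ALT_PAS"),
    Scenario.ALT_3SS: (True, True, "ii", "ALT_3SS_OR_ALT_TSS"),
    Scenario.ALT_TSS: (True, True, "ii", "ALT_3SS_OR_ALT_TSS"),
}


def default_scenario_bundle(n_replicates: int = 5) -> list[ScenarioSpec]:
    """One spec per scenario — the standard end-to-end test bundle. A few
    loci sit on the minus strand to exercise strand correction."""
    minus = {Scenario.ALT_3SS, Scenario.SNORNA_HOST, Scenario.DETAINED_INTRON}
    return [ScenarioSpec(scenario=sc, n_replicates=n_replicates,
                         strand="-" if sc in minus else "+")
            for sc in Scenario]


def expected_truth(specs: Sequence[ScenarioSpec],
                   loci: Sequence[Locus] | None = None) -> pd.DataFrame:
    """Expected per-region outcome for a spec list. When loci are supplied
    (post reference build), genomic branchpoint coordinates are included."""
    rows = []
    for i, spec in enumerate(specs):
        gene_id = spec.gene_id or _default_gene_id(i, spec)
        lc = loci[i] if loci is not None else None
        det_p, det_w, quadrant, final = _TRUTH[spec.scenario]
        is_circ = spec.scenario is Scenario.FREE_CIRCULAR_INTRON
        rows.append({
            "gene_id": gene_id,
            "region_id": f"{gene_id}:E1",
            "scenario": spec.scenario.value,
            "strand": spec.strand,
            "detectable_projection": det_p,
            "detectable_wholecell": det_w,
            "quadrant": quadrant,
            "final_class": final if det_p else "NOT_DETECTED",
            "bp_pos": (lc.bp_genomic() if (is_circ and lc is not None) else -1),
            "bp_base": spec.bp_base if is_circ else "",
            "bp_dist_to_3ss": spec.bp_offset_from_3ss if is_circ else 0,
            "tail_len": spec.tail_len if is_circ else 0,
        })
    return pd.DataFrame(rows)


def _default_gene_id(i: int, spec: ScenarioSpec) -> str:
    return f"g{i + 1:03d}_{spec.scenario.value.lower()}"


# ---------------------------------------------------------------------------
# reference construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def build_reference(specs: Sequence[ScenarioSpec], seed: int,
                    outdir: Union[str, Path], chrom: str = "chrT") -> Reference:
    """Build FASTA + GTF + truth table + synthetic conservation track.

    Every intron begins GT and ends AG in transcript orientation; free
    circular introns additionally carry the branchpoint base (preceded by C,
    giving the CC context) at the configured offset from the 3'SS. The GTF
    annotates only the canonical two-exon isoform of each gene: the
    alternative events are deliberately unannotated, since the pipeline's
    job is to discover them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    loci: list[Locus] = []
    chunks: list[str] = []
    cursor = 0
    for i, spec in enumerate(specs):
        gene_id = spec.gene_id or _default_gene_id(i, spec)
        ilen = spec.intron_len
        exon1 = _random_seq(rng, EXON_LEN)
        exon2 = _random_seq(rng, EXON_LEN)
        intron = list(_random_seq(rng, ilen))
        intron[0:2] = "GT"
        intron[-2:] = "AG"
        if spec.scenario is Scenario.FREE_CIRCULAR_INTRON:
            b = ilen - spec.bp_offset_from_3ss
            intron[b] = spec.bp_base
            intron[b - 1] = "C"
        tlocus = exon1 + "".join(intron) + exon2
        glocus = tlocus if spec.strand == "+" else revcomp(tlocus)
        gstart = cursor
        chunks.append(glocus)
        cursor += len(glocus)
        chunks.append(_random_seq(rng, SPACER_LEN))
        cursor += SPACER_LEN
        loci.append(Locus(
            spec=spec, gene_id=gene_id, chrom=chrom, strand=spec.strand,
            exonL=(gstart, gstart + EXON_LEN),
            intron=(gstart + EXON_LEN, gstart + EXON_LEN + ilen),
            exonR=(gstart + EXON_LEN + ilen, gstart + 2 * EXON_LEN + ilen),
        ))
    genome = "".join(chunks)

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 60):
            fh.write(genome[i:i + 60] + "\n")

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for lc in loci:
            tx = f"{lc.gene_id}.t1"
            for exon in (lc.exonL, lc.exonR):
                fh.write("\t".join([
                    chrom, "synthetic", "exon",
                    str(exon[0] + 1), str(exon[1]), ".", lc.strand, ".",
                    f'gene_id "{lc.gene_id}"; transcript_id "{tx}";',
                ]) + "\n")

    truth = expected_truth(specs, loci)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    cons_path = outdir / "conservation.bedgraph"
    _write_conservation(cons_path, chrom, len(genome), loci, rng)

    return Reference(
        genome_path=str(genome_path), gtf_path=str(gtf_path),
        truth_path=str(truth_path), conservation_path=str(cons_path),
        chrom=chrom, chrom_length=len(genome), loci=loci,
        truth=truth, genome_seq=genome,
    )


def _write_conservation(path: Path, chrom: str, length: int,
                        loci: Sequence[Locus], rng: np.random.Generator) -> None:
    # 10-nt bins: exonic bases conserved (~1.8), intronic/intergenic near 0
    exonic = np.zeros(length, dtype=bool)
    for lc in loci:
        for s, e in (lc.exonL, lc.exonR):
            exonic[s:e] = True
    with open(path, "w") as fh:
        for s in range(0, length, 10):
            e = min(s + 10, length)
            if exonic[s:e].any():
                v = rng.normal(1.8, 0.3)
            else:
                v = rng.normal(0.0, 0.2)
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class _SimRead:
    qname: str
    blocks: list[Interval]
    strand: str


def _merge_adjacent(blocks: list[Interval]) -> list[Interval]:
    blocks = sorted(blocks)
    out = [blocks[0]]
    for s, e in blocks[1:]:
        if s == out[-1][1]:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def _isoform_blocks(locus: Locus, pieces: Sequence) -> list[Interval]:
    blocks = []
    for p in pieces:
        if p == "exon1":
            blocks.append(locus.exon1)
        elif p == "exon2":
            blocks.append(locus.exon2)
        else:
            _tag, a, b = p
            blocks.append(locus.intron_tx(a, b))
    return _merge_adjacent(blocks)


def _mature_to_genomic(blocks: Sequence[Interval], strand: str,
                       u: int, length: int) -> list[Interval]:
    """Map mature-transcript interval [u, u+length) to genomic blocks."""
    tx_blocks = list(blocks) if strand == "+" else list(reversed(blocks))
    segs: list[Interval] = []
    remaining = length
    for bs, be in tx_blocks:
        blen = be - bs
        if u >= blen:
            u -= blen
            continue
        take = min(blen - u, remaining)
        if strand == "+":
            segs.append((bs + u, bs + u + take))
        else:
            segs.append((be - u - take, be - u))
        remaining -= take
        u = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past transcript end")
    return sorted(segs)


def _species_table(locus: Locus) -> list[tuple[str, list[Interval], float, float]]:
    """(name, genomic blocks, projection rate, whole-cell rate) per locus;
    the circular species is handled separately."""
    sc = locus.spec.scenario
    E = locus.spec.expression
    ilen = locus.spec.intron_len
    mature = _isoform_blocks(locus, ["exon1", "exon2"])
    unspliced = _isoform_blocks(locus, ["exon1", ("i", 0, ilen), "exon2"])
    half = max(1, E // 2)
    table: list[tuple[str, list[Interval], float, float]] = []
    if sc is Scenario.SPLICED_ONLY:
        table.append(("mature", mature, E, E))
    elif sc is Scenario.RETAINED_INTRON:
        table.append(("unspliced", unspliced, E, E))
        table.append(("mature", mature, half, half))
    elif sc is Scenario.DETAINED_INTRON:
        table.append(("unspliced", unspliced, 0, E))
        table.append(("mature", mature, E, E))
    elif sc is Scenario.FREE_CIRCULAR_INTRON:
        table.append(("mature", mature, half, half))
    elif sc is Scenario.INTRONIC_GENE_WITH_PAS:
        table.append(("subgene", _isoform_blocks(locus, [("i", 60, 260)]), E, E))
        table.append(("mature", mature, half, half))
    elif sc is Scenario.SNORNA_HOST:
        table.append(("snorna", _isoform_blocks(locus, [("i", 100, 230)]),
                      max(1, E // 3), E))
        table.append(("mature", mature, half, half))
    elif sc is Scenario.CASSETTE_EXON:
        table.append(("cassette", _isoform_blocks(
            locus, ["exon1", ("i", 150, 250), "exon2"]), E, E))
        table.append(("mature", mature, half, half))
    elif sc is Scenario.ALT_5SS:
        table.append(("alt5", _isoform_blocks(
            locus, ["exon1", ("i", 0, 120), "exon2"]), E, E))
        table.append(("mature", mature, half, half))
    elif sc is Scenario.ALT_3SS:
        table.append(("alt3", _isoform_blocks(
            locus, ["exon1", ("i", ilen - 120, ilen), "exon2"]), E, E))
        table.append(("mature", mature, half, half))
    elif sc is Scenario.ALT_TSS:
        table.append(("alt_tss", _isoform_blocks(
            locus, [("i", 200, ilen), "exon2"]), E, E))
        table.append(("mature", mature, half, half))
    elif sc is Scenario.ALT_PAS:
        table.append(("alt_pas", _isoform_blocks(
            locus, ["exon1", ("i", 0, 120)]), E, E))
        table.append(("mature", mature, half, half))
    return table


def _intron_tseq(locus: Locus, genome: str) -> str:
    s, e = locus.intron
    seq = genome[s:e]
    return seq if locus.strand == "+" else revcomp(seq)


def _circle_reads(locus: Locus, genome: str, n: int,
                  rng: np.random.Generator,
                  serial_prefix: str) -> tuple[list[_SimRead], list[tuple[str, str]]]:
    """Linear circle-body reads (SAM) and permuted junction reads (FASTQ)."""
    spec = locus.spec
    ilen, rl = spec.intron_len, spec.read_len
    anchor = 20
    tseq = _intron_tseq(locus, genome)
    b = ilen - spec.bp_offset_from_3ss          # branchpoint, intron-local
    body_hi = ilen - spec.tail_len - rl         # linear starts in [0, body_hi]
    sam: list[_SimRead] = []
    fastq: list[tuple[str, str]] = []
    for j in range(n):
        if rng.random() < spec.readthrough_rate:
            k = int(rng.integers(anchor, rl - anchor + 1))
            left = tseq[b + 1 - k: b + 1]
            right = tseq[0: rl - k]
            read = left + right
            if rng.random() < spec.bp_mismatch_prob:
                old = read[k - 1]
                choices = [x for x in "ACGT" if x != old]
                read = read[:k - 1] + choices[int(rng.integers(0, 3))] + read[k:]
            fastq.append((f"{serial_prefix}.circ.{j}", read))
        else:
            u = int(rng.integers(0, body_hi + 1))
            blocks = [locus.intron_tx(u, u + rl)]
            sam.append(_SimRead(f"{serial_prefix}.lin.{j}", blocks, locus.strand))
    return sam, fastq


def simulate_compartment_reads(reference: Reference, seed: int,
                               outdir: Union[str, Path],
                               n_ribo_replicates: int = 3) -> SimBundle:
    """Emit per-(compartment, replicate) SAM files, the unaligned permuted
    FASTQ, the PAS BED, ribosome-profiling SAMs and both sample sheets.

    Fragment counts are Poisson around each species' expression level
    (replicate noise); free-circle fragments traverse the 2'-5' junction
    with probability ``readthrough_rate`` and are diverted to FASTQ.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = reference.sequence()
    n_reps = max(s.n_replicates for s in (lc.spec for lc in reference.loci))

    sam_paths: dict[tuple[str, int], str] = {}
    fastq_reads: list[tuple[str, str]] = []
    sheet_rows = []
    for comp in ("projection", "whole_cell"):
        for rep in range(1, n_reps + 1):
            records: list[_SimRead] = []
            for lc in reference.loci:
                if rep > lc.spec.n_replicates:
                    continue
                rl = lc.spec.read_len
                for name, blocks, rate_p, rate_w in _species_table(lc):
                    rate = rate_p if comp == "projection" else rate_w
                    n = int(rng.poisson(rate)) if rate > 0 else 0
                    tlen = sum(e - s for s, e in blocks)
                    prefix = f"{lc.gene_id}|{name}|{comp}|r{rep}"
                    for j in range(n):
                        u = int(rng.integers(0, tlen - rl + 1))
                        segs = _mature_to_genomic(blocks, lc.strand, u, rl)
                        records.append(_SimRead(f"{prefix}|{j}", segs, lc.strand))
                if lc.spec.scenario is Scenario.FREE_CIRCULAR_INTRON:
                    rate = (lc.spec.expression if comp == "projection"
                            else max(1, lc.spec.expression // 4))
                    n = int(rng.poisson(rate))
                    sam, fq = _circle_reads(
                        lc, genome, n, rng, f"{lc.gene_id}|{comp}|r{rep}")
                    records.extend(sam)
                    fastq_reads.extend(fq)
            for j in range(N_JUNK_READS):
                fastq_reads.append((f"junk|{comp}|r{rep}|{j}",
                                    _random_seq(rng, 100)))
            sample_id = f"{comp}_r{rep}"
            path = outdir / f"{sample_id}.sam"
            _write_sam(path, reference, records, genome)
            sam_paths[(comp, rep)] = str(path)
            sheet_rows.append({"sample_id": sample_id, "compartment": comp,
                               "replicate": rep, "path": str(path),
                               "strandedness": "forward"})

    sheet = outdir / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)

    fastq_path = outdir / "unaligned.fastq"
    with open(fastq_path, "w") as fh:
        for name, seq in fastq_reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    pas_bed = outdir / "pas.bed"
    _write_pas(pas_bed, reference)

    ribo_paths: dict[int, str] = {}
    ribo_rows = []
    for rep in range(1, n_ribo_replicates + 1):
        records = []
        for lc in reference.loci:
            if lc.spec.scenario is not Scenario.CASSETTE_EXON:
                continue
            n = int(rng.poisson(10))
            prefix = f"{lc.gene_id}|ribo|r{rep}"
            for j in range(n):
                u = int(rng.integers(150, 250 - RIBO_READ_LEN + 1))
                records.append(_SimRead(f"{prefix}|{j}",
                                        [lc.intron_tx(u, u + RIBO_READ_LEN)],
                                        lc.strand))
        sample_id = f"ribo_r{rep}"
        path = outdir / f"{sample_id}.sam"
        _write_sam(path, reference, records, genome)
        ribo_paths[rep] = str(path)
        ribo_rows.append({"sample_id": sample_id, "compartment": "ribosome",
                          "replicate": rep, "path": str(path),
                          "strandedness": "forward"})
    ribo_sheet = outdir / "ribo_samples.tsv"
    pd.DataFrame(ribo_rows).to_csv(ribo_sheet, sep="\t", index=False)

    return SimBundle(sample_sheet=str(sheet), sam_paths=sam_paths,
                     fastq_path=str(fastq_path), pas_bed=str(pas_bed),
                     ribo_sheet=str(ribo_sheet), ribo_sam_paths=ribo_paths)


def simulate_permuted_reads(reference: Reference, seed: int,
                            n_replicates: int | None = None,
                            ) -> list[tuple[str, str]]:
    """Only the circularly permuted FASTQ reads of free-circle loci —
    a light-weight path for branchpoint-recovery studies."""
    rng = np.random.default_rng(seed)
    genome = reference.sequence()
    out: list[tuple[str, str]] = []
    for lc in reference.loci:
        if lc.spec.scenario is not Scenario.FREE_CIRCULAR_INTRON:
            continue
        reps = n_replicates or lc.spec.n_replicates
        for rep in range(1, reps + 1):
            n = int(rng.poisson(lc.spec.expression))
            _sam, fq = _circle_reads(lc, genome, n, rng,
                                     f"{lc.gene_id}|projection|r{rep}")
            out.extend(fq)
    return out


def _write_pas(path: Path, reference: Reference) -> None:
    rows = []
    for lc in reference.loci:
        # canonical PAS at the annotated transcript 3' end (outside regions)
        end_pos = lc.exon2[1] - 1 if lc.strand == "+" else lc.exon2[0]
        rows.append((lc.chrom, end_pos, f"{lc.gene_id}:pas", 0.9999, lc.strand))
        sc = lc.spec.scenario
        if sc is Scenario.INTRONIC_GENE_WITH_PAS:
            pos = lc.intron_tx_pos(250)
            rows.append((lc.chrom, pos, f"{lc.gene_id}:intronic_pas", 0.9999,
                         lc.strand))
        elif sc is Scenario.ALT_PAS:
            pos = lc.intron_tx_pos(119)
            rows.append((lc.chrom, pos, f"{lc.gene_id}:alt_pas", 0.9999,
                         lc.strand))
        elif sc is Scenario.RETAINED_INTRON:
            # low-confidence decoy that must be filtered out
            pos = lc.intron_tx_pos(200)
            rows.append((lc.chrom, pos, f"{lc.gene_id}:decoy_pas", 0.5,
                         lc.strand))
    rows.sort(key=lambda r: r[1])
    with open(path, "w") as fh:
        for chrom, pos, name, prob, strand in rows:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\t{prob}\t{strand}\n")


def _write_sam(path: Path, reference: Reference,
               records: list[_SimRead], genome: str) -> None:
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": reference.chrom, "LN": reference.chrom_length}]}
    records = sorted(records, key=lambda r: (r.blocks[0][0], r.qname))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.qname
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = r.blocks[0][0]
            a.mapping_quality = 50
            cig = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cig.append((3, s - prev_end))      # N gap
                cig.append((0, e - s))                 # M
                prev_end = e
            a.cigartuples = cig
            a.query_sequence = "".join(genome[s:e] for s, e in r.blocks)
            fh.write(a)


# ---------------------------------------------------------------------------
# random annotations (oracle fodder)


def random_annotation(rng: np.random.Generator,
                      n_genes: int = 20,
                      max_isoforms: int = 5,
                      max_exons: int = 10,
                      chrom: str = "chrR") -> GenomeAnnotation:
    """Random multi-isoform annotation for oracle-equivalence testing."""
    from .annotation import Gene, Transcript

    genes = []
    cursor = 0
    for gi in range(n_genes):
        territory = int(rng.integers(400, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(1, max_isoforms + 1))
        gene = Gene(gene_id=f"rg{gi:03d}", chrom=chrom, strand=strand)
        for ti in range(n_iso):
            n_exons = int(rng.integers(1, max_exons + 1))
            cuts = np.sort(rng.choice(territory, size=2 * n_exons, replace=False))
            exons = [(cursor + int(cuts[2 * k]), cursor + int(cuts[2 * k + 1]) + 1)
                     for k in range(n_exons)]
            gene.transcripts.append(
                Transcript(transcript_id=f"rg{gi:03d}.t{ti}", exons=exons))
        genes.append(gene)
        cursor += territory + int(rng.integers(50, 400))
    return GenomeAnnotation(genes=genes)
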
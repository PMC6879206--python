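"""Gene annotation parsing and intron-region derivation.

The unit of all downstream counting and classification is the *intron
region*: a maximal genomic interval that is intronic — and never exonic —
in every annotated transcript isoform of its gene that spans it. Because
the definition intersects over isoforms, an intron region is genuinely
"always intron": no annotated isoform shows it as exonic, so read coverage
over it implies an unspliced, excised-but-stable, or independently
transcribed species.

Coordinates are 0-based half-open internally. GTF is read 1-based
inclusive; BED is written/read 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

log = logging.getLogger(__name__)

#: Genomic interval, 0-based half-open.
Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Invalid annotation content (inconsistent strand/chrom, bad interval)."""


class GtfParseError(AnnotationError):
    """Malformed GTF input; message names the offending line number."""


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def exon_union(self) -> list[Interval]:
        return merge_intervals(
            [e for t in self.transcripts for e in t.exons]
        )

    def span_union(self) -> list[Interval]:
        return merge_intervals([t.span for t in self.transcripts])


@dataclass
class GenomeAnnotation:
    genes: list[Gene] = field(default_factory=list)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class IntronRegion:
    """Maximal always-intronic interval of one gene."""

    region_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BoundaryWindows:
    """EI/IE boundary windows and EE flanks for one intron region.

    ``ei_boundary``/``ie_boundary`` are the half-open split coordinates of
    the transcript-orientation 5' (exon->intron) and 3' (intron->exon)
    boundaries: a gapless alignment block [a, b) straddles a boundary ``x``
    iff a < x < b, i.e. it covers at least one base on each side.
    On the minus strand the EI boundary sits at the higher genomic
    coordinate.
    """

    region_id: str
    chrom: str
    strand: str
    ei_window: Interval
    ie_window: Interval
    ei_boundary: int
    ie_boundary: int
    ee_left_flank: Interval
    ee_right_flank: Interval
    flank_exon_nt: int
    boundary_exon_nt: int
    boundary_intron_nt: int
    clipped: bool = False
    overlapping: bool = False


# ---------------------------------------------------------------------------
# interval arithmetic

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; overlapping or bookended intervals are merged."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return [tuple(iv) for iv in out]


def subtract_intervals(minuend: Sequence[Interval],
                       subtrahend: Sequence[Interval]) -> list[Interval]:
    """Set difference minuend \\ subtrahend; both inputs must be merged/sorted."""
    out: list[Interval] = []
    j = 0
    for s, e in minuend:
        cur = s
        while j < len(subtrahend) and subtrahend[j][1] <= cur:
            j += 1
        k = j
        while k < len(subtrahend) and subtrahend[k][0] < e:
            bs, be = subtrahend[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# GTF parsing

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_annotation(source: Union[str, Path, TextIO, Iterable[str]]) -> GenomeAnnotation:
    """Parse exon features from a GTF stream into a :class:`GenomeAnnotation`.

    Only ``exon`` features are consumed; ``gene_id`` and ``transcript_id``
    attributes are required. Coordinates are converted from GTF's 1-based
    inclusive convention to 0-based half-open. Exons within a transcript are
    sorted and merged when overlapping or bookended.

    Raises
    ------
    GtfParseError
        on a malformed line (message names the line number).
    AnnotationError
        when exons of one gene disagree on strand or chromosome.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_annotation(fh)

    genes: dict[str, Gene] = {}
    transcripts: dict[tuple[str, str], Transcript] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
        if strand not in ("+", "-"):
            raise GtfParseError(f"line {lineno}: strand must be + or -, got {strand!r}")
        if end1 < start1:
            raise GtfParseError(f"line {lineno}: end < start")
        attr = dict(_ATTR_RE.findall(attrs))
        try:
            gene_id = attr["gene_id"]
            tx_id = attr["transcript_id"]
        except KeyError as missing:
            raise GtfParseError(f"line {lineno}: missing attribute {missing}") from None

        gene = genes.get(gene_id)
        if gene is None:
            gene = genes[gene_id] = Gene(gene_id=gene_id, chrom=chrom, strand=strand)
        elif gene.strand != strand:
            raise AnnotationError(
                f"gene {gene_id}: inconsistent strand ({gene.strand} vs {strand} "
                f"at line {lineno})"
            )
        elif gene.chrom != chrom:
            raise AnnotationError(
                f"gene {gene_id}: exons on multiple chromosomes "
                f"({gene.chrom} vs {chrom} at line {lineno})"
            )
        tx = transcripts.get((gene_id, tx_id))
        if tx is None:
            tx = transcripts[(gene_id, tx_id)] = Transcript(transcript_id=tx_id)
            gene.transcripts.append(tx)
        tx.exons.append((start1 - 1, end1))

    for tx in transcripts.values():
        tx.exons = merge_intervals(tx.exons)
    return GenomeAnnotation(genes=list(genes.values()))


# ---------------------------------------------------------------------------
# intron regions

def derive_intron_regions(annotation: GenomeAnnotation) -> list[IntronRegion]:
    """Derive intron regions: per gene, the maximal intervals that lie within
    at least one transcript span yet inside no exon of any isoform.

    A base inside a transcript's span that is not exonic in any isoform is
    intronic in every isoform spanning it, so this interval arithmetic is
    exactly the base-wise intersection-of-introns definition. Regions are
    computed per gene from that gene's transcripts only; overlapping genes do
    not subtract from each other (intron-hosted genes must survive
    derivation). Output is ordered by (chrom, start); region ids are
    ``gene_id:E<1-based genomic index>``.
    """
    _warn_overlapping_genes(annotation)
    regions: list[IntronRegion] = []
    for gene in annotation.genes:
        intronic = subtract_intervals(gene.span_union(), gene.exon_union())
        for i, (s, e) in enumerate(intronic, start=1):
            regions.append(IntronRegion(
                region_id=f"{gene.gene_id}:E{i}",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                start=s,
                end=e,
            ))
    regions.sort(key=lambda r: (r.chrom, r.start, r.region_id))
    return regions


def _warn_overlapping_genes(annotation: GenomeAnnotation) -> None:
    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for g in annotation.genes:
        if not g.transcripts:
            continue
        spans = g.span_union()
        by_key.setdefault((g.chrom, g.strand), []).append(
            (spans[0][0], spans[-1][1], g.gene_id)
        )
    for (chrom, strand), spans in by_key.items():
        spans.sort()
        for (s1, e1, g1), (s2, e2, g2) in zip(spans, spans[1:]):
            if s2 < e1:
                log.warning(
                    "genes %s and %s overlap on %s(%s); intron regions are "
                    "derived independently per gene", g1, g2, chrom, strand,
                )


def boundary_windows(region: IntronRegion,
                     chrom_length: int | None = None,
                     boundary_exon_nt: int = 25,
                     boundary_intron_nt: int = 25,
                     flank_exon_nt: int = 50) -> BoundaryWindows:
    """Compute EI/IE boundary windows and EE flanks for a region.

    For a + strand region [s, e): EI window = [s-exon, s+intron),
    IE window = [e-intron, e+exon); strand-swapped on -. EE flanks are the
    genomic-left [s-flank, s) and genomic-right [e, e+flank) exonic flanks.
    Windows are clipped at chromosome bounds (flagged), and flagged as
    overlapping when the region is shorter than twice the intronic half.
    """
    if boundary_exon_nt <= 0 or boundary_intron_nt <= 0:
        raise ValueError("boundary window halves must be positive")
    s, e = region.start, region.end
    if region.strand == "+":
        ei = (s - boundary_exon_nt, s + boundary_intron_nt)
        ie = (e - boundary_intron_nt, e + boundary_exon_nt)
        ei_boundary, ie_boundary = s, e
    else:
        ei = (e - boundary_intron_nt, e + boundary_exon_nt)
        ie = (s - boundary_exon_nt, s + boundary_intron_nt)
        ei_boundary, ie_boundary = e, s
    left = (s - flank_exon_nt, s)
    right = (e, e + flank_exon_nt)

    hi = chrom_length if chrom_length is not None else None
    clipped = False

    def clip(iv: Interval) -> Interval:
        nonlocal clipped
        cs, ce = max(0, iv[0]), iv[1] if hi is None else min(hi, iv[1])
        if (cs, ce) != iv:
            clipped = True
        return (cs, max(cs, ce))

    ei, ie, left, right = clip(ei), clip(ie), clip(left), clip(right)
    overlapping = region.length < 2 * boundary_intron_nt
    return BoundaryWindows(
        region_id=region.region_id,
        chrom=region.chrom,
        strand=region.strand,
        ei_window=ei,
        ie_window=ie,
        ei_boundary=ei_boundary,
        ie_boundary=ie_boundary,
        ee_left_flank=left,
        ee_right_flank=right,
        flank_exon_nt=flank_exon_nt,
        boundary_exon_nt=boundary_exon_nt,
        boundary_intron_nt=boundary_intron_nt,
        clipped=clipped,
        overlapping=overlapping,
    )


# ---------------------------------------------------------------------------
# BED / TSV I/O

def write_regions_bed(regions: Iterable[IntronRegion], path: Union[str, Path]) -> None:
    """Write intron regions as BED6 (name = region_id, score = length)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.length}\t{r.strand}\n")


def read_regions_bed(path: Union[str, Path]) -> list[IntronRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            gene_id = name.rsplit(":", 1)[0]
            regions.append(IntronRegion(
                region_id=name, gene_id=gene_id, chrom=chrom,
                strand=strand, start=int(start), end=int(end),
            ))
    return regions


def write_windows_tsv(windows: Iterable[BoundaryWindows], path: Union[str, Path]) -> None:
    cols = ("region_id chrom strand ei_start ei_end ie_start ie_end "
            "ee_left_start ee_left_end ee_right_start ee_right_end "
            "clipped overlapping").split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for w in windows:
            row = [w.region_id, w.chrom, w.strand,
                   w.ei_window[0], w.ei_window[1], w.ie_window[0], w.ie_window[1],
                   w.ee_left_flank[0], w.ee_left_flank[1],
                   w.ee_right_flank[0], w.ee_right_flank[1],
                   int(w.clipped), int(w.overlapping)]
            fh.write("\t".join(str(x) for x in row) + "\n")
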
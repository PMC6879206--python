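"""Alignment loading and per-region read counting.

Four read classes are counted per intron region and sample:

* **body** — any aligned block overlaps the region by >= 1 nt (gaps do not
  count as footprint), same strand;
* **EI / IE** — a single gapless block straddles the exon->intron (EI) or
  intron->exon (IE) boundary, i.e. covers at least one base on each side;
* **EE** — a split read whose outermost aligned bases fall in the two
  exonic flanks and one of whose inter-block gaps equals the intron region
  exactly (the spliced exon-exon junction).

Density is body reads per nucleotide of region; a read may count in several
regions but at most once per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import BoundaryWindows, IntronRegion, Interval

log = logging.getLogger(__name__)

COMPARTMENTS = ("projection", "whole_cell")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    compartment: str
    replicate: int
    path: str
    strandedness: str = "forward"  # fragment strand == read strand; "reverse" flips


@dataclass
class ReadAlignment:
    """One read's gapped genomic footprint, on the fragment strand."""

    read_id: str
    chrom: str
    strand: str
    blocks: list[Interval]
    mapq: int
    sample_id: str = ""
    compartment: str = ""
    replicate: int = 0
    mismatch_positions: list[int] | None = None

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])


def load_sample_sheet(path: Union[str, Path]) -> list[SampleMeta]:
    """Read a sample sheet TSV: sample_id, compartment, replicate, path, strandedness."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "compartment", "replicate", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"sample sheet {path} has no samples")
    out = []
    for row in df.itertuples(index=False):
        out.append(SampleMeta(
            sample_id=str(row.sample_id),
            compartment=str(row.compartment),
            replicate=int(row.replicate),
            path=str(row.path),
            strandedness=str(getattr(row, "strandedness", "forward")),
        ))
    return out


def load_alignments(path: Union[str, Path],
                    sample: SampleMeta | None = None,
                    min_mapq: int = 10,
                    known_chroms: set[str] | None = None) -> Iterator[ReadAlignment]:
    """Stream mapped primary alignments with mapq >= ``min_mapq`` from SAM/BAM.

    Secondary and supplementary records are excluded. Adjacent blocks split
    only by insertions are re-merged; N and D gaps keep blocks separate.
    Records on chromosomes absent from ``known_chroms`` are skipped with a
    warning. The reported strand is the *fragment* strand: the read strand,
    flipped when the sample's strandedness is "reverse".
    """
    path = str(path)
    flip = sample is not None and sample.strandedness == "reverse"
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if known_chroms is not None and chrom not in known_chroms:
                log.warning("skipping read %s on unknown chromosome %s",
                            rec.query_name, chrom)
                continue
            blocks = _merged_blocks(rec)
            if not blocks:
                continue
            strand = "-" if rec.is_reverse else "+"
            if flip:
                strand = "-" if strand == "+" else "+"
            yield ReadAlignment(
                read_id=rec.query_name,
                chrom=chrom,
                strand=strand,
                blocks=blocks,
                mapq=rec.mapping_quality,
                sample_id=sample.sample_id if sample else "",
                compartment=sample.compartment if sample else "",
                replicate=sample.replicate if sample else 0,
            )


def _merged_blocks(rec: pysam.AlignedSegment) -> list[Interval]:
    blocks: list[Interval] = []
    for s, e in rec.get_blocks():
        if blocks and s <= blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], max(blocks[-1][1], e))
        else:
            blocks.append((s, e))
    return blocks


# ---------------------------------------------------------------------------
# counting primitives


def read_overlaps_region(read: ReadAlignment, region: IntronRegion) -> bool:
    """Body membership: strand match and any block overlapping >= 1 nt."""
    if read.strand != region.strand or read.chrom != region.chrom:
        return False
    return any(b[0] < region.end and b[1] > region.start for b in read.blocks)


def _block_straddles(read: ReadAlignment, boundary: int) -> bool:
    return any(b[0] < boundary < b[1] for b in read.blocks)


def _block_overlaps_window(read: ReadAlignment, window: Interval) -> bool:
    return any(b[0] < window[1] and b[1] > window[0] for b in read.blocks)


def read_is_ei(read: ReadAlignment, windows: BoundaryWindows,
               boundary_mode: str = "straddle") -> bool:
    if read.strand != windows.strand or read.chrom != windows.chrom:
        return False
    if boundary_mode == "straddle":
        return _block_straddles(read, windows.ei_boundary)
    return _block_overlaps_window(read, windows.ei_window)


def read_is_ie(read: ReadAlignment, windows: BoundaryWindows,
               boundary_mode: str = "straddle") -> bool:
    if read.strand != windows.strand or read.chrom != windows.chrom:
        return False
    if boundary_mode == "straddle":
        return _block_straddles(read, windows.ie_boundary)
    return _block_overlaps_window(read, windows.ie_window)


def read_is_ee(read: ReadAlignment, region: IntronRegion,
               windows: BoundaryWindows) -> bool:
    """EE membership: split read starting/ending in the flanks with one gap
    exactly matching the region interval."""
    if read.strand != region.strand or read.chrom != region.chrom:
        return False
    if len(read.blocks) < 2:
        return False
    first, last = read.blocks[0][0], read.blocks[-1][1] - 1
    lf, rf = windows.ee_left_flank, windows.ee_right_flank
    if not (lf[0] <= first < lf[1] and rf[0] <= last < rf[1]):
        return False
    return any(
        read.blocks[i][1] == region.start and read.blocks[i + 1][0] == region.end
        for i in range(len(read.blocks) - 1)
    )


# spec-level operations over full alignment collections ----------------------


def count_region_reads(regions: Sequence[IntronRegion],
                       alignments: Iterable[ReadAlignment]) -> dict[str, int]:
    """Body read count per region_id (strand-matched block overlap)."""
    counts = _count(regions, None, alignments, what=("body",))
    return {rid: c["body"] for rid, c in counts.items()}


def count_boundary_reads(windows: Sequence[BoundaryWindows],
                         alignments: Iterable[ReadAlignment],
                         boundary_mode: str = "straddle") -> dict[str, tuple[int, int]]:
    """(EI, IE) counts per region_id."""
    regions = [IntronRegion(w.region_id, "", w.chrom, w.strand,
                            min(w.ei_boundary, w.ie_boundary),
                            max(w.ei_boundary, w.ie_boundary)) for w in windows]
    counts = _count(regions, {w.region_id: w for w in windows}, alignments,
                    what=("ei", "ie"), boundary_mode=boundary_mode)
    return {rid: (c["ei"], c["ie"]) for rid, c in counts.items()}


def count_ee_junction_reads(region: IntronRegion,
                            windows: BoundaryWindows,
                            alignments: Iterable[ReadAlignment]) -> int:
    return sum(read_is_ee(r, region, windows) for r in alignments)


def count_sample(regions: Sequence[IntronRegion],
                 windows: dict[str, BoundaryWindows],
                 alignments: Iterable[ReadAlignment],
                 boundary_mode: str = "straddle") -> pd.DataFrame:
    """Single pass producing body/EI/IE/EE counts and densities per region.

    Returns a DataFrame with one row per region (zero rows included), columns
    region_id, body_reads, body_density, ei_reads, ie_reads, ee_reads.
    """
    counts = _count(regions, windows, alignments,
                    what=("body", "ei", "ie", "ee"), boundary_mode=boundary_mode)
    rows = []
    for r in regions:
        c = counts[r.region_id]
        rows.append({
            "region_id": r.region_id,
            "body_reads": c["body"],
            "body_density": c["body"] / r.length,
            "ei_reads": c["ei"],
            "ie_reads": c["ie"],
            "ee_reads": c["ee"],
        })
    return pd.DataFrame(rows)


def _count(regions: Sequence[IntronRegion],
           windows: dict[str, BoundaryWindows] | None,
           alignments: Iterable[ReadAlignment],
           what: tuple[str, ...],
           boundary_mode: str = "straddle") -> dict[str, dict[str, int]]:
    # interval stabbing over [start - flank, end + flank) covers body,
    # boundary windows and EE flanks for the default window geometry
    pad = 0
    if windows:
        pad = max(max(w.flank_exon_nt, w.boundary_exon_nt) for w in windows.values())
    trees: dict[tuple[str, str], IntervalTree] = {}
    by_id = {r.region_id: r for r in regions}
    for r in regions:
        trees.setdefault((r.chrom, r.strand), IntervalTree()).addi(
            r.start - pad, r.end + pad, r.region_id)
    counts = {r.region_id: {k: 0 for k in ("body", "ei", "ie", "ee")} for r in regions}
    for read in alignments:
        tree = trees.get((read.chrom, read.strand))
        if tree is None:
            continue
        s, e = read.span
        for hit in tree.overlap(s, e):
            rid = hit.data
            region = by_id[rid]
            w = windows.get(rid) if windows else None
            c = counts[rid]
            if "body" in what and read_overlaps_region(read, region):
                c["body"] += 1
            if w is not None:
                if "ei" in what and read_is_ei(read, w, boundary_mode):
                    c["ei"] += 1
                if "ie" in what and read_is_ie(read, w, boundary_mode):
                    c["ie"] += 1
                if "ee" in what and read_is_ee(read, region, w):
                    c["ee"] += 1
    return counts


def count_all_samples(regions: Sequence[IntronRegion],
                      windows: dict[str, BoundaryWindows],
                      samples: Sequence[SampleMeta],
                      min_mapq: int = 10,
                      boundary_mode: str = "straddle") -> pd.DataFrame:
    """Count every sample in a sample sheet; returns the long-format
    RegionCounts table keyed by (region_id, sample_id)."""
    known = {r.chrom for r in regions}
    frames = []
    for sm in samples:
        reads = load_alignments(sm.path, sm, min_mapq=min_mapq, known_chroms=known)
        df = count_sample(regions, windows, reads, boundary_mode=boundary_mode)
        df.insert(1, "sample_id", sm.sample_id)
        df.insert(2, "compartment", sm.compartment)
        df.insert(3, "replicate", sm.replicate)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def region_coverage(region: IntronRegion,
                    alignments: Iterable[ReadAlignment]) -> np.ndarray:
    """Per-base read depth over the region (genomic orientation),
    strand-matched, from aligned blocks only."""
    cov = np.zeros(region.length, dtype=np.int64)
    for read in alignments:
        if read.strand != region.strand or read.chrom != region.chrom:
            continue
        for bs, be in read.blocks:
            s = max(bs, region.start) - region.start
            e = min(be, region.end) - region.start
            if s < e:
                cov[s:e] += 1
    return cov
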
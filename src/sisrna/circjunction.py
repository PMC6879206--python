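"""Circularly permuted read detection, 2'-5' junction refinement,
branchpoint calling, 3' tail coverage gaps, and consensus matrices.

An excised intron lariat carries a 2'-5' bond joining the intron 5' end to
the branchpoint nucleotide. Reverse transcriptase occasionally traverses
this bond, producing reads whose two halves map in inverted genomic order:
the read-5' half ends at the branchpoint (the *donor*), the read-3' half
begins at the intron 5' end (the *acceptor*). Detection is anchor-based:
the first and last ``anchor_len`` bases of an unaligned read must each map
uniquely, on the same strand, inside one candidate region (extended by the
anchor length), in permuted order. The exact split is then refined by
sliding the breakpoint across the unanchored middle and maximising matches;
mismatches concentrate at the junction because the polymerase reads through
the branched nucleotide with low fidelity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .annotation import IntronRegion

log = logging.getLogger(__name__)

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: consensus windows (offsets relative to anchor, inclusive), transcript
#: orientation; anchor offset 0 = intron first base / branchpoint base /
#: intron last base respectively
DEFAULT_CONSENSUS_WINDOWS: dict[str, tuple[int, int]] = {
    "five_prime_ss": (-3, 8),
    "branchpoint": (-8, 2),
    "three_prime_ss": (-10, 3),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


@dataclass
class CircParams:
    anchor_len: int = 20
    max_anchor_mismatch: int = 0        # only exact anchor lookup implemented
    max_span: int | None = None         # None: bounded by the extended region
    max_extension_mismatch: int = 2
    junction_mismatch_window: int = 5   # +-nt around the donor
    tail_gap_min_nt: int = 15
    min_body_mean: float = 1.0


@dataclass(frozen=True)
class CircJunction:
    """One read's resolved 2'-5' junction."""

    region_id: str
    chrom: str
    strand: str
    acceptor_pos: int          # genomic coord of intron first base (transcript 5')
    donor_pos: int             # genomic coord of the branchpoint base
    bp_base: str               # strand-corrected genome base at donor_pos
    dist_to_3ss: int           # donor to intron last base, inclusive
    read_id: str
    total_mismatches: int
    junction_mismatches: int   # within +-window of the donor


@dataclass
class BranchpointCall:
    """Aggregated junction support for one (donor, acceptor) pair."""

    region_id: str
    chrom: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    support: int
    bp_base: str
    dist_to_3ss: int
    canonical: bool            # branchpoint is the canonical adenosine
    mean_junction_mismatches: float


@dataclass
class _RegionIndex:
    """Transcript-oriented sequence and unique-k-mer index of one candidate
    region extended by the anchor length."""

    region: IntronRegion
    ext_start: int
    ext_end: int
    tseq: str
    t0: int                    # transcript coord of the intron first base
    kmers: dict[str, int]      # k-mer -> position; multi-hit k-mers removed
    multi: set[str]

    @property
    def t_end(self) -> int:
        return self.t0 + self.region.length

    def to_genomic(self, t: int) -> int:
        if self.region.strand == "+":
            return self.ext_start + t
        return self.ext_end - 1 - t


class GenomeIndex:
    """k-mer lookup over candidate regions of a genome."""

    def __init__(self, genome: Mapping[str, str] | str | Path,
                 regions: Sequence[IntronRegion],
                 anchor_len: int = 20) -> None:
        self.anchor_len = anchor_len
        self._seqs = _as_genome(genome)
        self.indexes: list[_RegionIndex] = [
            self._build(r) for r in regions
        ]

    def chrom_seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def _build(self, region: IntronRegion) -> _RegionIndex:
        k = self.anchor_len
        chrom_seq = self._seqs[region.chrom]
        ext_start = max(0, region.start - k)
        ext_end = min(len(chrom_seq), region.end + k)
        seq = chrom_seq[ext_start:ext_end].upper()
        if region.strand == "-":
            seq = revcomp(seq)
            t0 = ext_end - region.end
        else:
            t0 = region.start - ext_start
        kmers: dict[str, int] = {}
        multi: set[str] = set()
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if km in kmers or km in multi:
                multi.add(km)
                kmers.pop(km, None)
            else:
                kmers[km] = i
        return _RegionIndex(region=region, ext_start=ext_start, ext_end=ext_end,
                            tseq=seq, t0=t0, kmers=kmers, multi=multi)


@dataclass
class PermutedCandidate:
    read_id: str
    seq: str
    index: _RegionIndex
    p1: int                    # transcript-coord start of the read-5' anchor
    p2: int                    # transcript-coord start of the read-3' anchor


def _as_genome(genome: Mapping[str, str] | str | Path) -> Mapping[str, str]:
    if isinstance(genome, (str, Path)):
        import pyfaidx
        fa = pyfaidx.Fasta(str(genome))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    return genome


def iter_fastq(path: Union[str, Path]) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper()


def find_permuted_candidates(reads: Union[str, Path, Iterable[tuple[str, str]]],
                             genome: Mapping[str, str] | str | Path,
                             regions: Sequence[IntronRegion],
                             params: CircParams | None = None,
                             index: GenomeIndex | None = None,
                             ) -> list[PermutedCandidate]:
    """Anchor-map unaligned reads against candidate regions; keep reads whose
    terminal anchors map uniquely, same region/strand, in permuted order
    (read-5' anchor genomically downstream of the read-3' anchor on the
    transcript strand)."""
    params = params or CircParams()
    k = params.anchor_len
    if index is None:
        index = GenomeIndex(genome, regions, anchor_len=k)
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    out: list[PermutedCandidate] = []
    for read_id, seq in reads:
        if len(seq) < 2 * k:
            log.warning("read %s shorter than twice the anchor length; skipped",
                        read_id)
            continue
        a1, a2 = seq[:k], seq[-k:]
        hits1 = []
        hits2 = []
        ambiguous = False
        for ridx in index.indexes:
            if a1 in ridx.multi or a2 in ridx.multi:
                ambiguous = True
                break
            if a1 in ridx.kmers:
                hits1.append((ridx, ridx.kmers[a1]))
            if a2 in ridx.kmers:
                hits2.append((ridx, ridx.kmers[a2]))
        if ambiguous or len(hits1) != 1 or len(hits2) != 1:
            if ambiguous or len(hits1) > 1 or len(hits2) > 1:
                log.debug("read %s: non-unique anchor hits rejected", read_id)
            continue
        (r1, p1), (r2, p2) = hits1[0], hits2[0]
        if r1 is not r2:
            continue
        if p1 <= p2:        # colinear or overlapping order: not permuted
            continue
        span = (p1 + k) - p2
        if params.max_span is not None and span > params.max_span:
            continue
        out.append(PermutedCandidate(read_id=read_id, seq=seq,
                                     index=r1, p1=p1, p2=p2))
    return out


def refine_breakpoint(candidate: PermutedCandidate,
                      params: CircParams | None = None) -> CircJunction | None:
    """Slide the split point across the unanchored middle of the read and
    return the junction maximising matches, or None when the best alignment
    exceeds the mismatch budget.

    Ties are broken by (1) acceptor equal to the annotated intron start,
    then (2) smallest distance to the 3' splice site, then smallest split.
    """
    params = params or CircParams()
    k = params.anchor_len
    idx = candidate.index
    S = idx.tseq
    read = candidate.seq
    n = len(read)
    p1, p2 = candidate.p1, candidate.p2

    k_lo = max(k, n - k - p2)
    k_hi = min(n - k, len(S) - p1)
    if k_lo > k_hi:
        return None

    r = np.frombuffer(read.encode(), dtype=np.uint8)
    s = np.frombuffer(S.encode(), dtype=np.uint8)
    # left extension mismatch prefix sums: read[:k'] vs S[p1:p1+k']
    left_len = min(n, len(S) - p1)
    v = (r[:left_len] != s[p1:p1 + left_len]).astype(np.int64)
    vcum = np.concatenate([[0], np.cumsum(v)])
    # right extension: read[j] vs S[p2+k-n+j], valid where index >= 0
    off = p2 + k - n
    j0 = max(0, -off)
    w = np.zeros(n, dtype=np.int64)
    w[j0:] = (r[j0:] != s[off + j0: off + n]).astype(np.int64)
    wcum = np.concatenate([[0], np.cumsum(w)])
    wtot = wcum[-1]

    best: tuple[int, int, int, int] | None = None   # (mm, not_annot, dist, split)
    for split in range(k_lo, k_hi + 1):
        mm = int(vcum[split] + (wtot - wcum[split]))
        donor_t = p1 + split - 1
        acceptor_t = p2 + k - (n - split)
        if not (idx.t0 <= donor_t < idx.t_end):
            continue
        dist = idx.t_end - donor_t
        keyed = (mm, 0 if acceptor_t == idx.t0 else 1, dist, split)
        if best is None or keyed < best:
            best = keyed
    if best is None:
        return None
    mm, _na, dist, split = best
    if mm > params.max_extension_mismatch:
        return None

    donor_t = p1 + split - 1
    acceptor_t = p2 + k - (n - split)
    wwin = params.junction_mismatch_window
    # mismatches landing within +-window of the donor, either read half
    jmm = 0
    for j in range(split):
        if v[j] and abs((p1 + j) - donor_t) <= wwin:
            jmm += 1
    for j in range(split, n):
        t = off + j
        if w[j] and abs(t - donor_t) <= wwin:
            jmm += 1

    region = idx.region
    return CircJunction(
        region_id=region.region_id,
        chrom=region.chrom,
        strand=region.strand,
        acceptor_pos=idx.to_genomic(acceptor_t),
        donor_pos=idx.to_genomic(donor_t),
        bp_base=S[donor_t],
        dist_to_3ss=dist,
        read_id=candidate.read_id,
        total_mismatches=mm,
        junction_mismatches=jmm,
    )


def call_branchpoint(junctions: Sequence[CircJunction]) -> list[BranchpointCall]:
    """Aggregate per-read junctions of one region by (donor, acceptor);
    all distinct junctions are reported, ranked by support (ties by
    proximity to the 3'SS). The first entry is the modal junction."""
    if not junctions:
        raise ValueError("no accepted junctions to aggregate")
    groups: dict[tuple[int, int], list[CircJunction]] = {}
    for j in junctions:
        groups.setdefault((j.donor_pos, j.acceptor_pos), []).append(j)
    calls = []
    for (donor, acceptor), js in groups.items():
        j0 = js[0]
        calls.append(BranchpointCall(
            region_id=j0.region_id,
            chrom=j0.chrom,
            strand=j0.strand,
            donor_pos=donor,
            acceptor_pos=acceptor,
            support=len(js),
            bp_base=j0.bp_base,
            dist_to_3ss=j0.dist_to_3ss,
            canonical=j0.bp_base == "A",
            mean_junction_mismatches=float(np.mean(
                [j.junction_mismatches for j in js])),
        ))
    calls.sort(key=lambda c: (-c.support, c.dist_to_3ss, c.donor_pos))
    return calls


def detect_tail_gap(coverage: np.ndarray,
                    strand: str = "+",
                    tail_gap_min_nt: int = 15,
                    min_body_mean: float = 1.0) -> tuple[int, bool]:
    """Length of the zero-coverage run ending at the transcript-orientation
    3' terminus of a region, and whether it is flagged as a lariat-tail gap.

    ``coverage`` is per-base depth in genomic orientation; flagging requires
    gap >= ``tail_gap_min_nt`` and a covered body (mean depth over the rest
    of the region >= ``min_body_mean``), so entirely silent regions are not
    flagged.
    """
    cov = np.asarray(coverage)
    if strand == "-":
        cov = cov[::-1]
    nz = np.nonzero(cov)[0]
    gap = len(cov) if len(nz) == 0 else len(cov) - 1 - int(nz[-1])
    body = cov[:len(cov) - gap]
    flagged = (gap >= tail_gap_min_nt
               and len(body) > 0
               and float(body.mean()) >= min_body_mean)
    return gap, flagged


# ---------------------------------------------------------------------------
# consensus matrices

BASES = ("A", "C", "G", "T")


@dataclass
class ConsensusMatrix:
    anchor: str
    offsets: list[int]
    counts: pd.DataFrame           # index offsets, columns A/C/G/T
    information_content: np.ndarray

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.counts.copy()
        out.insert(0, "offset", self.offsets)
        out["information_content"] = self.information_content
        out.to_csv(path, sep="\t", index=False)


def column_information(counts: Sequence[float]) -> float:
    """Information content 2 + sum f*log2 f (bits) of one base-count column;
    empty columns score 0."""
    tot = float(sum(counts))
    if tot == 0:
        return 0.0
    ic = 2.0
    for c in counts:
        if c > 0:
            f = c / tot
            ic += f * math.log2(f)
    return max(0.0, ic)


def consensus_from_sequences(seqs: Sequence[str], lo: int,
                             anchor: str = "") -> ConsensusMatrix:
    """Base-count matrix and per-offset information content from aligned
    equal-length sequences whose position 0 corresponds to offset ``lo``.
    N bases are excluded from counts."""
    if not seqs:
        raise ValueError("no sequences")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences must be equal length")
    offsets = list(range(lo, lo + width))
    table = np.zeros((width, 4), dtype=np.int64)
    for s in seqs:
        for j, b in enumerate(s.upper()):
            if b in BASES:
                table[j, BASES.index(b)] += 1
    counts = pd.DataFrame(table, columns=list(BASES))
    ic = np.array([column_information(row) for row in table])
    return ConsensusMatrix(anchor=anchor, offsets=offsets,
                           counts=counts, information_content=ic)


def _anchor_window_seq(chrom_seq: str, anchor_pos: int, strand: str,
                       lo: int, hi: int) -> str:
    """Strand-corrected sequence at offsets lo..hi (inclusive) around a
    genomic anchor base; off-chromosome positions are padded with N."""
    if strand == "+":
        s, e = anchor_pos + lo, anchor_pos + hi + 1
        raw = chrom_seq[max(0, s):max(0, e)]
        return ("N" * max(0, -s)) + raw + ("N" * max(0, e - len(chrom_seq)))
    s, e = anchor_pos - hi, anchor_pos - lo + 1
    raw = chrom_seq[max(0, s):max(0, e)]
    padded = ("N" * max(0, -s)) + raw + ("N" * max(0, e - len(chrom_seq)))
    return revcomp(padded)


def junction_consensus(records: Sequence[tuple[IntronRegion, int]],
                       genome: Mapping[str, str] | str | Path,
                       windows: dict[str, tuple[int, int]] | None = None,
                       ) -> dict[str, ConsensusMatrix]:
    """Consensus matrices around the 5' splice site, branchpoint, and 3'
    splice site of regions with called branchpoints.

    ``records`` holds (region, donor_pos) pairs; anchors are the intron
    first base, the branchpoint base, and the intron last base, all in
    transcript orientation.
    """
    if not records:
        raise ValueError("no branchpoint records")
    windows = windows or DEFAULT_CONSENSUS_WINDOWS
    seqs = _as_genome(genome)
    out: dict[str, ConsensusMatrix] = {}
    for anchor, (lo, hi) in windows.items():
        aligned = []
        for region, donor_pos in records:
            chrom_seq = seqs[region.chrom].upper()
            if anchor == "five_prime_ss":
                pos = region.start if region.strand == "+" else region.end - 1
            elif anchor == "three_prime_ss":
                pos = region.end - 1 if region.strand == "+" else region.start
            elif anchor == "branchpoint":
                pos = donor_pos
            else:
                raise ValueError(f"unknown anchor {anchor}")
            aligned.append(_anchor_window_seq(chrom_seq, pos, region.strand, lo, hi))
        out[anchor] = consensus_from_sequences(aligned, lo, anchor=anchor)
    return out


# ---------------------------------------------------------------------------
# orchestration over one FASTQ


def call_junctions(reads: Union[str, Path, Iterable[tuple[str, str]]],
                   genome: Mapping[str, str] | str | Path,
                   regions: Sequence[IntronRegion],
                   params: CircParams | None = None,
                   ) -> tuple[dict[str, list[BranchpointCall]], list[CircJunction]]:
    """Full per-region junction calling: anchor search, breakpoint
    refinement, aggregation. Returns ({region_id: ranked calls}, accepted
    per-read junctions)."""
    params = params or CircParams()
    index = GenomeIndex(genome, regions, anchor_len=params.anchor_len)
    candidates = find_permuted_candidates(reads, genome, regions,
                                          params=params, index=index)
    accepted: list[CircJunction] = []
    for cand in candidates:
        j = refine_breakpoint(cand, params)
        if j is not None:
            accepted.append(j)
    by_region: dict[str, list[CircJunction]] = {}
    for j in accepted:
        by_region.setdefault(j.region_id, []).append(j)
    calls = {rid: call_branchpoint(js) for rid, js in by_region.items()}
    return calls, accepted


def junction_table(calls: Mapping[str, Sequence[BranchpointCall]]) -> pd.DataFrame:
    rows = []
    for rid in sorted(calls):
        for rank, c in enumerate(calls[rid], start=1):
            rows.append({
                "region_id": c.region_id, "chrom": c.chrom, "strand": c.strand,
                "donor_pos": c.donor_pos, "acceptor_pos": c.acceptor_pos,
                "rank": rank, "support": c.support, "bp_base": c.bp_base,
                "dist_to_3ss": c.dist_to_3ss, "canonical": c.canonical,
                "mean_junction_mismatches": c.mean_junction_mismatches,
            })
    cols = ["region_id", "chrom", "strand", "donor_pos", "acceptor_pos", "rank",
            "support", "bp_base", "dist_to_3ss", "canonical",
            "mean_junction_mismatches"]
    return pd.DataFrame(rows, columns=cols)
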
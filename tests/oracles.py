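"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity base-by-base or pair-by-pair,
sharing no code with the library implementations they check.
"""

from __future__ import annotations

import numpy as np


def intron_regions_basewise(gene):
    """Maximal runs of bases that are inside >=1 transcript span and inside
    no exon of any isoform (vectorised base-wise scan)."""
    spans = [(t.exons[0][0], t.exons[-1][1]) for t in gene.transcripts]
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    n = hi - lo
    in_span = np.zeros(n, dtype=bool)
    for s, e in spans:
        in_span[s - lo:e - lo] = True
    exonic = np.zeros(n, dtype=bool)
    for t in gene.transcripts:
        for s, e in t.exons:
            exonic[s - lo:e - lo] = True
    ok = in_span & ~exonic
    # maximal runs
    padded = np.concatenate([[False], ok, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(lo + int(s), lo + int(e)) for s, e in zip(starts, ends)]


def _straddle_boundary(read, boundary):
    return any(a < boundary < b for a, b in read.blocks)


def count_reads_allpairs(regions, reads, flank=50):
    """Naive all-pairs body/EI/IE/EE counting; boundaries recomputed from
    region coordinates and strand directly."""
    out = {}
    for r in regions:
        body = ei = ie = ee = 0
        if r.strand == "+":
            ei_b, ie_b = r.start, r.end
        else:
            ei_b, ie_b = r.end, r.start
        for read in reads:
            if read.chrom != r.chrom or read.strand != r.strand:
                continue
            if any(a < r.end and b > r.start for a, b in read.blocks):
                body += 1
            if _straddle_boundary(read, ei_b):
                ei += 1
            if _straddle_boundary(read, ie_b):
                ie += 1
            if len(read.blocks) >= 2:
                first = read.blocks[0][0]
                last = read.blocks[-1][1] - 1
                in_left = r.start - flank <= first < r.start
                in_right = r.end <= last < r.end + flank
                gap_match = any(
                    read.blocks[i][1] == r.start and read.blocks[i + 1][0] == r.end
                    for i in range(len(read.blocks) - 1))
                if in_left and in_right and gap_match:
                    ee += 1
        out[r.region_id] = dict(body=body, ei=ei, ie=ie, ee=ee)
    return out


def window_means_basewise(values, length, window=50, step=10):
    """Per-window means over covered bases, windows tiled from the region
    start; short regions get one whole-region window."""
    if length < window:
        spans = [(0, length)]
    else:
        spans = [(s, s + window) for s in range(0, length - window + 1, step)]
    means = []
    for s, e in spans:
        vals = [values[i] for i in range(s, e) if not np.isnan(values[i])]
        if vals:
            means.append(sum(vals) / len(vals))
    return means
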
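"""Detectability, EI/IE quadrant classification, evidence-based resolution
of the low/low quadrant, and projection-enrichment scoring.

A region is *detectable* in a compartment when every replicate contributes
at least one body read and the mean body density across replicates exceeds
0.005 reads/nt (strict). Detectable regions are placed in one of four
quadrants by mean EI and IE boundary-read counts (+0.1 pseudocount, strict
> 1 for "high"), computed from the projection compartment:

* i   (EI high, IE low)  -> unannotated alternative 5'SS or intronic PAS
* ii  (EI low, IE high)  -> unannotated alternative 3'SS or intronic TSS
* iii (both high)        -> retained intron
* iv  (both low)         -> resolved by orthogonal evidence: an intronic
  polyadenylation site call implies a gene-within-intron or alternative
  terminal exon; failing that, ribosome occupancy (mean body reads >= 5 per
  replicate) implies an unannotated cassette exon; otherwise the region is a
  free-intron candidate (stable excised intron or other nonpolyadenylated
  species), forwarded to the circular-junction search.

Projection enrichment is log2 of the ratio of mean body densities
(projection / whole cell), each offset by a pseudocount equivalent to one
read over the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .annotation import IntronRegion

QUADRANT_CLASS = {
    "i": "ALT_5SS_OR_ALT_PAS",
    "ii": "ALT_3SS_OR_ALT_TSS",
    "iii": "RETAINED",
}
LOWLOW_CLASSES = ("INTRONIC_GENE_OR_ALT_TERMINAL", "CASSETTE_EXON",
                  "FREE_INTRON_CANDIDATE")


@dataclass
class Thresholds:
    """All classification tunables; defaults are the study's operating point."""

    min_reads_per_replicate: int = 1
    min_mean_density: float = 0.005        # strict >
    ei_ie_pseudocount: float = 0.1
    ei_ie_threshold: float = 1.0           # strict > for "high"
    ribo_min_mean_per_replicate: float = 5.0   # inclusive >=
    pas_min_probability: float = 0.999     # classifier p-value < 0.001
    scatter_pseudocount: float = 1.0
    enrichment_pseudocount: float = 1.0    # reads; scaled by 1/region_length
    de_fold_change: float = 1.5            # recorded only; DE is out of scope
    de_qvalue: float = 0.01                # recorded only
    tail_gap_min_nt: int = 15

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"threshold {k} must be >= 0, got {v}")

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "Thresholds":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class PasSite:
    chrom: str
    position: int
    strand: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"PAS probability must be in [0,1], got {self.probability}")


def read_pas_bed(path: Union[str, Path]) -> list[PasSite]:
    """PAS calls as BED6; score column carries the classifier probability."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, _name, score, strand = line.rstrip("\n").split("\t")[:6]
            sites.append(PasSite(chrom, int(start), strand, float(score)))
    return sites


# ---------------------------------------------------------------------------
# elementary rules


def assess_detectability(body_reads: Sequence[int],
                         body_densities: Sequence[float],
                         thresholds: Thresholds | None = None) -> bool:
    """True iff every replicate has >= 1 body read and mean density > 0.005."""
    thr = thresholds or Thresholds()
    if len(body_reads) == 0:
        raise ValueError("no replicates supplied")
    if min(body_reads) < thr.min_reads_per_replicate:
        return False
    return float(np.mean(body_densities)) > thr.min_mean_density


def mean_with_pseudocount(counts: Sequence[float], pseudocount: float) -> float:
    # (sum + n*p)/n rather than mean(c+p): keeps the exact-threshold case
    # (e.g. nine 1s and one 0 with p=0.1) float-exact at 1.0
    n = len(counts)
    return (float(np.sum(counts)) + n * pseudocount) / n


def quadrant_classify(ei_reads: Sequence[int], ie_reads: Sequence[int],
                      thresholds: Thresholds | None = None) -> tuple[str, float, float]:
    """Quadrant from projection EI/IE replicate counts.

    Returns (quadrant, mean_ei, mean_ie); "high" is strict > threshold, so a
    mean exactly at the threshold falls on the low side.
    """
    thr = thresholds or Thresholds()
    mean_ei = mean_with_pseudocount(ei_reads, thr.ei_ie_pseudocount)
    mean_ie = mean_with_pseudocount(ie_reads, thr.ei_ie_pseudocount)
    hi_ei = mean_ei > thr.ei_ie_threshold
    hi_ie = mean_ie > thr.ei_ie_threshold
    if hi_ei and hi_ie:
        q = "iii"
    elif hi_ei:
        q = "i"
    elif hi_ie:
        q = "ii"
    else:
        q = "iv"
    return q, mean_ei, mean_ie


def pas_inside_region(region: IntronRegion, pas_sites: Iterable[PasSite],
                      min_probability: float = 0.999) -> bool:
    """A confident PAS strictly inside the region, same strand. Sites on the
    first or last intronic base are treated as boundary (annotated 3' ends)
    and excluded."""
    for p in pas_sites:
        if p.chrom != region.chrom or p.strand != region.strand:
            continue
        if p.probability < min_probability:
            continue
        if region.start < p.position < region.end - 1:
            return True
    return False


def resolve_lowlow(region: IntronRegion,
                   pas_sites: Iterable[PasSite],
                   ribo_body_reads: Sequence[float],
                   thresholds: Thresholds | None = None) -> tuple[str, bool]:
    """Resolve a quadrant-iv region: PAS evidence first, then ribosome
    occupancy, else free-intron candidate.

    Returns (final_class, dual_evidence) — dual_evidence flags regions where
    both PAS and ribosome criteria hold (PAS wins).
    """
    thr = thresholds or Thresholds()
    has_pas = pas_inside_region(region, pas_sites, thr.pas_min_probability)
    ribo_mean = float(np.mean(ribo_body_reads)) if len(ribo_body_reads) else 0.0
    has_ribo = ribo_mean >= thr.ribo_min_mean_per_replicate
    if has_pas:
        return "INTRONIC_GENE_OR_ALT_TERMINAL", has_ribo
    if has_ribo:
        return "CASSETTE_EXON", False
    return "FREE_INTRON_CANDIDATE", False


def enrichment_score(projection_densities: Sequence[float],
                     wholecell_densities: Sequence[float],
                     region_length: int,
                     thresholds: Thresholds | None = None) -> tuple[float, float]:
    """log2 projection/whole-cell mean-density ratio and overall mean density.

    The pseudocount is ``enrichment_pseudocount`` reads spread over the
    region (default one read / region length), applied to both numerator and
    denominator.
    """
    thr = thresholds or Thresholds()
    p = thr.enrichment_pseudocount / region_length
    mp = float(np.mean(projection_densities))
    mw = float(np.mean(wholecell_densities))
    log2_ratio = float(np.log2((mp + p) / (mw + p)))
    mean_all = float(np.mean(list(projection_densities) + list(wholecell_densities)))
    return log2_ratio, mean_all


# ---------------------------------------------------------------------------
# full table


def build_region_calls(regions: Sequence[IntronRegion],
                       counts: pd.DataFrame,
                       pas_sites: Iterable[PasSite] = (),
                       ribo_counts: pd.DataFrame | None = None,
                       thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Assemble the per-region call table.

    ``counts`` is the long-format RegionCounts table (region_id, sample_id,
    compartment, replicate, body_reads, body_density, ei_reads, ie_reads,
    ee_reads) covering both compartments; ``ribo_counts`` the same for
    ribosome-profiling samples (body fields used). Every region appears
    exactly once in the output. Quadrants use projection EI/IE only;
    final_class is assigned for projection-detectable regions, with
    quadrant-iv regions resolved by PAS-then-ribosome evidence.
    """
    thr = thresholds or Thresholds()
    pas_sites = list(pas_sites)
    by_region = dict(tuple(counts.groupby("region_id", sort=False)))
    ribo_by_region = (dict(tuple(ribo_counts.groupby("region_id", sort=False)))
                      if ribo_counts is not None and len(ribo_counts) else {})
    rows = []
    for region in regions:
        sub = by_region.get(region.region_id)
        if sub is None:
            raise ValueError(f"no counts for region {region.region_id}")
        proj = sub[sub.compartment == "projection"].sort_values("replicate")
        wc = sub[sub.compartment == "whole_cell"].sort_values("replicate")
        for name, part in (("projection", proj), ("whole_cell", wc)):
            if part.empty:
                raise ValueError(
                    f"region {region.region_id}: no {name} replicates in counts")
        det_p = assess_detectability(proj.body_reads.tolist(),
                                     proj.body_density.tolist(), thr)
        det_w = assess_detectability(wc.body_reads.tolist(),
                                     wc.body_density.tolist(), thr)
        quadrant, mean_ei, mean_ie = quadrant_classify(
            proj.ei_reads.tolist(), proj.ie_reads.tolist(), thr)
        dual = False
        if det_p:
            if quadrant in QUADRANT_CLASS:
                final = QUADRANT_CLASS[quadrant]
            else:
                ribo_sub = ribo_by_region.get(region.region_id)
                ribo_reads = (ribo_sub.body_reads.tolist()
                              if ribo_sub is not None else [])
                final, dual = resolve_lowlow(region, pas_sites, ribo_reads, thr)
        else:
            final = "NOT_DETECTED"
        enr, mean_all = enrichment_score(
            proj.body_density.tolist(), wc.body_density.tolist(),
            region.length, thr)
        rows.append({
            "region_id": region.region_id,
            "gene_id": region.gene_id,
            "chrom": region.chrom,
            "strand": region.strand,
            "start": region.start,
            "end": region.end,
            "length": region.length,
            "detectable_projection": det_p,
            "detectable_wholecell": det_w,
            "projection_only": det_p and not det_w,
            "mean_ei": mean_ei,
            "mean_ie": mean_ie,
            "mean_ee": float(proj.ee_reads.mean()),
            "quadrant": quadrant if det_p else "",
            "final_class": final,
            "dual_evidence": dual,
            "enrichment_log2": enr,
            "mean_density_all": mean_all,
        })
    return pd.DataFrame(rows)
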
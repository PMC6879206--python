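"""End-to-end orchestration: annotation -> counting -> classification ->
circular-junction search (on free-intron candidates) -> conservation.

Configured from a YAML file; writes a report bundle of TSVs, a run manifest
and a human-readable summary. Repeated runs with the same config and seed
produce byte-identical tables (the manifest carries the only timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignments import (count_all_samples, load_alignments, load_sample_sheet,
                         region_coverage)
from .annotation import (boundary_windows, derive_intron_regions,
                         parse_annotation, write_regions_bed, write_windows_tsv)
from .circjunction import (CircParams, call_junctions, detect_tail_gap,
                           junction_consensus, junction_table)
from .classify import Thresholds, build_region_calls, read_pas_bed
from .conservation import (ScoreTrack, ecdf_table, summaries_table,
                           window_conservation)

log = logging.getLogger(__name__)


@dataclass
class CountingParams:
    min_mapq: int = 10
    flank_exon_nt: int = 50
    boundary_exon_nt: int = 25
    boundary_intron_nt: int = 25
    boundary_mode: str = "straddle"


@dataclass
class ConservationParams:
    window: int = 50
    step: int = 10


@dataclass
class PipelineConfig:
    gtf: str
    genome: str
    sample_sheet: str
    outdir: str
    pas_bed: str | None = None
    ribo_sample_sheet: str | None = None
    conservation_track: str | None = None
    unaligned_fastq: str | None = None
    seed: int = 0
    genome_wide_circ: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    counting: CountingParams = field(default_factory=CountingParams)
    circ: CircParams = field(default_factory=CircParams)
    conservation: ConservationParams = field(default_factory=ConservationParams)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (("thresholds", Thresholds),
                         ("counting", CountingParams),
                         ("circ", CircParams),
                         ("conservation", ConservationParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        for name in ("gtf", "genome", "sample_sheet"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p} does not exist")
        for name in ("pas_bed", "ribo_sample_sheet", "conservation_track",
                     "unaligned_fastq"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p} does not exist")
        load_sample_sheet(self.sample_sheet)  # raises on empty/malformed


@dataclass
class RunResult:
    regions: list
    calls: pd.DataFrame
    junctions: pd.DataFrame
    tail_gaps: pd.DataFrame
    conservation: pd.DataFrame | None
    summary: dict


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute all stages; every intron region appears exactly once in the
    calls table. Stage failures raise after logging the stage name."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    stage = "annotation"
    try:
        annotation = parse_annotation(config.gtf)
        regions = derive_intron_regions(annotation)
        cp = config.counting
        windows = {r.region_id: boundary_windows(
            r, boundary_exon_nt=cp.boundary_exon_nt,
            boundary_intron_nt=cp.boundary_intron_nt,
            flank_exon_nt=cp.flank_exon_nt) for r in regions}
        write_regions_bed(regions, outdir / "intron_regions.bed")
        write_windows_tsv(windows.values(), outdir / "boundary_windows.tsv")

        stage = "counting"
        samples = load_sample_sheet(config.sample_sheet)
        counts = count_all_samples(regions, windows, samples,
                                   min_mapq=cp.min_mapq,
                                   boundary_mode=cp.boundary_mode)
        counts.to_csv(outdir / "region_counts.tsv", sep="\t", index=False,
                      float_format="%.6g")

        stage = "classification"
        pas = read_pas_bed(config.pas_bed) if config.pas_bed else []
        ribo_counts = None
        if config.ribo_sample_sheet:
            ribo_samples = load_sample_sheet(config.ribo_sample_sheet)
            ribo_counts = count_all_samples(regions, windows, ribo_samples,
                                            min_mapq=cp.min_mapq)
            ribo_counts.to_csv(outdir / "ribo_counts.tsv", sep="\t",
                               index=False, float_format="%.6g")
        calls = build_region_calls(regions, counts, pas, ribo_counts,
                                   config.thresholds)
        calls.to_csv(outdir / "region_calls.tsv", sep="\t", index=False,
                     float_format="%.6g")

        stage = "circjunction"
        junctions = pd.DataFrame()
        tail_gaps = pd.DataFrame()
        consensus_paths = []
        candidate_ids = set(
            calls.loc[calls.final_class == "FREE_INTRON_CANDIDATE", "region_id"])
        if config.genome_wide_circ:
            candidates = regions
        else:
            candidates = [r for r in regions if r.region_id in candidate_ids]
        if config.unaligned_fastq and candidates:
            calls_by_region, _ = call_junctions(
                config.unaligned_fastq, config.genome, candidates,
                params=config.circ)
            junctions = junction_table(calls_by_region)
            junctions.to_csv(outdir / "junctions.tsv", sep="\t", index=False,
                             float_format="%.6g")
            by_id = {r.region_id: r for r in regions}
            records = [(by_id[rid], calls_by_region[rid][0].donor_pos)
                       for rid in sorted(calls_by_region)]
            if records:
                matrices = junction_consensus(records, config.genome)
                for anchor, mat in matrices.items():
                    p = outdir / f"consensus_{anchor}.tsv"
                    mat.to_tsv(p)
                    consensus_paths.append(str(p))
        if candidates:
            tail_gaps = _tail_gap_table(candidates, samples, config)
            tail_gaps.to_csv(outdir / "tail_gaps.tsv", sep="\t", index=False,
                             float_format="%.6g")

        stage = "conservation"
        cons_table = None
        if config.conservation_track:
            track = ScoreTrack.open(config.conservation_track)
            label_of = dict(zip(calls.region_id, calls.final_class))
            summaries = [window_conservation(
                track, r, window=config.conservation.window,
                step=config.conservation.step,
                class_label=label_of.get(r.region_id, "")) for r in regions]
            cons_table = summaries_table(summaries)
            cons_table.to_csv(outdir / "conservation_summaries.tsv", sep="\t",
                              index=False, float_format="%.6g")
            ecdf_table(summaries).to_csv(outdir / "conservation_ecdf.tsv",
                                         sep="\t", index=False,
                                         float_format="%.6g")
    except Exception:
        log.exception("pipeline stage '%s' failed; partial outputs in %s",
                      stage, outdir)
        raise

    summary = _summarise(calls, junctions, tail_gaps)
    with open(outdir / "summary.txt", "w") as fh:
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.as_dict(), sort_keys=True).encode()).hexdigest(),
        "elapsed_seconds": round(time.time() - t_start, 3),
        "config": config.as_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return RunResult(regions=regions, calls=calls, junctions=junctions,
                     tail_gaps=tail_gaps, conservation=cons_table,
                     summary=summary)


def _tail_gap_table(candidates, samples, config: PipelineConfig) -> pd.DataFrame:
    """Tail-gap detection from pooled projection coverage over candidates."""
    import numpy as np
    cov = {r.region_id: np.zeros(r.length, dtype=np.int64) for r in candidates}
    known = {r.chrom for r in candidates}
    proj = [s for s in samples if s.compartment == "projection"]
    for sm in proj:
        reads = list(load_alignments(sm.path, sm,
                                     min_mapq=config.counting.min_mapq,
                                     known_chroms=known))
        for r in candidates:
            cov[r.region_id] += region_coverage(r, reads)
    rows = []
    for r in candidates:
        gap, flagged = detect_tail_gap(
            cov[r.region_id], strand=r.strand,
            tail_gap_min_nt=config.circ.tail_gap_min_nt,
            min_body_mean=config.circ.min_body_mean)
        rows.append({"region_id": r.region_id, "gap_length": gap,
                     "flagged": flagged})
    return pd.DataFrame(rows, columns=["region_id", "gap_length", "flagged"])


def _summarise(calls: pd.DataFrame, junctions: pd.DataFrame,
               tail_gaps: pd.DataFrame) -> dict:
    detectable = calls[calls.detectable_projection]
    summary = {
        "n_regions": len(calls),
        "n_detectable_projection": int(calls.detectable_projection.sum()),
        "n_detectable_wholecell": int(calls.detectable_wholecell.sum()),
        "n_projection_only": int(calls.projection_only.sum()),
    }
    for q in ("i", "ii", "iii", "iv"):
        summary[f"n_quadrant_{q}"] = int((detectable.quadrant == q).sum())
    for cls in sorted(calls.final_class.unique()):
        summary[f"n_class_{cls}"] = int((calls.final_class == cls).sum())
    if len(junctions):
        modal = junctions[junctions["rank"] == 1]
        summary["n_regions_with_junctions"] = int(modal.region_id.nunique())
        summary["n_noncanonical_branchpoints"] = int((~modal.canonical).sum())
    else:
        summary["n_regions_with_junctions"] = 0
        summary["n_noncanonical_branchpoints"] = 0
    if len(tail_gaps):
        summary["n_tail_gap_flagged"] = int(tail_gaps.flagged.sum())
    return summary
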
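import numpy as np
import pysam
import pytest

from sisrna.alignments import (ReadAlignment, SampleMeta, count_boundary_reads,
                               count_ee_junction_reads, count_region_reads,
                               count_sample, load_alignments, load_sample_sheet,
                               read_is_ee, read_is_ei, region_coverage)
from sisrna.annotation import IntronRegion, boundary_windows

from oracles import count_reads_allpairs


def make_read(blocks, strand="+", chrom="chr1", read_id="r", **kw):
    return ReadAlignment(read_id=read_id, chrom=chrom, strand=strand,
                         blocks=list(blocks), mapq=50, **kw)


def write_sam(path, records, chrom="chr1", length=100000):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, pos, cigar, mapq, flag in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = cigar
            n = sum(l for op, l in a.cigartuples if op in (0, 1, 4))
            a.query_sequence = "A" * n
            fh.write(a)


class TestLoadAlignments:
    def test_mapq_threshold_inclusive(self, tmp_path):
        path = tmp_path / "a.sam"
        write_sam(path, [("keep", 100, "50M", 10, 0),
                         ("drop", 100, "50M", 9, 0)])
        reads = list(load_alignments(path, min_mapq=10))
        assert [r.read_id for r in reads] == ["keep"]

    def test_gapped_cigar_yields_two_blocks(self, tmp_path):
        path = tmp_path / "a.sam"
        write_sam(path, [("split", 1000, "50M1000N50M", 50, 0)])
        (read,) = load_alignments(path)
        assert read.blocks == [(1000, 1050), (2050, 2100)]

    def test_secondary_and_supplementary_excluded(self, tmp_path):
        path = tmp_path / "a.sam"
        write_sam(path, [("sec", 100, "50M", 50, 256),
                         ("sup", 100, "50M", 50, 2048),
                         ("ok", 100, "50M", 50, 0)])
        assert [r.read_id for r in load_alignments(path)] == ["ok"]

    def test_reverse_flag_and_strandedness(self, tmp_path):
        path = tmp_path / "a.sam"
        write_sam(path, [("rev", 100, "50M", 50, 16)])
        fwd_meta = SampleMeta("s", "projection", 1, str(path), "forward")
        rev_meta = SampleMeta("s", "projection", 1, str(path), "reverse")
        (r1,) = load_alignments(path, fwd_meta)
        (r2,) = load_alignments(path, rev_meta)
        assert r1.strand == "-" and r2.strand == "+"

    def test_unknown_chromosome_skipped(self, tmp_path):
        path = tmp_path / "a.sam"
        write_sam(path, [("r", 100, "50M", 50, 0)])
        assert list(load_alignments(path, known_chroms={"chr2"})) == []

    def test_empty_sample_sheet_rejected(self, tmp_path):
        p = tmp_path / "sheet.tsv"
        p.write_text("sample_id\tcompartment\treplicate\tpath\tstrandedness\n")
        with pytest.raises(ValueError, match="no samples"):
            load_sample_sheet(p)


class TestBodyCounting:
    region = IntronRegion("g:E1", "g", "chr1", "+", 1000, 2000)

    def test_density_at_threshold_value(self):
        reads = [make_read([(1500, 1600)], read_id=f"r{i}") for i in range(5)]
        counts = count_region_reads([self.region], reads)
        assert counts["g:E1"] == 5           # density 5/1000 = 0.005

    def test_gap_only_overlap_not_counted(self):
        read = make_read([(900, 1000), (2000, 2100)])   # gap spans the region
        assert count_region_reads([self.region], [read])["g:E1"] == 0

    def test_strand_mismatch_not_counted(self):
        read = make_read([(1500, 1600)], strand="-")
        assert count_region_reads([self.region], [read])["g:E1"] == 0

    def test_one_base_overlap_counts(self):
        read = make_read([(999, 1001)])
        assert count_region_reads([self.region], [read])["g:E1"] == 1


class TestBoundaryCounting:
    region = IntronRegion("g:E1", "g", "chr1", "+", 100, 200)

    def windows(self):
        return boundary_windows(self.region)

    def test_block_straddling_ei_boundary(self):
        w = self.windows()
        counts = count_boundary_reads([w], [make_read([(90, 140)])])
        assert counts["g:E1"] == (1, 0)

    def test_split_read_over_intron_is_neither(self):
        w = self.windows()
        counts = count_boundary_reads([w], [make_read([(80, 100), (200, 240)])])
        assert counts["g:E1"] == (0, 0)

    def test_block_touching_boundary_without_crossing(self):
        w = self.windows()
        # ends exactly at the boundary: no intronic base covered
        counts = count_boundary_reads([w], [make_read([(60, 100)])])
        assert counts["g:E1"] == (0, 0)

    def test_minus_strand_ei_at_high_coordinate(self):
        region = IntronRegion("g:E1", "g", "chr1", "-", 100, 200)
        w = boundary_windows(region)
        counts = count_boundary_reads([w], [make_read([(190, 240)], strand="-")])
        assert counts["g:E1"] == (1, 0)

    def test_overlap_mode_counts_window_overlap(self):
        w = self.windows()
        read = make_read([(110, 120)])      # inside EI window, no straddle
        assert count_boundary_reads([w], [read])["g:E1"] == (0, 0)
        assert count_boundary_reads([w], [read],
                                    boundary_mode="overlap")["g:E1"] == (1, 0)


class TestEECounting:
    region = IntronRegion("g:E1", "g", "chr1", "+", 100, 200)

    def test_exact_gap_in_flanks_counted(self):
        w = boundary_windows(self.region)
        read = make_read([(60, 100), (200, 250)])
        assert count_ee_junction_reads(self.region, w, [read]) == 1

    def test_shifted_gap_not_counted(self):
        w = boundary_windows(self.region)
        read = make_read([(60, 105), (205, 260)])
        assert count_ee_junction_reads(self.region, w, [read]) == 0

    def test_endpoints_outside_flanks_not_counted(self):
        w = boundary_windows(self.region)   # flanks [50,100) and [200,250)
        read = make_read([(40, 100), (200, 260)])
        assert count_ee_junction_reads(self.region, w, [read]) == 0

    def test_gapless_read_not_ee(self):
        w = boundary_windows(self.region)
        assert not read_is_ee(make_read([(90, 210)]), self.region, w)

    def test_ei_and_ee_mutually_exclusive_per_boundary(self):
        w = boundary_windows(self.region)
        for read in (make_read([(90, 140)]), make_read([(60, 100), (200, 250)])):
            assert int(read_is_ei(read, w)) + int(read_is_ee(read, self.region, w)) == 1


def _random_reads(rng, n, chrom="chr1", lo=0, hi=20000):
    reads = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        n_blocks = int(rng.integers(1, 4))
        pos = int(rng.integers(lo, hi))
        blocks = []
        for _ in range(n_blocks):
            length = int(rng.integers(20, 120))
            blocks.append((pos, pos + length))
            pos += length + int(rng.integers(1, 500))
        reads.append(make_read(blocks, strand=strand, read_id=f"r{i}"))
    return reads


def _random_regions(rng, n, chrom="chr1", lo=0, hi=20000):
    regions = []
    for i in range(n):
        start = int(rng.integers(lo, hi - 600))
        length = int(rng.integers(60, 600))
        strand = "+" if rng.random() < 0.5 else "-"
        regions.append(IntronRegion(f"R{i}", f"G{i}", chrom, strand,
                                    start, start + length))
    return regions


class TestAgainstAllPairsOracle:
    def test_counts_match_oracle(self, rng):
        regions = _random_regions(rng, 30)
        reads = _random_reads(rng, 1500)
        # add exact-junction EE reads for a handful of regions
        for i, r in enumerate(regions[:10]):
            reads.append(make_read([(r.start - 40, r.start), (r.end, r.end + 40)],
                                   strand=r.strand, read_id=f"ee{i}"))
        windows = {r.region_id: boundary_windows(r) for r in regions}
        table = count_sample(regions, windows, reads).set_index("region_id")
        expected = count_reads_allpairs(regions, reads)
        for r in regions:
            row = table.loc[r.region_id]
            exp = expected[r.region_id]
            assert (row.body_reads, row.ei_reads, row.ie_reads, row.ee_reads) \
                == (exp["body"], exp["ei"], exp["ie"], exp["ee"])
            assert row.body_density == exp["body"] / r.length

    def test_order_independence(self, rng):
        regions = _random_regions(rng, 20)
        reads = _random_reads(rng, 500)
        windows = {r.region_id: boundary_windows(r) for r in regions}
        a = count_sample(regions, windows, reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        b = count_sample(regions, windows, shuffled)
        assert a.equals(b)


def test_region_coverage_from_blocks():
    region = IntronRegion("g:E1", "g", "chr1", "+", 100, 110)
    reads = [make_read([(95, 105)]), make_read([(103, 120)]),
             make_read([(95, 105)], strand="-")]
    cov = region_coverage(region, reads)
    assert cov.tolist() == [1, 1, 1, 2, 2, 1, 1, 1, 1, 1]
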
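import math

import numpy as np
import pytest

from sisrna.annotation import IntronRegion
from sisrna.circjunction import (CircJunction, CircParams, call_branchpoint,
                                 call_junctions, column_information,
                                 consensus_from_sequences, detect_tail_gap,
                                 find_permuted_candidates, junction_consensus,
                                 refine_breakpoint, revcomp)
from sisrna.synthetic import (Scenario, ScenarioSpec, build_reference,
                              simulate_permuted_reads)


def toy_genome(rng, n=2000, chrom="chrX"):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    return {chrom: seq}


@pytest.fixture()
def toy(rng):
    """Toy genome with one + strand intron region [500, 900); branchpoint at
    875 (25 nt from the 3'SS)."""
    genome = toy_genome(rng)
    region = IntronRegion("t:E1", "t", "chrX", "+", 500, 900)
    return genome, region, 875


def lariat_read(genome, region, bp, read_len=100, split=80):
    """Circularly permuted read: ends at the branchpoint, wraps to the
    intron 5' start."""
    seq = genome[region.chrom]
    left = seq[bp + 1 - split: bp + 1]
    right = seq[region.start: region.start + read_len - split]
    return left + right


class TestAnchorSearch:
    def test_permuted_read_yields_one_candidate(self, toy):
        genome, region, bp = toy
        read = lariat_read(genome, region, bp)
        cands = find_permuted_candidates([("r1", read)], genome, [region])
        assert len(cands) == 1
        assert cands[0].p1 > cands[0].p2        # permuted anchor order

    def test_colinear_read_rejected(self, toy):
        genome, region, _ = toy
        read = genome["chrX"][600:700]
        assert find_permuted_candidates([("r1", read)], genome, [region]) == []

    def test_read_outside_candidate_regions_rejected(self, toy):
        genome, region, bp = toy
        other = {"chrY": genome["chrX"]}        # same sequence, other chrom
        read = lariat_read(genome, region, bp)
        cands = find_permuted_candidates(
            [("r1", read)], {**genome, "chrY": "A" * 2000},
            [IntronRegion("y:E1", "y", "chrY", "+", 500, 900)])
        assert cands == []

    def test_short_read_skipped(self, toy):
        genome, region, _ = toy
        assert find_permuted_candidates([("r1", "ACGT" * 5)], genome,
                                        [region]) == []


class TestBreakpointRefinement:
    def test_error_free_read_recovers_exact_junction(self, toy):
        genome, region, bp = toy
        for split in (25, 50, 80):
            read = lariat_read(genome, region, bp, split=split)
            (cand,) = find_permuted_candidates([("r", read)], genome, [region])
            j = refine_breakpoint(cand)
            assert j is not None
            assert j.donor_pos == bp
            assert j.acceptor_pos == region.start
            assert j.dist_to_3ss == 25
            assert j.total_mismatches == 0

    def test_branchpoint_mismatch_recovered_and_counted(self, toy):
        genome, region, bp = toy
        read = lariat_read(genome, region, bp, split=60)
        true_base = read[59]
        sub = next(b for b in "ACGT" if b != true_base)
        read = read[:59] + sub + read[60:]
        (cand,) = find_permuted_candidates([("r", read)], genome, [region])
        j = refine_breakpoint(cand)
        assert j is not None
        assert (j.donor_pos, j.acceptor_pos) == (bp, region.start)
        assert j.junction_mismatches >= 1

    def test_scattered_errors_exceed_budget(self, toy):
        genome, region, bp = toy
        read = list(lariat_read(genome, region, bp, split=60))
        # three errors in each read half, away from the anchors: every
        # candidate split sees at least three true mismatches
        for pos in (30, 40, 50, 62, 66, 70):
            read[pos] = next(b for b in "ACGT" if b != read[pos])
        (cand,) = find_permuted_candidates(
            [("r", "".join(read))], genome, [region])
        # anchors still clean but 5 mismatches > budget of 2
        assert cand is not None
        assert refine_breakpoint(cand) is None


class TestBranchpointCalling:
    def make_junction(self, donor, acceptor, read_id):
        return CircJunction(region_id="t:E1", chrom="chrX", strand="+",
                            acceptor_pos=acceptor, donor_pos=donor,
                            bp_base="C", dist_to_3ss=25, read_id=read_id,
                            total_mismatches=0, junction_mismatches=0)

    def test_two_populations_ranked_by_support(self):
        js = ([self.make_junction(875, 500, f"a{i}") for i in range(7)]
              + [self.make_junction(850, 500, f"b{i}") for i in range(3)])
        calls = call_branchpoint(js)
        assert [(c.donor_pos, c.support) for c in calls] == [(875, 7), (850, 3)]

    def test_canonical_flag_tracks_base(self):
        j = self.make_junction(875, 500, "r")
        assert not call_branchpoint([j])[0].canonical
        j2 = CircJunction(region_id="t:E1", chrom="chrX", strand="+",
                          acceptor_pos=500, donor_pos=875, bp_base="A",
                          dist_to_3ss=25, read_id="r", total_mismatches=0,
                          junction_mismatches=0)
        assert call_branchpoint([j2])[0].canonical

    def test_no_junctions_is_an_error(self):
        with pytest.raises(ValueError):
            call_branchpoint([])


class TestStrandInvariance:
    def test_bp_base_and_distance_invariant_under_strand_flip(self, tmp_path):
        calls = {}
        for strand in "+-":
            spec = ScenarioSpec(scenario=Scenario.FREE_CIRCULAR_INTRON,
                                strand=strand, bp_mismatch_prob=0.0)
            ref = build_reference([spec], 77, tmp_path / f"s{strand}")
            reads = simulate_permuted_reads(ref, 78)
            assert reads
            by_region, _ = call_junctions(reads, ref.genome_path,
                                          ref.regions())
            (ranked,) = by_region.values()
            calls[strand] = ranked[0]
        assert calls["+"].bp_base == calls["-"].bp_base == "C"
        assert calls["+"].dist_to_3ss == calls["-"].dist_to_3ss == 25
        truth_plus = build_reference(
            [ScenarioSpec(scenario=Scenario.FREE_CIRCULAR_INTRON, strand="+")],
            77, tmp_path / "truth").loci[0].bp_genomic()
        assert calls["+"].donor_pos == truth_plus


class TestTailGap:
    def test_tail_gap_detected(self):
        cov = np.concatenate([np.full(375, 10), np.zeros(25)])
        gap, flagged = detect_tail_gap(cov)
        assert gap == 25 and flagged

    def test_uniform_coverage_not_flagged(self):
        gap, flagged = detect_tail_gap(np.full(400, 5))
        assert gap == 0 and not flagged

    def test_silent_region_not_flagged(self):
        gap, flagged = detect_tail_gap(np.zeros(400))
        assert gap == 400 and not flagged

    def test_minus_strand_gap_at_genomic_start(self):
        cov = np.concatenate([np.zeros(25), np.full(375, 10)])
        gap, flagged = detect_tail_gap(cov, strand="-")
        assert gap == 25 and flagged

    def test_short_gap_below_threshold_not_flagged(self):
        cov = np.concatenate([np.full(390, 10), np.zeros(10)])
        gap, flagged = detect_tail_gap(cov, tail_gap_min_nt=15)
        assert gap == 10 and not flagged


class TestConsensus:
    def test_identical_sequences_give_two_bits(self):
        mat = consensus_from_sequences(["ACGT"] * 8, lo=0)
        assert np.allclose(mat.information_content, 2.0)

    def test_uniform_composition_gives_zero_bits(self):
        mat = consensus_from_sequences(["A", "C", "G", "T"], lo=0)
        assert np.allclose(mat.information_content, 0.0)

    def test_branchpoint_composition_information(self):
        # 12 C + 2 G at one offset
        ic = column_information([0, 12, 2, 0])
        expected = 2 + (12 / 14) * math.log2(12 / 14) \
            + (2 / 14) * math.log2(2 / 14)
        assert ic == pytest.approx(expected, abs=1e-12)

    def test_n_bases_excluded_from_counts(self):
        mat = consensus_from_sequences(["AN", "AN", "AC"], lo=-1)
        assert mat.counts.iloc[0].sum() == 3
        assert mat.counts.iloc[1].sum() == 1
        assert mat.offsets == [-1, 0]

    def test_anchor_windows_extract_splice_site_motifs(self, tmp_path):
        spec = ScenarioSpec(scenario=Scenario.FREE_CIRCULAR_INTRON)
        ref = build_reference([spec], 5, tmp_path)
        (region,) = ref.regions()
        bp = ref.loci[0].bp_genomic()
        mats = junction_consensus([(region, bp)], ref.genome_path)
        five = mats["five_prime_ss"]
        # offsets 0,1 are the GT dinucleotide of the 5' splice site
        assert five.counts.loc[five.offsets.index(0), "G"] == 1
        assert five.counts.loc[five.offsets.index(1), "T"] == 1
        three = mats["three_prime_ss"]
        assert three.counts.loc[three.offsets.index(-1), "A"] == 1
        assert three.counts.loc[three.offsets.index(0), "G"] == 1
        bp_mat = mats["branchpoint"]
        assert bp_mat.counts.loc[bp_mat.offsets.index(0), "C"] == 1
        assert bp_mat.counts.loc[bp_mat.offsets.index(-1), "C"] == 1


def test_revcomp():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"
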
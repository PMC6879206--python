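"""Call a lariat branchpoint from circularly permuted reads.

A stable excised intron with a C branchpoint resists debranching; reverse
transcriptase occasionally reads through the 2'-5' bond, yielding reads
whose halves map in inverted order (branchpoint side upstream in the read,
intron 5' end downstream). Anchor mapping plus breakpoint refinement
recovers the branchpoint coordinate and base.
"""

import tempfile

from sisrna import (Scenario, ScenarioSpec, build_reference, call_junctions,
                    simulate_permuted_reads)

spec = ScenarioSpec(scenario=Scenario.FREE_CIRCULAR_INTRON, expression=200,
                    readthrough_rate=0.05, bp_mismatch_prob=0.3,
                    bp_base="C", bp_offset_from_3ss=25)

with tempfile.TemporaryDirectory() as tmp:
    ref = build_reference([spec], seed=21, outdir=tmp)
    reads = simulate_permuted_reads(ref, seed=22)
    print(f"{len(reads)} circularly permuted reads simulated")
    calls, accepted = call_junctions(reads, ref.genome_path, ref.regions())
    truth_bp = ref.loci[0].bp_genomic()
    for region_id, ranked in calls.items():
        for call in ranked:
            print(f"  {region_id}: donor {call.donor_pos} "
                  f"(truth {truth_bp}), acceptor {call.acceptor_pos}, "
                  f"base {call.bp_base}, {call.dist_to_3ss} nt from 3'SS, "
                  f"support {call.support}, "
                  f"canonical={call.canonical}")
print()
print("The modal junction pinpoints the branchpoint: a non-canonical C,")
print("25 nt upstream of the 3' splice site. Mismatches concentrate at the")
print("junction because the polymerase traverses the branch with low")
print("fidelity; minority junctions from those errors rank below the modal")
print("one.")
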
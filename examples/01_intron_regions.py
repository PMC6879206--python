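"""Derive intron regions from a small two-isoform annotation.

An intron region is a maximal interval that no isoform of the gene shows as
exonic. Here isoform t2 has an extra exon [250,300) inside the first intron
of t1, so only the parts intronic in *both* isoforms survive.
"""

import io

from sisrna import boundary_windows, derive_intron_regions, parse_annotation

GTF = """\
chr1\tdemo\texon\t1\t100\t.\t+\t.\tgene_id "demo"; transcript_id "t1";
chr1\tdemo\texon\t201\t300\t.\t+\t.\tgene_id "demo"; transcript_id "t1";
chr1\tdemo\texon\t401\t500\t.\t+\t.\tgene_id "demo"; transcript_id "t1";
chr1\tdemo\texon\t1\t100\t.\t+\t.\tgene_id "demo"; transcript_id "t2";
chr1\tdemo\texon\t251\t300\t.\t+\t.\tgene_id "demo"; transcript_id "t2";
chr1\tdemo\texon\t401\t500\t.\t+\t.\tgene_id "demo"; transcript_id "t2";
"""

annotation = parse_annotation(io.StringIO(GTF))
regions = derive_intron_regions(annotation)
print("intron regions (0-based half-open):")
for r in regions:
    w = boundary_windows(r)
    print(f"  {r.region_id}: [{r.start},{r.end}) length {r.length}  "
          f"EI window {w.ei_window}  IE window {w.ie_window}")
print()
print("The interval [200,250) is excluded: it is exonic in t2, so it is not")
print("intronic in every isoform spanning it. Each region's EI/IE windows")
print("cover 25 exonic + 25 intronic nt around the splice sites.")
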
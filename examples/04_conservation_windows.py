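"""Summarise per-base conservation over regions with sliding windows and
compare classes by empirical CDF.

Scores are averaged over 50-nt windows with 10-nt steps; each region is
summarised by the median of its window means. Conserved exon-like regions
separate cleanly from unconserved free-intron-like regions in the ECDF.
"""

import numpy as np

from sisrna import ScoreTrack, ecdf_table, window_conservation
from sisrna.annotation import IntronRegion

rng = np.random.default_rng(5)
n = 20000
starts = np.arange(0, n, 10)
# conserved block [0, 10000): scores ~ N(1.8, 0.3); rest ~ N(0, 0.2)
values = np.where(starts < 10000, rng.normal(1.8, 0.3, len(starts)),
                  rng.normal(0.0, 0.2, len(starts)))
track = ScoreTrack({"chr1": (starts, starts + 10, values)})

summaries = []
for i in range(30):
    s = int(rng.integers(0, 9000))
    summaries.append(window_conservation(
        track, IntronRegion(f"e{i}", "g", "chr1", "+", s, s + 400),
        class_label="exon_like"))
    s = int(rng.integers(10000, 19000))
    summaries.append(window_conservation(
        track, IntronRegion(f"f{i}", "g", "chr1", "+", s, s + 400),
        class_label="free_intron_like"))

first = summaries[0]
print(f"example region {first.region_id}: {first.n_windows} windows, "
      f"median window mean {first.region_median:.3f}")

table = ecdf_table(summaries)
for label, sub in table.groupby("class_label"):
    med = sub.region_median.median()
    print(f"{label}: n={len(sub)}, median of region medians {med:.3f}")
print()
print("Medians near 1.8 vs near 0 reproduce the qualitative contrast")
print("between conserved exons and unconserved free introns; the ECDF")
print("table has one nondecreasing cumulative curve per class.")
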
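"""Per-base conservation summarisation: sliding-window means, region
medians, and per-class empirical CDFs.

Windows of ``window`` nt are tiled from the region start with ``step`` nt
stride, fully inside the region; trailing bases that do not fill a final
full window are dropped (regions shorter than one window get a single
window spanning the whole region). Window means ignore uncovered bases;
fully uncovered windows are dropped. The region summary statistic is the
median of window means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import IntronRegion


class ScoreTrack:
    """Sparse per-base score track with NaN for uncovered bases."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), sorted non-overlapping intervals
        self._data = data

    @classmethod
    def from_bedgraph(cls, path: Union[str, Path]) -> "ScoreTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        data = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            data[str(chrom)] = (sub.start.to_numpy(np.int64),
                                sub.end.to_numpy(np.int64),
                                sub.value.to_numpy(np.float64))
        return cls(data)

    @classmethod
    def from_bigwig(cls, path: Union[str, Path]) -> "ScoreTrack":
        import pyBigWig
        bw = pyBigWig.open(str(path))
        data = {}
        for chrom, length in bw.chroms().items():
            ivs = bw.intervals(chrom) or []
            data[chrom] = (np.array([i[0] for i in ivs], dtype=np.int64),
                           np.array([i[1] for i in ivs], dtype=np.int64),
                           np.array([i[2] for i in ivs], dtype=np.float64))
        bw.close()
        return cls(data)

    @classmethod
    def open(cls, path: Union[str, Path]) -> "ScoreTrack":
        p = str(path)
        if p.endswith((".bw", ".bigwig", ".bigWig")):
            return cls.from_bigwig(p)
        return cls.from_bedgraph(p)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are NaN."""
        out = np.full(end - start, np.nan)
        if chrom not in self._data:
            return out
        starts, ends, vals = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(starts[i], start) - start
            e = min(ends[i], end) - start
            if s < e:
                out[s:e] = vals[i]
        return out


@dataclass
class ConservationSummary:
    region_id: str
    n_windows: int
    window_means: list[float]
    region_median: float       # NaN when no covered window
    class_label: str = ""


def window_positions(length: int, window: int = 50, step: int = 10) -> list[tuple[int, int]]:
    """Region-relative window intervals; a region shorter than one window
    yields a single whole-region window."""
    if length < window:
        return [(0, length)]
    return [(s, s + window) for s in range(0, length - window + 1, step)]


def window_conservation(track: ScoreTrack, region: IntronRegion,
                        window: int = 50, step: int = 10,
                        class_label: str = "") -> ConservationSummary:
    """Sliding-window mean conservation and region median for one region."""
    scores = track.values(region.chrom, region.start, region.end)
    means = []
    for s, e in window_positions(region.length, window, step):
        vals = scores[s:e]
        if np.all(np.isnan(vals)):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means.append(float(np.nanmean(vals)))
    median = float(np.median(means)) if means else float("nan")
    return ConservationSummary(
        region_id=region.region_id,
        n_windows=len(means),
        window_means=means,
        region_median=median,
        class_label=class_label,
    )


def summaries_table(summaries: Iterable[ConservationSummary]) -> pd.DataFrame:
    rows = [{
        "region_id": s.region_id,
        "class_label": s.class_label,
        "n_windows": s.n_windows,
        "region_median": s.region_median,
    } for s in summaries]
    return pd.DataFrame(rows, columns=["region_id", "class_label",
                                       "n_windows", "region_median"])


def ecdf_table(summaries: Iterable[ConservationSummary]) -> pd.DataFrame:
    """Per-class empirical CDF of region medians: sorted values with
    cumulative fractions. NaN medians are excluded."""
    by_class: dict[str, list[float]] = {}
    for s in summaries:
        if np.isnan(s.region_median):
            continue
        by_class.setdefault(s.class_label, []).append(s.region_median)
    rows = []
    for label in sorted(by_class):
        vals = sorted(by_class[label])
        n = len(vals)
        for i, v in enumerate(vals, start=1):
            rows.append({"class_label": label, "region_median": v,
                         "cumulative_fraction": i / n})
    return pd.DataFrame(rows, columns=["class_label", "region_median",
                                       "cumulative_fraction"])
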
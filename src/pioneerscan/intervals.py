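"""Half-open interval overlap machinery shared by the analysis modules.

bedtools-style semantics: two intervals overlap when they share at least
one base under 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .core_model import GenomeInterval, Peak, as_interval

__all__ = ["IntervalIndex", "merge_intervals", "overlap_bases"]


def overlap_bases(a: GenomeInterval | Peak, b: GenomeInterval | Peak) -> int:
    a, b = as_interval(a), as_interval(b)
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Sequence[GenomeInterval | Peak], join_bookended: bool = True
) -> list[GenomeInterval]:
    """Merge overlapping (and, by default, touching) intervals per chromosome."""
    ivs = sorted(
        (as_interval(i) for i in intervals), key=lambda i: (i.chrom, i.start, i.end)
    )
    out: list[GenomeInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and (
            iv.start < out[-1].end or (join_bookended and iv.start == out[-1].end)
        ):
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(replace(iv, name=None, score=None, strand="."))
    return out


class IntervalIndex:
    """Sorted per-chromosome index over raw intervals.

    ``max_overlap`` returns the largest number of bases the query shares
    with any single indexed interval, so ``overlaps(q, k)`` is the
    bedtools-style "overlaps some interval by >= k bases" test.
    """

    def __init__(self, intervals: Sequence[GenomeInterval | Peak]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomeInterval]] = {}
        for item in intervals:
            iv = as_interval(item)
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda i: (i.start, i.end))
            self._starts[chrom] = np.array([i.start for i in ivs])
            self._ends[chrom] = np.array([i.end for i in ivs])

    def max_overlap(self, query: GenomeInterval | Peak) -> int:
        """Largest single-interval overlap (in bases) with the query."""
        q = as_interval(query)
        starts = self._starts.get(q.chrom)
        if starts is None or len(starts) == 0:
            return 0
        ends = self._ends[q.chrom]
        # candidates: indexed intervals starting before query end
        hi = int(np.searchsorted(starts, q.end, side="left"))
        if hi == 0:
            return 0
        ov = np.minimum(ends[:hi], q.end) - np.maximum(starts[:hi], q.start)
        return int(ov.max(initial=0))

    def overlaps(self, query: GenomeInterval | Peak, min_overlap: int = 1) -> bool:
        return self.max_overlap(query) >= min_overlap
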
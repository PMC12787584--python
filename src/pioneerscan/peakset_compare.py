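"""Replicate consensus and condition-versus-condition peak comparison.

Consensus peaks are those detected in all biological replicates.  When two
conditions are compared, a peak is *shared* if detected in at least one
replicate of each condition and *unique* to a condition if present in all
of its replicates and absent from every replicate of the other.  Retained
and gained percentages use the first (baseline) condition's consensus peak
count as denominator — the only convention under which a gained percentage
above 100% is possible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import GenomeInterval, Peak, as_interval
from .intervals import IntervalIndex, merge_intervals

__all__ = [
    "PeakComparison",
    "consensus_peaks",
    "compare_conditions",
    "reference_overlap",
]

PeakList = list  # list[Peak | GenomeInterval]


@dataclass
class PeakComparison:
    shared: PeakList
    unique_a: PeakList
    unique_b: PeakList
    retained_pct: float
    gained_pct: float
    n_consensus_a: int
    n_consensus_b: int


def consensus_peaks(replicates: list[PeakList], min_overlap: int = 1) -> PeakList:
    """Peaks detected in every replicate.

    A replicate-1 peak is retained iff it overlaps >= ``min_overlap`` bases
    with at least one peak of every other replicate; retained peaks keep
    replicate-1 coordinates.
    """
    if not replicates:
        raise ValueError("empty replicate list")
    if len(replicates) == 1:
        return list(replicates[0])
    indexes = [IntervalIndex(rep) for rep in replicates[1:]]
    return [
        p
        for p in replicates[0]
        if all(ix.overlaps(p, min_overlap) for ix in indexes)
    ]


def _detected_in_any(peak, replicate_indexes: list[IntervalIndex]) -> bool:
    return any(ix.overlaps(peak) for ix in replicate_indexes)


def compare_conditions(
    a_reps: list[PeakList], b_reps: list[PeakList]
) -> PeakComparison:
    """Shared/unique peak logic between two conditions (A = baseline).

    shared: union of both consensus sets, deduplicated by overlap keeping
    A's coordinates, restricted to loci detected in >=1 replicate of each
    condition.  unique_a: in all A replicates, in no B replicate (unique_b
    symmetric).  retained_pct = 100·|A consensus also detected in B| / |A
    consensus|; gained_pct = 100·|unique_b| / |A consensus|.
    """
    if not a_reps or not b_reps:
        raise ValueError("each condition needs >= 1 replicate")
    ca = consensus_peaks(a_reps)
    cb = consensus_peaks(b_reps)
    a_idx = [IntervalIndex(rep) for rep in a_reps]
    b_idx = [IntervalIndex(rep) for rep in b_reps]

    a_in_b = [p for p in ca if _detected_in_any(p, b_idx)]
    unique_a = [p for p in ca if not _detected_in_any(p, b_idx)]
    unique_b = [p for p in cb if not _detected_in_any(p, a_idx)]

    # union deduplication: B consensus loci already represented by an A
    # consensus peak keep A's coordinates via a_in_b
    ca_index = IntervalIndex(ca)
    shared = a_in_b + [
        p for p in cb if _detected_in_any(p, a_idx) and not ca_index.overlaps(p)
    ]

    n_a = len(ca)
    retained = 100.0 * len(a_in_b) / n_a if n_a else 0.0
    gained = 100.0 * len(unique_b) / n_a if n_a else 0.0
    return PeakComparison(
        shared=shared,
        unique_a=unique_a,
        unique_b=unique_b,
        retained_pct=retained,
        gained_pct=gained,
        n_consensus_a=n_a,
        n_consensus_b=len(cb),
    )


def reference_overlap(
    a_reps: list[PeakList],
    b_reps: list[PeakList],
    reference: PeakList,
) -> dict[str, int]:
    """Gained/shared/lost counts against an external reference peak set.

    Each condition's peaks are first restricted to those overlapping the
    merged reference, then compared with the shared/unique rules: shared =
    reference-overlapping loci detected in both conditions, gained = in B
    only, lost = in A only.
    """
    if not reference:
        return {"gained": 0, "shared": 0, "lost": 0}
    ref_index = IntervalIndex(merge_intervals([as_interval(r) for r in reference]))
    a_restricted = [[p for p in rep if ref_index.overlaps(p)] for rep in a_reps]
    b_restricted = [[p for p in rep if ref_index.overlaps(p)] for rep in b_reps]
    cmp = compare_conditions(a_restricted, b_restricted)
    return {
        "gained": len(cmp.unique_b),
        "shared": len(cmp.shared),
        "lost": len(cmp.unique_a),
    }
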
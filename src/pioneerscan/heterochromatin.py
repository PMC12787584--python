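"""Heterochromatin targeting and local-density subtypes.

Binding sites that fall inside broad H3K9me3 or H3K27me3 domains are
classified by the ratio of repressive-mark signal at the site to its
flanks: *high* local density (mark focally enriched beneath the peak),
*moderate* (site as enriched as the surrounding domain) or *low* (site in
a local gap of the domain).  The window geometry and ratio thresholds are
an explicit operationalization of a grouping that is otherwise visual;
both are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import GenomeInterval, Peak, SignalTrack, as_interval
from .intervals import IntervalIndex, merge_intervals
from .signal_ops import central_window_mean

__all__ = [
    "HeteroDomain",
    "LocalDensityCall",
    "intersect_domains",
    "local_density",
    "classify_local_density",
    "factor_subtype_summary",
    "track_epsilon",
]

MARKS = ("H3K9me3", "H3K27me3")
SUBTYPES = ("high", "moderate", "low")


@dataclass(frozen=True)
class HeteroDomain:
    interval: GenomeInterval
    mark: str

    def __post_init__(self):
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}")


@dataclass
class LocalDensityCall:
    peak: Peak | GenomeInterval
    mark: str
    center_signal: float
    flank_signal: float
    ratio: float
    subtype: str  # high | moderate | low


def intersect_domains(
    peaks: list[Peak | GenomeInterval],
    domains: list[HeteroDomain],
) -> dict[str, list[Peak | GenomeInterval]]:
    """Assign peaks to marks by >=1-base overlap with merged domains.

    Domains of each mark are merged (bookended intervals joined) before
    intersection; a peak may carry both marks.
    """
    out: dict[str, list[Peak | GenomeInterval]] = {m: [] for m in MARKS}
    for mark in MARKS:
        merged = merge_intervals([d.interval for d in domains if d.mark == mark])
        if not merged:
            continue
        index = IntervalIndex(merged)
        out[mark] = [p for p in peaks if index.overlaps(p)]
    return out


def track_epsilon(track: SignalTrack) -> float:
    """Ratio-stabilizing pseudo-signal: 1% of the median nonzero value.

    Scales with the track, so subtype calls are invariant under uniform
    rescaling of the mark signal.
    """
    nonzero = np.concatenate(
        [v[v > 0] for v in track.values.values()] or [np.zeros(1)]
    )
    if nonzero.size == 0:
        return 0.0
    return 0.01 * float(np.median(nonzero))


def local_density(
    peak: Peak | GenomeInterval,
    mark_track: SignalTrack,
    mark: str,
    center_width: int = 1_000,
    flank_offset: int = 5_000,
    flank_width: int = 2_000,
    ratio_high: float = 1.5,
    ratio_low: float = 0.67,
    epsilon: float | None = None,
) -> LocalDensityCall:
    """Classify one heterochromatin-overlapping site by center/flank ratio.

    center_signal is the mean mark signal over a ``center_width`` window on
    the peak center; flank_signal averages two ``flank_width`` windows at
    ±``flank_offset``, clipped at chromosome bounds.  subtype is high when
    ratio >= ratio_high, low when ratio <= ratio_low, else moderate.
    """
    if epsilon is None:
        epsilon = track_epsilon(mark_track)
    iv = as_interval(peak)
    c = iv.center
    center_signal, _ = central_window_mean(mark_track, iv, center_width)
    chrom_len = mark_track.genome.length(iv.chrom)
    flank_means = []
    for sign in (-1, 1):
        fc = c + sign * flank_offset
        ws = max(0, fc - flank_width // 2)
        we = min(chrom_len, fc - flank_width // 2 + flank_width)
        if we > ws:
            m, _ = central_window_mean(
                mark_track, GenomeInterval(iv.chrom, ws, we), flank_width
            )
            flank_means.append(m)
    flank_signal = float(np.mean(flank_means)) if flank_means else 0.0
    ratio = center_signal / (flank_signal + epsilon)
    if ratio >= ratio_high:
        subtype = "high"
    elif ratio <= ratio_low:
        subtype = "low"
    else:
        subtype = "moderate"
    return LocalDensityCall(peak, mark, center_signal, flank_signal, ratio, subtype)


def classify_local_density(
    peaks: list[Peak | GenomeInterval],
    mark_track: SignalTrack,
    mark: str,
    **kwargs,
) -> list[LocalDensityCall]:
    """Batch local-density classification with the epsilon computed once."""
    eps = kwargs.pop("epsilon", None)
    if eps is None:
        eps = track_epsilon(mark_track)
    return [local_density(p, mark_track, mark, epsilon=eps, **kwargs) for p in peaks]


def factor_subtype_summary(
    calls: list[LocalDensityCall],
) -> tuple[dict[str, dict[str, float]], str]:
    """Per-mark subtype fractions and the factor's majority subtype.

    Majority is over all calls; ties break high > moderate > low.
    """
    if not calls:
        raise ValueError("no local-density calls")
    fractions: dict[str, dict[str, float]] = {}
    for mark in MARKS:
        mark_calls = [c for c in calls if c.mark == mark]
        if not mark_calls:
            continue
        fractions[mark] = {
            s: sum(c.subtype == s for c in mark_calls) / len(mark_calls)
            for s in SUBTYPES
        }
    totals = {s: sum(c.subtype == s for c in calls) for s in SUBTYPES}
    majority = max(SUBTYPES, key=lambda s: (totals[s], -SUBTYPES.index(s)))
    return fractions, majority
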
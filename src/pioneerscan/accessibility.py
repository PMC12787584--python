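"""Peak and motif classification by preexisting chromatin accessibility.

Binding sites are split into DNase-accessible versus DNase-resistant
chromatin at a fixed RPM cutoff (0.05 by default; an exact tie is called
resistant, the conservative choice when claiming pioneer targeting), and
further dichotomized by 6h H2B nucleosome-turnover signal.  Binned motif
enrichment re-implements the accessibility-decile analysis: peaks are
sorted by DNase level, cut into equal-size bins, and each bin is scored
for motif occurrence against all remaining bins as background with a
one-sided binomial test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .core_model import GenomeInterval, PWM, Peak, SignalTrack
from .signal_ops import (
    average_over_interval,
    central_window_mean,
    standardize_peak_widths,
)
from .sampling import has_hit

__all__ = [
    "AccessibilityCall",
    "MotifSplit",
    "BinnedEnrichmentResult",
    "classify_accessibility",
    "classify_turnover",
    "motif_accessibility_split",
    "binned_motif_enrichment",
    "closed_fraction",
    "DEFAULT_DNASE_CUTOFF",
]

DEFAULT_DNASE_CUTOFF = 0.05  # RPM over the peak


@dataclass
class AccessibilityCall:
    peak: Peak
    dnase_mean: float
    label: str  # accessible | resistant
    turnover_mean: float | None = None
    turnover_label: str | None = None  # high | low


@dataclass
class MotifSplit:
    accessible: list[GenomeInterval]
    inaccessible: list[GenomeInterval]
    means: np.ndarray  # central-window DNase mean, input order


def classify_accessibility(
    peaks: list[Peak],
    dnase: SignalTrack,
    cutoff: float = DEFAULT_DNASE_CUTOFF,
) -> list[AccessibilityCall]:
    """Label each peak accessible (DNase mean > cutoff) or resistant."""
    if not peaks:
        raise ValueError("empty peak list")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    calls = []
    for peak in peaks:
        mean, _ = average_over_interval(dnase, peak)
        calls.append(
            AccessibilityCall(
                peak, mean, "accessible" if mean > cutoff else "resistant"
            )
        )
    return calls


def closed_fraction(calls: list[AccessibilityCall]) -> float:
    """Fraction of peaks in DNase-resistant (closed) chromatin."""
    return sum(c.label == "resistant" for c in calls) / len(calls)


def classify_turnover(
    calls: list[AccessibilityCall],
    h2b: SignalTrack,
    cutoff: float | None = None,
    width: int = 100,
) -> list[AccessibilityCall]:
    """Add a high/low nucleosome-turnover label to accessibility calls.

    No absolute turnover cutoff is defined for the assay, so the default is
    the median central-window H2B mean over the peak set; pass ``cutoff``
    to override.  Labels high iff mean > cutoff.
    """
    means = [central_window_mean(h2b, c.peak, width)[0] for c in calls]
    if cutoff is None:
        cutoff = float(np.median(means))
    for call, mean in zip(calls, means):
        call.turnover_mean = mean
        call.turnover_label = "high" if mean > cutoff else "low"
    return calls


def motif_accessibility_split(
    motifs: list[GenomeInterval],
    dnase: SignalTrack,
    cutoff: float = DEFAULT_DNASE_CUTOFF,
    width: int = 100,
) -> MotifSplit:
    """Split motif instances by DNase signal over their central 100 bases.

    Same tie rule as peaks: a motif exactly at the cutoff is inaccessible.
    """
    means = np.array([central_window_mean(dnase, m, width)[0] for m in motifs])
    accessible = [m for m, v in zip(motifs, means) if v > cutoff]
    inaccessible = [m for m, v in zip(motifs, means) if v <= cutoff]
    return MotifSplit(accessible, inaccessible, means)


@dataclass
class BinnedEnrichmentResult:
    """Per-(motif, accessibility bin) enrichment table.

    ``table`` columns: pwm, bin, fg_freq, bg_freq, log2_enrichment, pvalue,
    adj_pvalue, enriched.  Bins are numbered from least (0) to most
    accessible; ``bin_edges`` holds the DNase value range of each bin and
    ``bin_sizes`` the number of peaks per bin.
    """

    table: pd.DataFrame
    bin_edges: list[tuple[float, float]]
    bin_sizes: list[int]


def _equal_size_bins(order: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Cut an ordering into n_bins equal-size bins; the remainder joins the
    last (most accessible) bin."""
    n = len(order)
    size = n // n_bins
    bins = [order[i * size : (i + 1) * size] for i in range(n_bins - 1)]
    bins.append(order[(n_bins - 1) * size :])
    return bins


def binned_motif_enrichment(
    peaks: list[Peak | GenomeInterval],
    dnase_values: np.ndarray,
    pwms: list[PWM],
    genome_sequence: dict[str, str],
    n_bins: int = 10,
    neglog_adj_p_cutoff: float = 2.0,
    fg_freq_cutoff: float = 0.05,
) -> BinnedEnrichmentResult:
    """Motif enrichment across DNase-accessibility bins of a peak set.

    Peaks are width-standardized and recentered, sorted by DNase value and
    cut into equal-size bins; each bin is scored against all other bins.
    A motif is reported enriched in a bin when -log10 of its BH-adjusted
    one-sided binomial p exceeds ``neglog_adj_p_cutoff`` and its foreground
    hit frequency exceeds ``fg_freq_cutoff``.
    """
    dnase_values = np.asarray(dnase_values, float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(peaks) < n_bins:
        raise ValueError("need at least n_bins peaks")
    if len(dnase_values) != len(peaks):
        raise ValueError("dnase_values must align with peaks")

    standardized = standardize_peak_widths(peaks)
    seqs = []
    for iv in standardized:
        chrom_seq = genome_sequence[iv.chrom]
        s, e = max(0, iv.start), min(len(chrom_seq), iv.end)
        seq = chrom_seq[s:e]
        if not seq:
            raise ValueError(f"empty sequence for peak {iv}")
        seqs.append(seq)

    order = np.argsort(dnase_values, kind="stable")
    bins = _equal_size_bins(order, n_bins)

    # hit matrix: peaks × motifs, >=1 match at the PWM's own threshold
    hits = np.zeros((len(seqs), len(pwms)), bool)
    for j, pwm in enumerate(pwms):
        for i, seq in enumerate(seqs):
            hits[i, j] = has_hit(seq, pwm)

    rows = []
    for j, pwm in enumerate(pwms):
        for b, idx in enumerate(bins):
            fg = hits[idx, j]
            bg_idx = np.concatenate([bins[k] for k in range(n_bins) if k != b])
            bg = hits[bg_idx, j]
            n_fg, k_fg = len(fg), int(fg.sum())
            n_bg, k_bg = len(bg), int(bg.sum())
            fg_freq = k_fg / n_fg
            bg_freq = k_bg / n_bg
            eps = 1.0 / (2 * n_fg)
            log2_enr = float(np.log2((fg_freq + eps) / (bg_freq + eps)))
            p_null = min(max(bg_freq, 1e-300), 1.0 - 1e-16)
            pval = binomtest(k_fg, n_fg, p_null, alternative="greater").pvalue
            rows.append(
                {
                    "pwm": pwm.name,
                    "bin": b,
                    "n_fg": n_fg,
                    "fg_freq": fg_freq,
                    "bg_freq": bg_freq,
                    "log2_enrichment": log2_enr,
                    "pvalue": pval,
                }
            )
    table = pd.DataFrame(rows)
    table["adj_pvalue"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(table["adj_pvalue"])
    table["enriched"] = (neglog > neglog_adj_p_cutoff) & (
        table["fg_freq"] > fg_freq_cutoff
    )

    edges = [
        (float(dnase_values[idx].min()), float(dnase_values[idx].max()))
        for idx in bins
    ]
    return BinnedEnrichmentResult(table, edges, [len(b) for b in bins])
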
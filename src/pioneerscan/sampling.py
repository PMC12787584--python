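"""Motif-sampling cistrome analysis.

A transcription factor binds called peaks at a small fraction of its
genomic motif instances, but reproducible low-level ChIP signal —
"sampling" — appears at many more.  This module scans a genome for motif
instances, ranks them by input-subtracted IP signal over their central 100
bases, filters unmappable sites by coverage, and classifies every instance
as bound (overlaps a consensus peak), sampled (central signal above a
threshold derived from a +10 kb shifted-motif background) or unsampled.
Between-condition transitions of those classes are tabulated for hybrid
factor comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    GenomeDescription,
    GenomeInterval,
    PWM,
    Peak,
    SignalTrack,
)
from .intervals import IntervalIndex
from .signal_ops import central_window_mean

__all__ = [
    "MotifInstance",
    "SamplingResult",
    "scan_pwm",
    "has_hit",
    "shift_background",
    "classify_motifs",
    "transition_table",
    "write_sampling_result",
]

CLASSES = ("bound", "sampled", "unsampled")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = lod.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    # pad the 4xL matrix with a -inf row so N (code 4) poisons its window
    padded = np.vstack([lod, np.full(L, -np.inf)])
    scores = np.zeros(n)
    for i in range(L):
        scores += padded[codes[i : i + n], i]
    return scores


def scan_pwm(
    sequence: dict[str, str],
    pwm: PWM,
    score_threshold: float | None = None,
) -> list[GenomeInterval]:
    """Scan both strands of a genome for PWM matches.

    Scores are log2 odds (bits) against the PWM background.  Hits at the
    same locus on opposite strands are deduplicated keeping the higher
    score, ties going to the + strand.  Hits come back coordinate-sorted.
    """
    if not sequence or all(len(s) == 0 for s in sequence.values()):
        raise ValueError("empty sequence")
    thr = pwm.score_threshold if score_threshold is None else score_threshold
    lod = pwm.log_odds()
    # reverse-complement matrix scores the - strand at the same coordinates
    rc_lod = lod[::-1, ::-1]
    hits: list[GenomeInterval] = []
    L = pwm.length
    for chrom in sequence:
        codes = _encode(sequence[chrom])
        fwd = _window_scores(codes, lod)
        rev = _window_scores(codes, rc_lod)
        with np.errstate(invalid="ignore"):
            take = (fwd >= thr) | (rev >= thr)
        for pos in np.flatnonzero(take):
            f, r = fwd[pos], rev[pos]
            if f >= r:
                score, strand = f, "+"
            else:
                score, strand = r, "-"
            hits.append(
                GenomeInterval(
                    chrom, int(pos), int(pos) + L,
                    name=pwm.name, score=float(score), strand=strand,
                )
            )
    return hits


def has_hit(sequence: str, pwm: PWM, score_threshold: float | None = None) -> bool:
    """True when the sequence contains >=1 match on either strand."""
    thr = pwm.score_threshold if score_threshold is None else score_threshold
    codes = _encode(sequence)
    lod = pwm.log_odds()
    if len(codes) < pwm.length:
        return False
    return bool(
        np.any(_window_scores(codes, lod) >= thr)
        or np.any(_window_scores(codes, lod[::-1, ::-1]) >= thr)
    )


def shift_background(
    motifs: list[GenomeInterval],
    genome: GenomeDescription,
    shift: int = 10_000,
) -> tuple[list[GenomeInterval], int]:
    """Translate motifs +shift bases to build a background set.

    Intervals pushed past their chromosome end are dropped; the count of
    dropped intervals is returned alongside the shifted list.
    """
    if shift <= 0:
        raise ValueError("shift must be positive")
    out = []
    dropped = 0
    for m in motifs:
        if m.end + shift <= genome.length(m.chrom):
            out.append(m.shifted(shift))
        else:
            dropped += 1
    return out, dropped


@dataclass(frozen=True)
class MotifInstance:
    interval: GenomeInterval
    pwm_score: float | None
    central_signal: float
    covered_fraction: float
    klass: str  # bound | sampled | unsampled | filtered


@dataclass
class SamplingResult:
    """Classified motif instances, sorted by central signal high to low."""

    instances: list[MotifInstance]
    background_threshold: float
    fractions: dict[str, float]
    n_total: int
    n_unfiltered: int
    background_dropped: int

    def instances_in_input_order(self) -> list[MotifInstance]:
        return sorted(
            self.instances,
            key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end),
        )


def classify_motifs(
    motifs: list[GenomeInterval],
    ip_track: SignalTrack,
    peaks: list[Peak],
    background_quantile: float = 0.95,
    coverage_min: float = 0.75,
    shift: int = 10_000,
    window: int = 100,
) -> SamplingResult:
    """Classify every motif instance as bound, sampled or unsampled.

    Central signal and covered fraction come from the 100-base window
    around each motif center on the input-subtracted IP track.  Motifs with
    covered fraction <= ``coverage_min`` are filtered (low-coverage or
    unmappable).  A motif overlapping >=1 consensus peak by >=1 base is
    bound regardless of signal.  The remaining motifs are sampled when
    their central signal exceeds the ``background_quantile`` quantile of
    central signal over the +``shift`` shifted (and equally
    coverage-filtered) motif set, else unsampled.  Fractions are reported
    over unfiltered motifs.
    """
    if not 0.0 <= background_quantile <= 1.0:
        raise ValueError("background_quantile must be in [0, 1]")

    background, dropped = shift_background(motifs, ip_track.genome, shift)
    bg_signals = []
    for b in background:
        mean, cov = central_window_mean(ip_track, b, window)
        if cov > coverage_min:
            bg_signals.append(mean)
    if not bg_signals:
        raise ValueError(
            "empty background after coverage filtering; use a larger genome "
            "or a lower coverage_min"
        )
    threshold = float(np.quantile(bg_signals, background_quantile))

    peak_index = IntervalIndex(peaks)
    chrom_order = {c: i for i, c in enumerate(ip_track.genome.names)}
    instances = []
    counts = {c: 0 for c in CLASSES}
    for m in motifs:
        mean, cov = central_window_mean(ip_track, m, window)
        if cov <= coverage_min:
            klass = "filtered"
        elif peak_index.overlaps(m):
            klass = "bound"
        elif mean > threshold:
            klass = "sampled"
        else:
            klass = "unsampled"
        if klass in counts:
            counts[klass] += 1
        instances.append(MotifInstance(m, m.score, mean, cov, klass))

    n_unfiltered = sum(counts.values())
    fractions = {
        c: (counts[c] / n_unfiltered if n_unfiltered else 0.0) for c in CLASSES
    }
    instances.sort(
        key=lambda mi: (
            -mi.central_signal,
            chrom_order[mi.interval.chrom],
            mi.interval.start,
        )
    )
    return SamplingResult(
        instances=instances,
        background_threshold=threshold,
        fractions=fractions,
        n_total=len(motifs),
        n_unfiltered=n_unfiltered,
        background_dropped=dropped,
    )


def transition_table(a: SamplingResult, b: SamplingResult) -> pd.DataFrame:
    """3x3 class-transition counts between two conditions.

    Both results must be classified over the identical motif list; only
    motifs unfiltered in both conditions are counted, so the table total is
    the size of the common unfiltered set.
    """
    ai = a.instances_in_input_order()
    bi = b.instances_in_input_order()
    if [m.interval for m in ai] != [m.interval for m in bi]:
        raise ValueError("sampling results cover different motif lists")
    table = pd.DataFrame(
        np.zeros((3, 3), int), index=list(CLASSES), columns=list(CLASSES)
    )
    for ma, mb in zip(ai, bi):
        if ma.klass != "filtered" and mb.klass != "filtered":
            table.loc[ma.klass, mb.klass] += 1
    return table


def write_sampling_result(path, result: SamplingResult) -> None:
    """One row per motif (signal-sorted) plus a footer with the summary."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tstrand\tcentral_signal\t"
                 "covered_fraction\tclass\n")
        for mi in result.instances:
            iv = mi.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.strand}\t{mi.central_signal!r}\t"
                f"{mi.covered_fraction!r}\t{mi.klass}\n"
            )
        fh.write(f"#background_threshold\t{result.background_threshold!r}\n")
        fh.write(f"#n_total\t{result.n_total}\n")
        fh.write(f"#n_unfiltered\t{result.n_unfiltered}\n")
        for c in CLASSES:
            fh.write(f"#fraction_{c}\t{result.fractions[c]!r}\n")
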
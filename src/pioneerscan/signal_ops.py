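"""Signal extraction over intervals.

In-house equivalents of the interval-averaging and reference-point matrix
utilities used around ChIP-seq tracks: interval means with covered
fraction, central-window sampling, signal matrices and metaprofiles, plus
peak-width standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_model import (
    GenomeInterval,
    Peak,
    SignalTrack,
    as_interval,
)

__all__ = [
    "average_over_interval",
    "central_window_mean",
    "signal_matrix",
    "metaprofile",
    "standardize_peak_widths",
    "SignalMatrix",
]


def average_over_interval(
    track: SignalTrack, interval: GenomeInterval | Peak
) -> tuple[float, float]:
    """Mean signal over an interval and the fraction of its bases covered.

    The mean is the overlap-weighted sum of bin values divided by the
    interval length in bases; uncovered bases contribute 0 to the sum but
    count in the denominator.
    """
    iv = as_interval(interval)
    iv.validate(track.genome)
    bs = track.bin_size
    b0, b1 = iv.start // bs, (iv.end - 1) // bs
    v = track.values[iv.chrom][b0 : b1 + 1]
    c = track.covered[iv.chrom][b0 : b1 + 1]
    edges = np.arange(b0, b1 + 2) * bs
    overlap = np.minimum(edges[1:], iv.end) - np.maximum(edges[:-1], iv.start)
    length = iv.end - iv.start
    mean = float(np.dot(v, overlap) / length)
    covered = float(np.dot(c, overlap) / length)
    return mean, covered


def central_window_mean(
    track: SignalTrack,
    interval: GenomeInterval | Peak,
    width: int = 100,
) -> tuple[float, float]:
    """Mean over a fixed-width window centered on the interval.

    The center is floor((start+end)/2); the window is clipped at chromosome
    bounds with the denominator reduced to the clipped length.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    iv = as_interval(interval)
    c = iv.center
    ws = max(0, c - width // 2)
    we = min(track.genome.length(iv.chrom), c - width // 2 + width)
    return average_over_interval(track, GenomeInterval(iv.chrom, ws, we))


@dataclass
class SignalMatrix:
    """Reference-point signal matrix: one row per interval, fixed bins
    spanning [reference − window, reference + window)."""

    values: np.ndarray
    window: int
    bin_width: int
    references: list[tuple[str, int]]

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window, self.bin_width)


def signal_matrix(
    track: SignalTrack,
    intervals: list[GenomeInterval | Peak],
    window: int,
    bin_width: int,
    reference: str = "center",
    skip_zero_rows: bool = False,
    missing_as_zero: bool = True,
) -> SignalMatrix:
    """Build a reference-point matrix around interval centers or summits.

    Each cell is the mean signal over its column window; windows (or parts
    of windows) outside the chromosome are treated as zero when
    ``missing_as_zero``, otherwise NaN.  Row order follows the input list.
    """
    if window % bin_width:
        raise ValueError("window must be a multiple of bin width")
    if reference not in ("center", "summit"):
        raise ValueError("reference must be 'center' or 'summit'")
    ncols = 2 * window // bin_width
    rows = []
    refs = []
    for item in intervals:
        iv = as_interval(item)
        if reference == "summit" and isinstance(item, Peak):
            ref = item.summit
        else:
            ref = iv.center
        refs.append((iv.chrom, ref))
        chrom_len = track.genome.length(iv.chrom)
        row = np.zeros(ncols) if missing_as_zero else np.full(ncols, np.nan)
        for j in range(ncols):
            ws = ref - window + j * bin_width
            we = ws + bin_width
            cs, ce = max(0, ws), min(chrom_len, we)
            if ce <= cs:
                continue
            mean, _ = average_over_interval(track, GenomeInterval(iv.chrom, cs, ce))
            if missing_as_zero:
                # out-of-chromosome bases count as zero signal
                row[j] = mean * (ce - cs) / bin_width
            elif ce - cs == bin_width:
                row[j] = mean
        rows.append(row)
    values = np.array(rows) if rows else np.empty((0, ncols))
    if skip_zero_rows and len(values):
        keep = ~np.all(values == 0, axis=1)
        values = values[keep]
        refs = [r for r, k in zip(refs, keep) if k]
    return SignalMatrix(values, window, bin_width, refs)


def metaprofile(matrix: SignalMatrix) -> np.ndarray:
    """Column-wise mean of a signal matrix."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty matrix")
    return matrix.values.mean(axis=0)


def standardize_peak_widths(
    peaks: list[Peak | GenomeInterval],
    genome=None,
) -> list[GenomeInterval]:
    """Recenter every peak and fix its width to the rounded mean width.

    Width rounding is half-up to whole bases.  Standardized intervals are
    shifted inward where they would cross a chromosome boundary (only
    possible for peaks near an edge), so widths stay uniform.
    """
    if not peaks:
        raise ValueError("empty peak list")
    ivs = [as_interval(p) for p in peaks]
    mean_w = int(np.floor(np.mean([len(iv) for iv in ivs]) + 0.5))
    out = []
    for iv in ivs:
        c = iv.center
        start = c - mean_w // 2
        end = start + mean_w
        if genome is not None:
            length = genome.length(iv.chrom)
            if start < 0:
                start, end = 0, mean_w
            if end > length:
                start, end = length - mean_w, length
        out.append(replace(iv, start=start, end=end))
    return out
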
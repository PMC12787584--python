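"""Domain types and plain-text genomics I/O.

Coordinate convention is 0-based half-open throughout (BED semantics).
Signal lives in :class:`SignalTrack`, a dense per-chromosome vector at a
fixed bin resolution with a parallel coverage mask; bedGraph is the native
on-disk dialect.  Strand is carried on intervals but ignored by every
signal operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeDescription",
    "GenomeInterval",
    "Peak",
    "SignalTrack",
    "PWM",
    "StateSegmentation",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_pwm",
    "write_pwm",
    "read_segmentation",
    "write_segmentation",
    "subtract_input",
    "rpm_normalize",
    "as_interval",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomeDescription:
    """Ordered chromosome names and lengths."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeDescription":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for name, length in self.chroms:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(name == chrom for name, _ in self.chroms)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chroms)

    def chrom_index(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chroms):
            if name == chrom:
                return i
        raise KeyError(chrom)


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic span [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, genome: GenomeDescription) -> "GenomeInterval":
        if self.chrom not in genome:
            raise ValueError(f"chromosome {self.chrom!r} absent from genome")
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome.length(self.chrom)}"
            )
        return self

    def shifted(self, delta: int) -> "GenomeInterval":
        return replace(self, start=self.start + delta, end=self.end + delta)


@dataclass(frozen=True)
class Peak:
    """A called binding site: an interval plus optional summit and score."""

    interval: GenomeInterval
    summit_offset: int | None = None
    enrichment: float = 0.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError("summit offset outside peak")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int:
        """Absolute summit position; falls back to the interval center."""
        if self.summit_offset is None:
            return self.interval.center
        return self.interval.start + self.summit_offset


def as_interval(x: GenomeInterval | Peak) -> GenomeInterval:
    return x.interval if isinstance(x, Peak) else x


class SignalTrack:
    """Dense binned signal with a coverage mask.

    ``values[chrom][i]`` is the mean per-base signal over bin *i* (bases
    ``[i*bin_size, (i+1)*bin_size)`` clipped to the chromosome); bases with
    no observation contribute 0 to that mean.  ``covered[chrom][i]`` is True
    where at least one base of the bin had an observation.
    """

    def __init__(
        self,
        genome: GenomeDescription,
        bin_size: int,
        values: dict[str, np.ndarray] | None = None,
        covered: dict[str, np.ndarray] | None = None,
    ):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        self.values: dict[str, np.ndarray] = {}
        self.covered: dict[str, np.ndarray] = {}
        for chrom, length in genome.chroms:
            n = -(-length // bin_size)
            v = np.zeros(n) if values is None else np.asarray(values[chrom], float)
            if covered is not None:
                c = np.asarray(covered[chrom], bool)
            else:
                # values without a mask mean a fully observed track
                c = np.zeros(n, bool) if values is None else np.ones(n, bool)
            if len(v) != n or len(c) != n:
                raise ValueError(f"vector length mismatch on {chrom}")
            self.values[chrom] = np.where(c, v, 0.0)
            self.covered[chrom] = c

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def compatible_with(self, other: "SignalTrack") -> bool:
        return self.genome == other.genome and self.bin_size == other.bin_size

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            self.genome,
            self.bin_size,
            {c: v * factor for c, v in self.values.items()},
            {c: m.copy() for c, m in self.covered.items()},
        )

    def to_base_resolution(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-base expansion (value, covered) — the brute-force view."""
        length = self.genome.length(chrom)
        v = np.repeat(self.values[chrom], self.bin_size)[:length]
        c = np.repeat(self.covered[chrom], self.bin_size)[:length]
        return v, c


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 4×L probabilities, rows A, C, G, T."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0
    score_threshold: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, float)
        object.__setattr__(self, "background", bg)
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError("PWM must be 4×L with L >= 4")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4×L log2(p/background) with pseudocount regularization."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=0, keepdims=True)
        if np.any(p == 0):
            raise ValueError("PWM has a zero entry after pseudocount")
        return np.log2(p / self.background[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=0))

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.0,
        score_threshold: float = 0.0,
        name: str = "motif",
    ) -> "PWM":
        counts = np.asarray(counts, float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs, bg, pseudocount, score_threshold, name)

    @classmethod
    def from_consensus(
        cls, consensus: str, strength: float = 0.97, **kw
    ) -> "PWM":
        """Near-deterministic PWM around a consensus string."""
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        m = np.full((4, len(consensus)), (1 - strength) / 3)
        for j, base in enumerate(consensus.upper()):
            m[idx[base], j] = strength
        return cls(m, **kw)


@dataclass(frozen=True)
class StateSegmentation:
    """Non-overlapping labeled intervals covering a genome (states 1..K)."""

    intervals: tuple[GenomeInterval, ...]
    n_states: int

    def __post_init__(self) -> None:
        for iv in self.intervals:
            s = int(iv.name)
            if not (1 <= s <= self.n_states):
                raise ValueError(f"state label {iv.name} outside 1..{self.n_states}")

    def state_of(self, iv: GenomeInterval) -> int:
        return int(iv.name)

    def validate_coverage(self, genome: GenomeDescription) -> None:
        """Raise if the segmentation does not tile the genome; lists gaps."""
        by_chrom: dict[str, list[GenomeInterval]] = {c: [] for c in genome.names}
        for iv in self.intervals:
            iv.validate(genome)
            by_chrom[iv.chrom].append(iv)
        gaps: list[str] = []
        for chrom, length in genome.chroms:
            ivs = sorted(by_chrom[chrom], key=lambda i: i.start)
            pos = 0
            for iv in ivs:
                if iv.start > pos:
                    gaps.append(f"{chrom}:{pos}-{iv.start}")
                elif iv.start < pos:
                    raise ValueError(f"overlapping segmentation at {chrom}:{iv.start}")
                pos = iv.end
            if pos < length:
                gaps.append(f"{chrom}:{pos}-{length}")
        if gaps:
            raise ValueError("segmentation gaps: " + ", ".join(gaps))


# ---------------------------------------------------------------------------
# BED / narrowPeak

def read_bed(
    path: str | Path, genome: GenomeDescription | None = None
) -> list[GenomeInterval | Peak]:
    """Read BED3–BED6 or ENCODE narrowPeak.

    narrowPeak lines (10 columns) come back as :class:`Peak` with the summit
    offset and signalValue populated; plain BED lines come back as
    :class:`GenomeInterval`.  Input order is preserved.
    """
    out: list[GenomeInterval | Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
            try:
                iv = GenomeInterval(chrom, start, end, name, score, strand)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if genome is not None:
                try:
                    iv.validate(genome)
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if len(fields) == 10:  # narrowPeak: signalValue, pValue, qValue, peak
                signal = float(fields[6])
                summit = int(fields[9])
                out.append(
                    Peak(
                        iv,
                        summit_offset=None if summit < 0 else summit,
                        enrichment=signal,
                    )
                )
            else:
                out.append(iv)
    return out


def write_bed(path: str | Path, items: Iterable[GenomeInterval | Peak]) -> None:
    """Write BED6 for intervals, narrowPeak for peaks (homogeneous input)."""
    with open(path, "w") as fh:
        for item in items:
            if isinstance(item, Peak):
                iv = item.interval
                summit = -1 if item.summit_offset is None else item.summit_offset
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            str(iv.start),
                            str(iv.end),
                            iv.name or ".",
                            "0" if iv.score is None else repr(float(iv.score)),
                            iv.strand,
                            repr(float(item.enrichment)),
                            "-1",
                            "-1",
                            str(summit),
                        ]
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        [
                            item.chrom,
                            str(item.start),
                            str(item.end),
                            item.name or ".",
                            "." if item.score is None else repr(float(item.score)),
                            item.strand,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(
    path: str | Path, genome: GenomeDescription, bin_size: int
) -> SignalTrack:
    """Rasterize a 4-column bedGraph onto fixed bins.

    Bin value = coverage-weighted mean over the bin with uncovered bases
    counted as 0; a bin is covered when any of its bases is.  Records may
    arrive unsorted; overlapping records are an error.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    records: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome.names}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: need 4 columns")
            chrom = fields[0]
            if chrom not in genome:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom}")
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            if not (0 <= start < end <= genome.length(chrom)):
                raise ValueError(f"{path}: line {lineno}: bad span {start}-{end}")
            records[chrom].append((start, end, value))

    track = SignalTrack(genome, bin_size)
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        sums = np.zeros(track.n_bins(chrom))
        covered = np.zeros(track.n_bins(chrom), bool)
        for start, end, value in recs:
            if start < prev_end:
                raise ValueError(f"overlapping bedGraph records on {chrom} at {start}")
            prev_end = end
            b0, b1 = start // bin_size, (end - 1) // bin_size
            if b0 == b1:
                sums[b0] += value * (end - start)
            else:
                sums[b0] += value * ((b0 + 1) * bin_size - start)
                if b1 > b0 + 1:
                    sums[b0 + 1 : b1] += value * bin_size
                sums[b1] += value * (end - b1 * bin_size)
            covered[b0 : b1 + 1] = True
        widths = np.full(track.n_bins(chrom), bin_size, float)
        length = genome.length(chrom)
        if length % bin_size:
            widths[-1] = length % bin_size
        track.values[chrom] = sums / widths
        track.covered[chrom] = covered
    return track


def write_bedgraph(path: str | Path, track: SignalTrack) -> None:
    """Write covered bins as run-length-merged bedGraph records."""
    with open(path, "w") as fh:
        for chrom, length in track.genome.chroms:
            v = track.values[chrom]
            c = track.covered[chrom]
            if not c.any():
                continue
            # break runs where coverage or value changes
            change = np.empty(len(v), bool)
            change[0] = True
            change[1:] = (v[1:] != v[:-1]) | (c[1:] != c[:-1])
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], len(v))
            for b0, b1 in zip(starts, ends):
                if not c[b0]:
                    continue
                s = int(b0) * track.bin_size
                e = min(int(b1) * track.bin_size, length)
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v[b0])!r}\n")


# ---------------------------------------------------------------------------
# PWM text (JASPAR-style)

def read_pwm(path: str | Path, **kw) -> list[PWM]:
    """Read one or more JASPAR-style matrices.

    Format: a ``>name`` header, then four rows A/C/G/T of counts or
    probabilities, optionally bracketed (``A [ 4 19 0 ]``).
    """
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        if name is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise ValueError(f"PWM {name}: need exactly rows A, C, G, T")
        counts = np.array([rows[b] for b in "ACGT"])
        pwms.append(PWM.from_counts(counts, name=name, **kw))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = {}
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                if parts[0].upper() in "ACGT":
                    rows[parts[0].upper()] = [float(x) for x in parts[1:]]
                else:
                    raise ValueError(f"unrecognized PWM row: {line!r}")
    flush()
    return pwms


def write_pwm(path: str | Path, pwms: Iterable[PWM]) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(repr(float(x)) for x in pwm.matrix[i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Segmentation BED (4 columns, state label in the name field)

def read_segmentation(
    path: str | Path, genome: GenomeDescription | None = None
) -> StateSegmentation:
    items = read_bed(path, genome)
    intervals = []
    for iv in items:
        iv = as_interval(iv)
        label = iv.name or ""
        digits = "".join(ch for ch in label if ch.isdigit())
        if not digits:
            raise ValueError(f"segmentation interval without state label: {iv}")
        intervals.append(replace(iv, name=str(int(digits))))
    k = max(int(iv.name) for iv in intervals)
    return StateSegmentation(tuple(intervals), k)


def write_segmentation(path: str | Path, seg: StateSegmentation) -> None:
    with open(path, "w") as fh:
        for iv in seg.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# Track arithmetic

def subtract_input(ip: SignalTrack, input_track: SignalTrack) -> SignalTrack:
    """IP minus input, per bin.  Negative differences are retained: the
    downstream sampling thresholds operate on the signed difference."""
    if not ip.compatible_with(input_track):
        raise ValueError("genome/bin_size mismatch between IP and input")
    values = {
        c: ip.values[c] - input_track.values[c] for c in ip.genome.names
    }
    covered = {
        c: ip.covered[c] | input_track.covered[c] for c in ip.genome.names
    }
    return SignalTrack(ip.genome, ip.bin_size, values, covered)


def rpm_normalize(counts: SignalTrack, total_reads: int) -> SignalTrack:
    """Scale raw counts to reads per million mapped reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return counts.scaled(1e6 / total_reads)
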
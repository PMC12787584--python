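"""Synthetic multi-chromosome genome with planted ground truth.

Emulates the data model of an ectopic transcription-factor ChIP experiment
in fibroblasts: a chromatin-state layout (naive open / naive closed /
H3K9me3 domain / H3K27me3 domain), broad repressive-mark domains carrying
small internal gaps and focal-enrichment sites, motif instances with known
bound / sampled / unsampled classes, and signal tracks (DNase, 6h H2B
turnover, H3K9me3, H3K27me3, input-subtracted IP) consistent with all of
the above.  Everything is driven by one integer seed and is byte-stable.

The IP background is modelled as sparse Poisson-placed read fragments
rather than dense per-bin noise: an input-subtracted coverage track is
exactly zero over most unread bases, and only occasional background
fragments produce nonzero pileups.  ``noise_sd`` sets the mean pileup
height of such a fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core_model import (
    GenomeDescription,
    GenomeInterval,
    PWM,
    Peak,
    SignalTrack,
    StateSegmentation,
    write_bed,
    write_bedgraph,
    write_segmentation,
)

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticTruth",
    "SyntheticData",
    "GenerationError",
    "generate",
    "write_fixture",
    "largest_remainder",
]

STATE_NAMES = ("open_naive", "closed_naive", "K9_domain", "K27_domain")
STATE_IDS = {name: i + 1 for i, name in enumerate(STATE_NAMES)}
CLASS_NAMES = ("bound", "sampled", "unsampled")

# geometry of planted heterochromatin-density sites: flank windows reach
# ±6 kb from a site center, so sites keep 8 kb mutual separation and a
# 6 kb margin inside their domain
_SITE_MARGIN = 6_000
_SITE_MIN_SEP = 8_000
_HIGH_SITE_SD = 300.0


class GenerationError(RuntimeError):
    """Raised when planted features cannot be placed without overlap."""


def _default_motif() -> PWM:
    # SOX-family-like 7-mer consensus; near-deterministic columns
    return PWM.from_consensus("CATTGTT", strength=0.97, name="SOX")


@dataclass
class SyntheticGenomeSpec:
    """Study conditions for one synthetic genome."""

    n_chroms: int = 4
    chrom_length: int = 2_000_000
    bin_size: int = 10
    state_fractions: dict[str, float] = dc_field(
        default_factory=lambda: {
            "open_naive": 0.25,
            "closed_naive": 0.35,
            "K9_domain": 0.20,
            "K27_domain": 0.20,
        }
    )
    gap_rate: float = 2.0          # expected spontaneous gaps per domain
    gap_width: int = 2_000         # bases
    motif: PWM = dc_field(default_factory=_default_motif)
    n_motifs: int = 1_000
    class_fractions: dict[str, float] = dc_field(
        default_factory=lambda: {"bound": 0.03, "sampled": 0.31, "unsampled": 0.66}
    )
    bound_signal_mean: float = 10.0    # RPM, IP bump height at bound motifs
    sampled_signal_mean: float = 1.0   # RPM, IP bump height at sampled motifs
    noise_sd: float = 0.2              # RPM, mean background fragment pileup
    dnase_open_mean: float = 0.5       # RPM
    dnase_closed_mean: float = 0.01    # RPM
    turnover_high_mean: float = 1.0    # RPM
    turnover_low_mean: float = 0.05    # RPM
    seed: int = 0
    # layout details
    segment_length: int = 100_000      # chromatin-state block size
    mark_level: float = 1.0            # RPM inside K9/K27 domains
    mark_background: float = 0.02      # RPM outside domains
    track_cv: float = 0.1              # relative within-state noise
    bump_sd: float = 200.0             # IP bump sd, ~300-500 bp fragments
    min_motif_separation: int = 1_200  # bases between motif centers
    peak_halfwidth: int = 200          # called-peak half width at bound motifs
    replicate_dropout: float = 0.0     # per-replicate peak dropout probability
    n_hetero_sites: int = 40           # planted sites per density class
    noise_fragment_rate: float = 4e-5  # background fragments per base
    noise_fragment_length: int = 300   # bases

    def validate(self) -> None:
        if set(self.state_fractions) != set(STATE_NAMES):
            raise ValueError(f"state_fractions must cover {STATE_NAMES}")
        if abs(sum(self.state_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("state_fractions must sum to 1")
        if set(self.class_fractions) != set(CLASS_NAMES):
            raise ValueError(f"class_fractions must cover {CLASS_NAMES}")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if not (self.bound_signal_mean > self.sampled_signal_mean > 0):
            raise ValueError("need bound_signal_mean > sampled_signal_mean > 0")
        if self.segment_length % self.bin_size:
            raise ValueError("segment_length must be a multiple of bin_size")
        if self.chrom_length % self.bin_size:
            raise ValueError("chrom_length must be a multiple of bin_size")


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature."""

    motif_classes: list[str]
    peak_open: list[bool]
    domains: list[tuple[GenomeInterval, str]]
    gaps: list[tuple[GenomeInterval, str]]
    hetero_sites: list[tuple[GenomeInterval, str, str]]  # (site, mark, class)
    segmentation: StateSegmentation


@dataclass
class SyntheticData:
    spec: SyntheticGenomeSpec
    genome: GenomeDescription
    sequence: dict[str, str]
    tracks: dict[str, SignalTrack]
    peak_replicates: list[list[Peak]]
    peaks: list[Peak]
    motifs: list[GenomeInterval]
    truth: SyntheticTruth


def largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n items to the given fractions, deterministically.

    Floors the quotas, then hands remaining items to the largest fractional
    parts; ties break by key order in the dict.
    """
    keys = list(fractions)
    quotas = [fractions[k] * n for k in keys]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(keys)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts))


def _layout_states(
    spec: SyntheticGenomeSpec, rng: np.random.Generator, genome: GenomeDescription
) -> tuple[StateSegmentation, dict[str, np.ndarray]]:
    """Tile chromosomes with fixed-length blocks and shuffle state labels."""
    segs_per_chrom = spec.chrom_length // spec.segment_length
    if segs_per_chrom < 1:
        raise ValueError("chrom_length must be at least one segment_length")
    n_segments = spec.n_chroms * segs_per_chrom
    counts = largest_remainder(spec.state_fractions, n_segments)
    labels = np.concatenate(
        [np.full(counts[s], STATE_IDS[s]) for s in STATE_NAMES]
    )
    rng.shuffle(labels)
    intervals: list[GenomeInterval] = []
    state_bins: dict[str, np.ndarray] = {}
    k = 0
    for chrom, length in genome.chroms:
        bins = np.empty(length // spec.bin_size, dtype=np.int8)
        pos = 0
        for j in range(segs_per_chrom):
            state = int(labels[k])
            # the final block absorbs any remainder so the tiling covers
            # the chromosome exactly
            end = length if j == segs_per_chrom - 1 else pos + spec.segment_length
            # merge with previous block of the same state
            if intervals and intervals[-1].chrom == chrom and int(
                intervals[-1].name
            ) == state and intervals[-1].end == pos:
                intervals[-1] = GenomeInterval(chrom, intervals[-1].start, end, str(state))
            else:
                intervals.append(GenomeInterval(chrom, pos, end, str(state)))
            bins[pos // spec.bin_size : end // spec.bin_size] = state
            pos = end
            k += 1
        state_bins[chrom] = bins
    return StateSegmentation(tuple(intervals), len(STATE_NAMES)), state_bins


def _place_domain_features(
    spec: SyntheticGenomeSpec,
    rng: np.random.Generator,
    domains: list[tuple[GenomeInterval, str]],
) -> tuple[
    list[tuple[GenomeInterval, str]], list[tuple[GenomeInterval, str, str]]
]:
    """Plant gaps and high/flat/gap density sites inside domains."""
    usable = [
        (iv, mark)
        for iv, mark in domains
        if iv.end - iv.start > 2 * _SITE_MARGIN + 1
    ]
    if not usable and (spec.n_hetero_sites > 0 or spec.gap_rate > 0):
        if spec.n_hetero_sites > 0:
            raise GenerationError("no domain is wide enough for planted sites")
    accepted: dict[int, list[int]] = {i: [] for i in range(len(usable))}

    def try_place(dom_idx: int) -> int | None:
        iv, _ = usable[dom_idx]
        lo, hi = iv.start + _SITE_MARGIN, iv.end - _SITE_MARGIN
        for _ in range(200):
            c = int(rng.integers(lo, hi))
            if all(abs(c - o) >= _SITE_MIN_SEP for o in accepted[dom_idx]):
                accepted[dom_idx].append(c)
                return c
        return None

    gaps: list[tuple[GenomeInterval, str]] = []
    sites: list[tuple[GenomeInterval, str, str]] = []

    # spontaneous gaps, Poisson per domain
    for i, (iv, mark) in enumerate(usable):
        for _ in range(int(rng.poisson(spec.gap_rate))):
            c = try_place(i)
            if c is None:
                continue  # domain saturated; spontaneous gaps are best-effort
            gaps.append(
                (GenomeInterval(iv.chrom, c - spec.gap_width // 2,
                                c - spec.gap_width // 2 + spec.gap_width), mark)
            )

    # deliberate high / flat / gap sites, spread over domains
    requests = [cls for cls in ("high", "flat", "gap") for _ in range(spec.n_hetero_sites)]
    for cls in requests:
        placed = False
        for dom_idx in rng.permutation(len(usable)):
            c = try_place(int(dom_idx))
            if c is not None:
                iv, mark = usable[int(dom_idx)]
                site = GenomeInterval(iv.chrom, c - 500, c + 500)
                sites.append((site, mark, cls))
                if cls == "gap":
                    gaps.append(
                        (GenomeInterval(iv.chrom, c - spec.gap_width // 2,
                                        c - spec.gap_width // 2 + spec.gap_width),
                         mark)
                    )
                placed = True
                break
        if not placed:
            raise GenerationError(
                "could not place a planted heterochromatin site; "
                "increase domain fractions or lower n_hetero_sites"
            )
    return gaps, sites


def _place_motifs(
    spec: SyntheticGenomeSpec, rng: np.random.Generator, genome: GenomeDescription
) -> list[GenomeInterval]:
    lm = spec.motif.length
    margin = 1_000
    centers: dict[str, list[int]] = {c: [] for c in genome.names}
    placed: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 200 * spec.n_motifs
    while len(placed) < spec.n_motifs:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                "could not place motifs without overlap; lower n_motifs or "
                "min_motif_separation"
            )
        chrom = genome.names[int(rng.integers(0, len(genome.names)))]
        c = int(rng.integers(margin, genome.length(chrom) - margin))
        if all(abs(c - o) >= spec.min_motif_separation for o in centers[chrom]):
            centers[chrom].append(c)
            placed.append((chrom, c))
    placed.sort(key=lambda t: (t[0], t[1]))
    strands = rng.choice(["+", "-"], size=len(placed))
    return [
        GenomeInterval(chrom, c - lm // 2, c - lm // 2 + lm,
                       name=f"motif_{i}", strand=str(strands[i]))
        for i, (chrom, c) in enumerate(placed)
    ]


_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _make_sequence(
    spec: SyntheticGenomeSpec,
    rng: np.random.Generator,
    genome: GenomeDescription,
    motifs: list[GenomeInterval],
) -> dict[str, str]:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    consensus = np.array([idx[b] for b in spec.motif.consensus()], dtype=np.uint8)
    codes = {
        chrom: rng.integers(0, 4, size=length).astype(np.uint8)
        for chrom, length in genome.chroms
    }
    for m in motifs:
        planted = consensus if m.strand != "-" else _COMPLEMENT[consensus][::-1]
        codes[m.chrom][m.start : m.end] = planted
    return {c: _BASES[v].tobytes().decode() for c, v in codes.items()}


def _add_bump(values: np.ndarray, bin_size: int, center: int, amp: float,
              sd: float) -> None:
    half = int(4 * sd)
    b0 = max(0, (center - half) // bin_size)
    b1 = min(len(values), (center + half) // bin_size + 1)
    x = np.arange(b0, b1) * bin_size + bin_size / 2.0
    values[b0:b1] += amp * np.exp(-((x - center) ** 2) / (2 * sd * sd))


def _state_track(
    genome: GenomeDescription,
    bin_size: int,
    state_bins: dict[str, np.ndarray],
    means: dict[int, float],
    cv: float,
    rng: np.random.Generator,
) -> SignalTrack:
    values = {}
    covered = {}
    for chrom, _ in genome.chroms:
        sb = state_bins[chrom]
        mean = np.zeros(len(sb))
        for state, m in means.items():
            mean[sb == state] = m
        v = rng.normal(mean, cv * mean)
        values[chrom] = np.maximum(v, 0.0)
        covered[chrom] = np.ones(len(sb), bool)
    return SignalTrack(genome, bin_size, values, covered)


def generate(spec: SyntheticGenomeSpec) -> SyntheticData:
    """Generate the full synthetic bundle for one seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome = GenomeDescription.from_pairs(
        (f"chr{i + 1}", spec.chrom_length) for i in range(spec.n_chroms)
    )

    segmentation, state_bins = _layout_states(spec, rng, genome)
    domains = [
        (GenomeInterval(iv.chrom, iv.start, iv.end),
         "H3K9me3" if int(iv.name) == STATE_IDS["K9_domain"] else "H3K27me3")
        for iv in segmentation.intervals
        if int(iv.name) in (STATE_IDS["K9_domain"], STATE_IDS["K27_domain"])
    ]
    gaps, hetero_sites = _place_domain_features(spec, rng, domains)
    motifs = _place_motifs(spec, rng, genome)
    sequence = _make_sequence(spec, rng, genome, motifs)

    # class assignment: exact apportionment, then a seeded shuffle
    counts = largest_remainder(spec.class_fractions, spec.n_motifs)
    classes = np.concatenate(
        [np.full(counts[c], i) for i, c in enumerate(CLASS_NAMES)]
    )
    rng.shuffle(classes)
    motif_classes = [CLASS_NAMES[i] for i in classes]

    # state-driven tracks
    oid, cid = STATE_IDS["open_naive"], STATE_IDS["closed_naive"]
    k9id, k27id = STATE_IDS["K9_domain"], STATE_IDS["K27_domain"]
    dnase = _state_track(
        genome, spec.bin_size, state_bins,
        {oid: spec.dnase_open_mean, cid: spec.dnase_closed_mean,
         k9id: spec.dnase_closed_mean, k27id: spec.dnase_closed_mean},
        spec.track_cv, rng,
    )
    h2b = _state_track(
        genome, spec.bin_size, state_bins,
        {oid: spec.turnover_high_mean, cid: spec.turnover_low_mean,
         k9id: spec.turnover_low_mean, k27id: spec.turnover_low_mean},
        spec.track_cv, rng,
    )
    k9 = _state_track(
        genome, spec.bin_size, state_bins,
        {oid: spec.mark_background, cid: spec.mark_background,
         k9id: spec.mark_level, k27id: spec.mark_background},
        spec.track_cv, rng,
    )
    k27 = _state_track(
        genome, spec.bin_size, state_bins,
        {oid: spec.mark_background, cid: spec.mark_background,
         k9id: spec.mark_background, k27id: spec.mark_level},
        spec.track_cv, rng,
    )
    mark_tracks = {"H3K9me3": k9, "H3K27me3": k27}
    for iv, mark, cls in hetero_sites:
        if cls == "high":
            _add_bump(
                mark_tracks[mark].values[iv.chrom], spec.bin_size,
                iv.center, 2.0 * spec.mark_level, _HIGH_SITE_SD,
            )
    for iv, mark in gaps:
        v = mark_tracks[mark].values[iv.chrom]
        b0, b1 = iv.start // spec.bin_size, -(-iv.end // spec.bin_size)
        v[b0:b1] *= 0.1

    # IP: sparse background fragments plus Gaussian bumps at signal motifs
    ip_values = {}
    for chrom, length in genome.chroms:
        v = np.zeros(length // spec.bin_size)
        n_frag = int(rng.poisson(spec.noise_fragment_rate * length))
        starts = rng.integers(0, length - spec.noise_fragment_length, size=n_frag)
        heights = rng.exponential(spec.noise_sd, size=n_frag)
        for s, h in zip(starts, heights):
            b0 = int(s) // spec.bin_size
            b1 = min(len(v), (int(s) + spec.noise_fragment_length) // spec.bin_size + 1)
            v[b0:b1] += h
        ip_values[chrom] = v
    ip = SignalTrack(
        genome, spec.bin_size, ip_values,
        {c: np.ones(len(v), bool) for c, v in ip_values.items()},
    )
    for m, cls in zip(motifs, motif_classes):
        if cls == "bound":
            _add_bump(ip.values[m.chrom], spec.bin_size, m.center,
                      spec.bound_signal_mean, spec.bump_sd)
        elif cls == "sampled":
            _add_bump(ip.values[m.chrom], spec.bin_size, m.center,
                      spec.sampled_signal_mean, spec.bump_sd)
    for chrom in genome.names:
        np.maximum(ip.values[chrom], 0.0, out=ip.values[chrom])

    # peaks at bound motifs, two pseudo-replicates with optional dropout
    def peak_at(m: GenomeInterval, rep: str) -> Peak:
        s = m.center - spec.peak_halfwidth
        e = m.center + spec.peak_halfwidth
        return Peak(
            GenomeInterval(m.chrom, s, e, name=f"peak_{m.name}"),
            summit_offset=spec.peak_halfwidth,
            enrichment=spec.bound_signal_mean,
            replicate_id=rep,
        )

    bound_motifs = [m for m, c in zip(motifs, motif_classes) if c == "bound"]
    keep = rng.random((2, len(bound_motifs))) >= spec.replicate_dropout
    rep1 = [peak_at(m, "rep1") for i, m in enumerate(bound_motifs) if keep[0, i]]
    rep2 = [peak_at(m, "rep2") for i, m in enumerate(bound_motifs) if keep[1, i]]
    consensus = [
        peak_at(m, "consensus")
        for i, m in enumerate(bound_motifs)
        if keep[0, i] and keep[1, i]
    ]
    peak_open = [
        state_bins[p.chrom][p.summit // spec.bin_size] == oid for p in consensus
    ]

    truth = SyntheticTruth(
        motif_classes=motif_classes,
        peak_open=peak_open,
        domains=domains,
        gaps=gaps,
        hetero_sites=hetero_sites,
        segmentation=segmentation,
    )
    return SyntheticData(
        spec=spec,
        genome=genome,
        sequence=sequence,
        tracks={"dnase": dnase, "h2b": h2b, "H3K9me3": k9, "H3K27me3": k27, "ip": ip},
        peak_replicates=[rep1, rep2],
        peaks=consensus,
        motifs=motifs,
        truth=truth,
    )


def write_fixture(outdir: str | Path, data: SyntheticData) -> list[Path]:
    """Write the bundle as plain-text files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / "genome.chrom.sizes"
    with open(p, "w") as fh:
        for chrom, length in data.genome.chroms:
            fh.write(f"{chrom}\t{length}\n")
    written.append(p)

    for name, track in data.tracks.items():
        p = outdir / f"{name}.bedGraph"
        write_bedgraph(p, track)
        written.append(p)

    for i, reps in enumerate(data.peak_replicates, 1):
        p = outdir / f"peaks_rep{i}.narrowPeak"
        write_bed(p, reps)
        written.append(p)
    p = outdir / "peaks_consensus.narrowPeak"
    write_bed(p, data.peaks)
    written.append(p)

    p = outdir / "motifs.bed"
    write_bed(p, data.motifs)
    written.append(p)

    p = outdir / "segmentation.bed"
    write_segmentation(p, data.truth.segmentation)
    written.append(p)

    p = outdir / "truth.tsv"
    rows = [
        {
            "name": m.name,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
            "true_class": cls,
        }
        for m, cls in zip(data.motifs, data.truth.motif_classes)
    ]
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    written.append(p)

    p = outdir / "genome.fa"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="synthetic")
         for chrom, seq in data.sequence.items()],
        p,
        "fasta",
    )
    written.append(p)
    return written
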
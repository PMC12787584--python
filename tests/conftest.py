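import numpy as np
import pytest

from pioneerscan import (
    GenomeDescription,
    GenomeInterval,
    SignalTrack,
    SyntheticGenomeSpec,
    generate,
)


def make_random_track(
    rng: np.random.Generator,
    genome: GenomeDescription,
    bin_size: int,
    cover_prob: float = 0.8,
) -> SignalTrack:
    values, covered = {}, {}
    for chrom, length in genome.chroms:
        n = -(-length // bin_size)
        covered[chrom] = rng.random(n) < cover_prob
        values[chrom] = rng.normal(1.0, 2.0, n)
    return SignalTrack(genome, bin_size, values, covered)


def per_base_view(track: SignalTrack, chrom: str):
    """Independent per-base expansion used by brute-force oracles."""
    length = track.genome.length(chrom)
    v = np.repeat(np.asarray(track.values[chrom]), track.bin_size)[:length]
    c = np.repeat(np.asarray(track.covered[chrom]), track.bin_size)[:length]
    return np.where(c, v, 0.0), c


def oracle_interval_mean(track: SignalTrack, iv: GenomeInterval):
    v, c = per_base_view(track, iv.chrom)
    seg_v, seg_c = v[iv.start : iv.end], c[iv.start : iv.end]
    return seg_v.sum() / len(seg_v), seg_c.mean()


def random_intervals(rng, genome, n, max_len=200):
    out = []
    for _ in range(n):
        chrom, length = genome.chroms[rng.integers(len(genome.chroms))]
        start = int(rng.integers(0, length - 1))
        end = int(min(length, start + 1 + rng.integers(max_len)))
        out.append(GenomeInterval(chrom, start, end))
    return out


@pytest.fixture(scope="session")
def small_genome():
    return GenomeDescription.from_pairs([("chr1", 10_000), ("chr2", 7_003)])


@pytest.fixture(scope="session")
def default_data():
    """The default synthetic study genome, fixed seed."""
    return generate(SyntheticGenomeSpec(seed=1))


@pytest.fixture(scope="session")
def hetero_data():
    """Heterochromatin-heavy genome for local-density subtype recovery."""
    spec = SyntheticGenomeSpec(
        seed=2,
        state_fractions={
            "open_naive": 0.15,
            "closed_naive": 0.25,
            "K9_domain": 0.30,
            "K27_domain": 0.30,
        },
        n_hetero_sites=110,
        n_motifs=200,
    )
    return generate(spec)
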
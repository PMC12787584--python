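import numpy as np
import pytest
from scipy.stats import binom

from pioneerscan import (
    GenomeDescription,
    GenomeInterval,
    PWM,
    Peak,
    SignalTrack,
    SyntheticGenomeSpec,
    binned_motif_enrichment,
    classify_accessibility,
    classify_turnover,
    closed_fraction,
    generate,
    motif_accessibility_split,
)
from pioneerscan.accessibility import _equal_size_bins


def track_with_values(genome, per_chrom_values, bin_size=10):
    return SignalTrack(
        genome, bin_size,
        per_chrom_values,
        {c: np.ones(len(v), bool) for c, v in per_chrom_values.items()},
    )


@pytest.fixture(scope="module")
def genome():
    return GenomeDescription.from_pairs([("chr1", 10_000)])


class TestClassifyAccessibility:
    def test_cutoff_predicate(self, genome):
        vals = np.zeros(1000)
        vals[0:10] = 0.07   # peak 1: above cutoff
        vals[20:30] = 0.0   # peak 2: zero
        vals[40:50] = 0.05  # peak 3: exact tie
        dnase = track_with_values(genome, {"chr1": vals})
        peaks = [
            Peak(GenomeInterval("chr1", 0, 100)),
            Peak(GenomeInterval("chr1", 200, 300)),
            Peak(GenomeInterval("chr1", 400, 500)),
        ]
        calls = classify_accessibility(peaks, dnase)
        assert calls[0].label == "accessible"
        assert calls[1].label == "resistant"
        # exact tie at the cutoff goes to resistant
        tie = classify_accessibility(
            [Peak(GenomeInterval("chr1", 400, 410))], dnase
        )[0]
        assert tie.dnase_mean == pytest.approx(0.05)
        assert tie.label == "resistant"

    def test_empty_peak_list_rejected(self, genome):
        with pytest.raises(ValueError):
            classify_accessibility([], track_with_values(genome, {"chr1": np.zeros(1000)}))

    def test_fractions_complementary(self, genome):
        rng = np.random.default_rng(0)
        dnase = track_with_values(genome, {"chr1": rng.exponential(0.05, 1000)})
        peaks = [
            Peak(GenomeInterval("chr1", i, i + 50)) for i in range(0, 5000, 100)
        ]
        calls = classify_accessibility(peaks, dnase)
        open_frac = sum(c.label == "accessible" for c in calls) / len(calls)
        assert open_frac + closed_fraction(calls) == pytest.approx(1.0)

    def test_monotone_in_cutoff(self, genome):
        rng = np.random.default_rng(1)
        dnase = track_with_values(genome, {"chr1": rng.exponential(0.05, 1000)})
        peaks = [
            Peak(GenomeInterval("chr1", i, i + 50)) for i in range(0, 5000, 100)
        ]
        prev_accessible = None
        for cutoff in (0.01, 0.05, 0.1, 0.5):
            acc = {
                id(c.peak)
                for c in classify_accessibility(peaks, dnase, cutoff)
                if c.label == "accessible"
            }
            if prev_accessible is not None:
                assert acc <= prev_accessible
            prev_accessible = acc

    @pytest.mark.parametrize("p_open", [0.2, 0.5, 0.8])
    def test_planted_open_fraction_recovered(self, p_open):
        rest = (1 - p_open) / 3
        spec = SyntheticGenomeSpec(
            n_chroms=2,
            chrom_length=1_000_000,
            n_motifs=400,
            n_hetero_sites=0,
            state_fractions={
                "open_naive": p_open,
                "closed_naive": rest,
                "K9_domain": rest,
                "K27_domain": 1 - p_open - 2 * rest,
            },
            seed=7,
        )
        data = generate(spec)
        peaks = [Peak(GenomeInterval(m.chrom, m.center - 50, m.center + 50))
                 for m in data.motifs]
        calls = classify_accessibility(peaks, data.tracks["dnase"])
        k = sum(c.label == "accessible" for c in calls)
        n = len(calls)
        lo, hi = binom.ppf(0.005, n, p_open), binom.ppf(0.995, n, p_open)
        assert lo <= k <= hi


class TestClassifyTurnover:
    def test_zero_track_all_low(self, genome):
        h2b = track_with_values(genome, {"chr1": np.zeros(1000)})
        peaks = [Peak(GenomeInterval("chr1", i, i + 50)) for i in range(0, 1000, 100)]
        calls = classify_accessibility(peaks, h2b, cutoff=0.0)
        calls = classify_turnover(calls, h2b)
        assert all(c.turnover_label == "low" for c in calls)

    def test_infinite_cutoff_all_low(self, genome):
        rng = np.random.default_rng(2)
        h2b = track_with_values(genome, {"chr1": rng.exponential(1.0, 1000)})
        peaks = [Peak(GenomeInterval("chr1", i, i + 50)) for i in range(0, 1000, 100)]
        calls = classify_turnover(
            classify_accessibility(peaks, h2b), h2b, cutoff=np.inf
        )
        assert all(c.turnover_label == "low" for c in calls)

    def test_planted_high_turnover_recovered(self, default_data):
        h2b = default_data.tracks["h2b"]
        seg = default_data.truth.segmentation
        open_ivs = [iv for iv in seg.intervals if iv.name == "1"]
        peaks = [
            Peak(GenomeInterval(iv.chrom, iv.center - 50, iv.center + 50))
            for iv in open_ivs
        ]
        closed_ivs = [iv for iv in seg.intervals if iv.name == "2"][: len(peaks)]
        peaks += [
            Peak(GenomeInterval(iv.chrom, iv.center - 50, iv.center + 50))
            for iv in closed_ivs
        ]
        calls = classify_turnover(
            classify_accessibility(peaks, default_data.tracks["dnase"]), h2b
        )
        high = [c for c, iv in zip(calls, open_ivs) if c.turnover_label == "high"]
        assert len(high) >= 0.95 * len(open_ivs)


class TestMotifSplit:
    def test_all_zero_dnase_all_inaccessible(self, genome):
        dnase = track_with_values(genome, {"chr1": np.zeros(1000)})
        motifs = [GenomeInterval("chr1", i, i + 7) for i in range(100, 1000, 100)]
        split = motif_accessibility_split(motifs, dnase)
        assert split.accessible == []
        assert len(split.inaccessible) == len(motifs)

    def test_planted_state_recovery(self, default_data):
        seg = default_data.truth.segmentation
        state_of = {}
        for iv in seg.intervals:
            state_of[(iv.chrom, iv.start)] = iv
        split = motif_accessibility_split(
            default_data.motifs, default_data.tracks["dnase"]
        )
        open_set = {
            m
            for m in default_data.motifs
            if any(
                iv.chrom == m.chrom and iv.start <= m.center < iv.end
                for iv in seg.intervals
                if iv.name == "1"
            )
        }
        acc = set(split.accessible)
        correct = len(acc & open_set) + len(
            (set(default_data.motifs) - acc) - open_set
        )
        assert correct / len(default_data.motifs) >= 0.95

    def test_recovered_split_fraction_close_to_planted(self):
        spec = SyntheticGenomeSpec(
            n_chroms=2,
            chrom_length=1_000_000,
            n_motifs=500,
            n_hetero_sites=0,
            state_fractions={
                "open_naive": 0.5,
                "closed_naive": 0.3,
                "K9_domain": 0.1,
                "K27_domain": 0.1,
            },
            seed=11,
        )
        data = generate(spec)
        split = motif_accessibility_split(data.motifs, data.tracks["dnase"])
        frac = len(split.accessible) / len(data.motifs)
        assert abs(frac - 0.5) <= 0.03 + 3 * np.sqrt(0.25 / 500)


class TestBinnedEnrichment:
    @staticmethod
    def _fixture(seed=0, planted_bin=None, uniform=False):
        """120 peaks on one chromosome; motif planted per scenario."""
        rng = np.random.default_rng(seed)
        n = 120
        genome = GenomeDescription.from_pairs([("chr1", 200_000)])
        seq = rng.choice(list("ACGT"), size=200_000)
        motif = "TTGACA"
        dnase_values = np.linspace(0.001, 1.0, n)
        peaks = []
        for i in range(n):
            s = 500 + i * 1500
            peaks.append(Peak(GenomeInterval("chr1", s, s + 200)))
        order = np.argsort(dnase_values, kind="stable")
        bins = _equal_size_bins(order, 10)
        for b, idx in enumerate(bins):
            for i in idx:
                plant = uniform or (planted_bin is not None and b == planted_bin)
                if plant:
                    c = peaks[i].interval.center
                    seq[c - 3 : c + 3] = list(motif)
        pwm = PWM.from_consensus(motif, strength=0.97, name="planted")
        pwm = PWM(pwm.matrix, pwm.background, 0.0, pwm.max_score() - 1e-6, "planted")
        return peaks, dnase_values, [pwm], {"chr1": "".join(seq)}

    def test_uniform_motif_not_reported(self):
        peaks, dnase, pwms, seqs = self._fixture(uniform=True)
        res = binned_motif_enrichment(peaks, dnase, pwms, seqs)
        assert not res.table["enriched"].any()
        assert np.allclose(res.table["log2_enrichment"], 0.0, atol=0.2)

    def test_planted_top_bin_motif_reported(self):
        peaks, dnase, pwms, seqs = self._fixture(planted_bin=9)
        res = binned_motif_enrichment(peaks, dnase, pwms, seqs)
        top = res.table[(res.table["bin"] == 9)]
        assert top["enriched"].all()
        others = res.table[res.table["bin"] < 9]
        assert not others["enriched"].any()

    def test_remainder_goes_to_last_bin(self):
        order = np.arange(25)
        bins = _equal_size_bins(order, 10)
        assert [len(b) for b in bins] == [2] * 9 + [7]
        assert np.concatenate(bins).tolist() == list(range(25))

    def test_bins_partition_peaks(self):
        peaks, dnase, pwms, seqs = self._fixture(planted_bin=0)
        res = binned_motif_enrichment(peaks, dnase, pwms, seqs)
        assert sum(res.bin_sizes) == len(peaks)

    def test_too_few_peaks_rejected(self):
        peaks, dnase, pwms, seqs = self._fixture()
        with pytest.raises(ValueError):
            binned_motif_enrichment(peaks[:5], dnase[:5], pwms, seqs)
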
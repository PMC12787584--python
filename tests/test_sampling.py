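import itertools

import numpy as np
import pytest

from pioneerscan import (
    GenomeDescription,
    GenomeInterval,
    PWM,
    Peak,
    SignalTrack,
    classify_motifs,
    scan_pwm,
    shift_background,
    transition_table,
)
from pioneerscan.sampling import SamplingResult


@pytest.fixture(scope="module")
def pwm4():
    return PWM.from_consensus("ACGT", strength=0.91, name="toy")


class TestScan:
    def test_exhaustive_log_odds_oracle(self, pwm4):
        # score every 4-mer window by an explicit log2(p/q) sum
        lod = np.log2(
            pwm4.matrix / 0.25
        )
        seq = "".join("".join(w) for w in itertools.product("ACGT", repeat=4))
        hits = scan_pwm({"chr1": seq}, pwm4, score_threshold=-np.inf)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        comp = str.maketrans("ACGT", "TGCA")
        for h in hits:
            window = seq[h.start : h.end]
            fwd = sum(lod[idx[b], j] for j, b in enumerate(window))
            rev = sum(
                lod[idx[b], j]
                for j, b in enumerate(window.translate(comp)[::-1])
            )
            assert h.score == pytest.approx(max(fwd, rev), abs=1e-9)

    def test_planted_consensus_recovered_exactly(self):
        pwm = PWM.from_consensus("TTGACA", strength=0.97, name="p")
        rng = np.random.default_rng(5)
        seq = list("".join(rng.choice(list("ACGT"), size=2000)))
        planted = [100, 500, 1500]
        for pos in planted:
            seq[pos : pos + 6] = "TTGACA"
        # strand hit: plant the reverse complement too
        seq[1000:1006] = "TGTCAA"
        seq_s = "".join(seq)
        hits = scan_pwm({"chr1": seq_s}, pwm, score_threshold=pwm.max_score() - 1e-9)
        starts = {(h.start, h.strand) for h in hits}
        assert {(100, "+"), (500, "+"), (1500, "+"), (1000, "-")} <= starts
        # no other position matches the consensus at the max-score threshold
        comp = str.maketrans("ACGT", "TGCA")
        rc = "TTGACA".translate(comp)[::-1]
        for h in hits:
            assert seq_s[h.start : h.end] in ("TTGACA", rc)

    def test_uniform_pwm_scores_zero(self):
        uni = PWM(np.full((4, 5), 0.25), name="uniform")
        hits = scan_pwm({"chr1": "ACGTACGTACGT"}, uni, score_threshold=1e-9)
        assert hits == []
        all_hits = scan_pwm({"chr1": "ACGTACGTACGT"}, uni, score_threshold=0.0)
        assert all(h.score == 0.0 for h in all_hits)

    def test_windows_with_n_are_skipped(self, pwm4):
        hits = scan_pwm({"chr1": "ACNTACGT"}, pwm4, score_threshold=-100.0)
        assert all("N" not in "ACNTACGT"[h.start : h.end] for h in hits)

    def test_palindrome_dedup_prefers_plus_strand(self):
        pwm = PWM.from_consensus("ACGT", strength=0.97)  # palindromic consensus
        hits = scan_pwm({"chr1": "AAACGTAA"}, pwm, score_threshold=1.0)
        at_locus = [h for h in hits if h.start == 2]
        assert len(at_locus) == 1
        assert at_locus[0].strand == "+"

    def test_empty_sequence_rejected(self, pwm4):
        with pytest.raises(ValueError):
            scan_pwm({}, pwm4)


class TestShiftBackground:
    def test_plus_10kb(self):
        g = GenomeDescription.from_pairs([("chr1", 20_000)])
        shifted, dropped = shift_background(
            [GenomeInterval("chr1", 0, 10)], g, shift=10_000
        )
        assert shifted == [GenomeInterval("chr1", 10_000, 10_010)]
        assert dropped == 0

    def test_interval_past_chromosome_end_dropped(self):
        g = GenomeDescription.from_pairs([("chr1", 10_010)])
        shifted, dropped = shift_background(
            [GenomeInterval("chr1", 0, 10), GenomeInterval("chr1", 100, 110)],
            g,
            shift=10_000,
        )
        assert dropped == 1
        assert shifted == [GenomeInterval("chr1", 10_000, 10_010)]

    def test_shift_composition(self):
        g = GenomeDescription.from_pairs([("chr1", 100_000)])
        ivs = [GenomeInterval("chr1", i * 1000, i * 1000 + 10) for i in range(20)]
        once, _ = shift_background(ivs, g, shift=10_000)
        twice, _ = shift_background(*(shift_background(ivs, g, 5_000)[:1]), shift=5_000, genome=g)
        assert once == twice


def _flat_track(genome, value=0.0, bin_size=10):
    n = {c: -(-l // bin_size) for c, l in genome.chroms}
    return SignalTrack(
        genome, bin_size,
        {c: np.full(k, float(value)) for c, k in n.items()},
        {c: np.ones(k, bool) for c, k in n.items()},
    )


class TestClassifyMotifs:
    def test_all_zero_ip_everything_unsampled(self):
        g = GenomeDescription.from_pairs([("chr1", 100_000)])
        motifs = [GenomeInterval("chr1", i, i + 7) for i in range(500, 50_000, 1000)]
        res = classify_motifs(motifs, _flat_track(g), peaks=[])
        assert res.fractions == {"bound": 0.0, "sampled": 0.0, "unsampled": 1.0}

    def test_coverage_filter_marks_filtered(self):
        g = GenomeDescription.from_pairs([("chr1", 100_000)])
        track = _flat_track(g, 1.0)
        # strip coverage under the first motif's central window
        track.covered["chr1"][0:100] = False
        track.values["chr1"][0:100] = 0.0
        motifs = [
            GenomeInterval("chr1", 500, 507),
            GenomeInterval("chr1", 5_000, 5_007),
        ]
        res = classify_motifs(motifs, track, peaks=[])
        by_start = {m.interval.start: m.klass for m in res.instances}
        assert by_start[500] == "filtered"
        assert by_start[5_000] != "filtered"
        assert res.n_unfiltered == 1

    def test_bound_requires_only_peak_overlap(self):
        g = GenomeDescription.from_pairs([("chr1", 100_000)])
        motifs = [GenomeInterval("chr1", 500, 507)]
        peaks = [Peak(GenomeInterval("chr1", 400, 600))]
        res = classify_motifs(motifs, _flat_track(g), peaks)
        assert res.instances[0].klass == "bound"

    def test_fraction_recovery_on_default_genome(self, default_data):
        res = classify_motifs(
            default_data.motifs, default_data.tracks["ip"], default_data.peaks
        )
        truth = default_data.truth.motif_classes
        n = len(truth)
        for cls in ("bound", "sampled", "unsampled"):
            true_frac = truth.count(cls) / n
            assert abs(res.fractions[cls] - true_frac) <= 0.02

    def test_background_quantile_monotone(self, default_data):
        args = (default_data.motifs, default_data.tracks["ip"], default_data.peaks)
        sampled = {}
        for q in (0.8, 0.95, 0.99):
            res = classify_motifs(*args, background_quantile=q)
            sampled[q] = {
                m.interval for m in res.instances if m.klass == "sampled"
            }
        assert sampled[0.99] <= sampled[0.95] <= sampled[0.8]

    def test_bound_calls_invariant_to_quantile(self, default_data):
        args = (default_data.motifs, default_data.tracks["ip"], default_data.peaks)
        bounds = [
            {m.interval for m in classify_motifs(*args, background_quantile=q).instances
             if m.klass == "bound"}
            for q in (0.5, 0.95)
        ]
        assert bounds[0] == bounds[1]

    def test_signal_rank_tracks_true_class(self, default_data):
        from scipy.stats import spearmanr

        res = classify_motifs(
            default_data.motifs, default_data.tracks["ip"], default_data.peaks
        )
        ordinal = {"bound": 2, "sampled": 1, "unsampled": 0}
        truth_by_iv = {
            m: ordinal[c]
            for m, c in zip(default_data.motifs, default_data.truth.motif_classes)
        }
        xs = [truth_by_iv[m.interval] for m in res.instances]
        ys = [m.central_signal for m in res.instances]
        rho = spearmanr(xs, ys).statistic
        assert rho > 0.8

    def test_fractions_sum_to_one(self, default_data):
        res = classify_motifs(
            default_data.motifs, default_data.tracks["ip"], default_data.peaks
        )
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_instances_sorted_high_to_low(self, default_data):
        res = classify_motifs(
            default_data.motifs, default_data.tracks["ip"], default_data.peaks
        )
        signals = [m.central_signal for m in res.instances]
        assert signals == sorted(signals, reverse=True)


def _result_with_classes(motifs, classes):
    from pioneerscan.sampling import MotifInstance

    instances = [
        MotifInstance(m, None, 0.0, 1.0, c) for m, c in zip(motifs, classes)
    ]
    n_unf = sum(c != "filtered" for c in classes)
    return SamplingResult(
        instances=instances,
        background_threshold=0.0,
        fractions={},
        n_total=len(motifs),
        n_unfiltered=n_unf,
        background_dropped=0,
    )


@pytest.fixture(scope="module")
def motifs():
    return [GenomeInterval("chr1", i, i + 7) for i in range(0, 500, 10)]


class TestTransitions:

    def test_identical_conditions_give_diagonal(self, motifs):
        rng = np.random.default_rng(0)
        classes = list(rng.choice(["bound", "sampled", "unsampled"], size=len(motifs)))
        t = transition_table(
            _result_with_classes(motifs, classes),
            _result_with_classes(motifs, classes),
        )
        assert t.values.sum() == len(motifs)
        assert np.all(t.values == np.diag(np.diag(t.values)))

    def test_constructed_sampled_to_bound_shift(self, motifs):
        a = ["sampled"] * 10 + ["unsampled"] * (len(motifs) - 10)
        b = ["bound"] * 10 + ["unsampled"] * (len(motifs) - 10)
        t = transition_table(
            _result_with_classes(motifs, a), _result_with_classes(motifs, b)
        )
        assert t.loc["sampled", "bound"] == 10
        assert t.loc["unsampled", "unsampled"] == len(motifs) - 10

    def test_total_is_common_unfiltered_count(self, motifs):
        rng = np.random.default_rng(1)
        opts = ["bound", "sampled", "unsampled", "filtered"]
        a = list(rng.choice(opts, size=len(motifs)))
        b = list(rng.choice(opts, size=len(motifs)))
        t = transition_table(
            _result_with_classes(motifs, a), _result_with_classes(motifs, b)
        )
        expected = sum(
            1 for x, y in zip(a, b) if x != "filtered" and y != "filtered"
        )
        assert t.values.sum() == expected

    def test_mismatched_motif_lists_rejected(self, motifs):
        a = _result_with_classes(motifs, ["unsampled"] * len(motifs))
        b = _result_with_classes(motifs[:-1], ["unsampled"] * (len(motifs) - 1))
        with pytest.raises(ValueError):
            transition_table(a, b)
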
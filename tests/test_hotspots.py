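import itertools
import math

import numpy as np
import pytest
from scipy import stats

from meiohot.coverage import SignalMatrix
from meiohot.hotspots import (
    PWM,
    MotifHit,
    SpikeSpec,
    assign_allele_by_motif,
    center_and_filter_hotspots,
    central_flank_decomposition,
    classify_hybrid_hotspots,
    decompose_profile,
    dual_mark_classes,
    scan_motif,
    scan_sequence,
    spikein_normalize,
    strength_correlation,
)
from meiohot.intervals import GenomicInterval, IntervalSet

RC = str.maketrans("ACGT", "TGCA")


def naive_window_score(seq, pwm, i):
    """Independent per-base log-odds scorer."""
    total = 0.0
    for j, base in enumerate(seq[i: i + len(pwm)]):
        k = "ACGT".index(base)
        total += math.log2(pwm.probs[j, k] / pwm.background[k])
    return total


class TestPWM:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM(np.full((6, 4), 0.3))

    def test_consensus_round_trip(self):
        pwm = PWM.from_consensus("ACGTACGT")
        assert pwm.consensus == "ACGTACGT"

    def test_tsv_round_trip(self, tmp_path):
        pwm = PWM.from_consensus("ACGTAC")
        p = tmp_path / "pwm.tsv"
        pwm.write_tsv(p)
        again = PWM.read_tsv(p)
        np.testing.assert_allclose(again.probs, pwm.probs)


class TestScanMotif:
    def test_planted_consensus_found_at_exact_positions(self, rng):
        motif = "CCTCCCTAGCCACG"
        pwm = PWM.from_consensus(motif)
        seq = list("".join(rng.choice(list("ACGT"), size=20_000)))
        positions = list(range(100, 19_000, 380))[:50]
        for p in positions:
            seq[p: p + len(motif)] = motif
        hits = scan_sequence("".join(seq), pwm, threshold=15.0)
        found = {h.start for h in hits if h.strand == "+"}
        assert set(positions) <= found

    def test_reverse_complement_symmetry(self):
        motif = "CCTAGCCACGTAAT"
        pwm = PWM.from_consensus(motif)
        pad = "A" * 40
        fwd_seq = pad + motif + pad
        rc_seq = pad + motif.translate(RC)[::-1] + pad
        fwd_hit = max(scan_sequence(fwd_seq, pwm, 10.0), key=lambda h: h.score)
        rc_hit = max(scan_sequence(rc_seq, pwm, 10.0), key=lambda h: h.score)
        assert fwd_hit.strand == "+" and rc_hit.strand == "-"
        assert fwd_hit.score == pytest.approx(rc_hit.score)
        assert fwd_hit.start == rc_hit.start == 40

    def test_matches_brute_force_enumeration(self, rng):
        pwm = PWM.from_counts(rng.integers(1, 40, size=(8, 4)))
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        hits = scan_sequence(seq, pwm, threshold=-5.0)
        for h in hits:
            window = seq if h.strand == "+" else seq.translate(RC)[::-1]
            i = h.start if h.strand == "+" else len(seq) - h.end
            assert h.score == pytest.approx(naive_window_score(window, pwm, i))
        # accepted hits are non-overlapping and each passes threshold
        hits_sorted = sorted(hits, key=lambda h: h.start)
        for a, b in zip(hits_sorted, hits_sorted[1:]):
            assert a.end <= b.start
        assert all(h.score >= -5.0 for h in hits)

    def test_sequence_shorter_than_motif_errors(self):
        with pytest.raises(ValueError):
            scan_sequence("ACG", PWM.from_consensus("ACGTA"), 0.0)


class TestCenterAndFilter:
    def _hit(self, start, length=16, chrom="chr1"):
        return MotifHit(chrom, start, "+", 20.0, length)

    def test_single_hit_centered_at_midpoint(self):
        hs = IntervalSet([GenomicInterval("chr1", 500, 1500)])
        anchors, report = center_and_filter_hotspots(hs, [self._hit(1000)])
        assert list(anchors.positions) == [1008]
        assert report == {"kept": 1, "zero_motif": 0, "multi_motif": 0}

    def test_multi_motif_hotspot_excluded(self):
        hs = IntervalSet([GenomicInterval("chr1", 500, 1500)])
        anchors, report = center_and_filter_hotspots(
            hs, [self._hit(600), self._hit(1200)]
        )
        assert len(anchors) == 0
        assert report["multi_motif"] == 1

    def test_zero_motif_hotspot_excluded(self):
        hs = IntervalSet([GenomicInterval("chr1", 500, 1500)])
        anchors, report = center_and_filter_hotspots(hs, [])
        assert len(anchors) == 0 and report["zero_motif"] == 1

    def test_empty_hotspots(self):
        anchors, _ = center_and_filter_hotspots(IntervalSet(), [self._hit(10)])
        assert len(anchors) == 0


class TestHybridClassification:
    def test_toy_case_matches_exhaustive_check(self):
        f1 = IntervalSet([GenomicInterval("chr1", i * 1000, i * 1000 + 500)
                          for i in range(6)])
        b6 = IntervalSet([GenomicInterval("chr1", 0, 400),
                          GenomicInterval("chr1", 2000, 2100)])
        cast = IntervalSet([GenomicInterval("chr1", 2050, 2400),
                            GenomicInterval("chr1", 4000, 4010)])
        out = classify_hybrid_hotspots(f1, b6, cast)
        expected = []
        for iv in f1:
            inb = any(iv.overlap_bp(x) for x in b6)
            inc = any(iv.overlap_bp(x) for x in cast)
            expected.append(
                "shared-both" if inb and inc else
                "shared-B6" if inb else "shared-CAST" if inc else "novel"
            )
        assert out["class"].tolist() == expected
        assert expected.count("novel") == out.attrs["counts"].get("novel", 0)


class TestAlleleAssignment:
    def test_identical_pwms_all_ambiguous(self, small_genome):
        genome, truth = small_genome
        pwm = PWM.from_consensus(truth.motifs["Dom2"])
        calls = assign_allele_by_motif(
            truth.intervals(genome.lengths), genome.chroms, pwm, pwm
        )
        assert (calls["allele"] == "ambiguous").all()

    def test_infinite_margin_all_ambiguous(self, small_genome):
        genome, truth = small_genome
        pa = PWM.from_consensus(truth.motifs["Dom2"])
        pb = PWM.from_consensus(truth.motifs["Cast"])
        calls = assign_allele_by_motif(
            truth.intervals(genome.lengths), genome.chroms, pa, pb,
            margin=np.inf,
        )
        assert (calls["allele"] == "ambiguous").all()

    def test_planted_alleles_recovered(self, small_genome):
        genome, truth = small_genome
        pa = PWM.from_consensus(truth.motifs["Dom2"])
        pb = PWM.from_consensus(truth.motifs["Cast"])
        calls = assign_allele_by_motif(
            truth.intervals(genome.lengths), genome.chroms, pa, pb
        )
        expected = truth.table.sort_values(["chrom", "center"])["allele"].tolist()
        assert calls["allele"].tolist() == expected


class TestDualMarkClasses:
    def test_identical_sets_all_both(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100)])
        df, summary = dual_mark_classes(s, s, s)
        assert summary["fractions"] == {"both": 1.0}

    def test_fractions_partition(self):
        zc = IntervalSet([GenomicInterval("chr1", i * 1000, i * 1000 + 100)
                          for i in range(10)])
        k4 = IntervalSet([GenomicInterval("chr1", 0, 3100)])
        k36 = IntervalSet([GenomicInterval("chr1", 2000, 5100)])
        _, summary = dual_mark_classes(zc, k4, k36)
        assert sum(summary["fractions"].values()) == pytest.approx(1.0)

    def test_planted_strength_elevation_detected(self, rng):
        # both-class peaks carry higher strengths; rank-sum should see it
        n = 400
        ivs = [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(n)]
        zc = IntervalSet(ivs)
        both_end = int(0.85 * n)
        k4 = IntervalSet(ivs[: both_end + 40])  # both + K4-only
        k36 = IntervalSet(ivs[:both_end] + ivs[both_end + 40: both_end + 52])
        strengths = np.concatenate([
            rng.normal(100, 10, size=both_end),
            rng.normal(60, 10, size=n - both_end),
        ])
        _, summary = dual_mark_classes(zc, k4, k36, strengths)
        for res in summary["rank_sum_both_greater"].values():
            assert res["p"] < 0.01


class TestSpikeNormalization:
    def _reads(self, rng, n_hot, n_spike):
        chroms = ["chr1"] * n_hot + ["chrS"] * n_spike
        pos = np.concatenate([
            rng.integers(47_000, 53_000, size=n_hot),
            rng.integers(49_000, 51_000, size=n_spike),
        ])
        return chroms, pos

    def test_five_percent_spike_divides_by_twenty(self):
        assert SpikeSpec("chrS", 50_000, 0.05).divisor == pytest.approx(20.0)

    def test_duplication_invariance_exact(self, rng):
        windows = IntervalSet([GenomicInterval("chr1", 47_000, 53_000)])
        spike = SpikeSpec("chrS", 50_000, 0.05)
        chroms, pos = self._reads(rng, 5000, 250)
        once = spikein_normalize(chroms, pos, windows, spike)
        twice = spikein_normalize(chroms * 2, np.concatenate([pos, pos]), windows, spike)
        assert once["normalized"] == pytest.approx(twice["normalized"], rel=1e-12)

    def test_zero_spike_signal_errors(self, rng):
        windows = IntervalSet([GenomicInterval("chr1", 47_000, 53_000)])
        spike = SpikeSpec("chrS", 50_000, 0.05)
        chroms, pos = self._reads(rng, 100, 0)
        with pytest.raises(ValueError):
            spikein_normalize(chroms, pos, windows, spike)

    def test_invalid_spike_fraction_rejected(self):
        with pytest.raises(ValueError):
            SpikeSpec("chrS", 100, 0.0)


def _matrix_from_profile(profile, flank, binsize):
    return SignalMatrix(np.asarray([profile], dtype=float), flank, binsize)


class TestDecomposition:
    def _profile(self, central, flank_val, flank=3000, binsize=50):
        ncol = 2 * flank // binsize
        centers = -flank + binsize * np.arange(ncol) + binsize / 2
        vals = np.where(np.abs(centers) < 250, central, flank_val)
        return _matrix_from_profile(vals, flank, binsize)

    def test_identical_samples_unit_ratios(self):
        m = self._profile(10.0, 2.0)
        out = central_flank_decomposition({"a": m, "b": m}, contrast=("a", "b"))
        assert out["contrast"]["flank_ratio"] == pytest.approx(1.0)
        assert out["contrast"]["central_ratio"] == pytest.approx(1.0)

    def test_windows_partition_total_mass(self):
        m = self._profile(10.0, 2.0, flank=4000)
        d = decompose_profile(m, central_halfwidth=250, flank_range=(250, 3000))
        prof = m.mean_profile
        centers = m.offsets + m.binsize / 2
        central_mask = np.abs(centers) < 250
        flank_mask = (np.abs(centers) >= 250) & (np.abs(centers) <= 3000)
        outside = ~(central_mask | flank_mask)
        total = prof.sum()
        assert (prof[central_mask].sum() + prof[flank_mask].sum()
                + prof[outside].sum()) == pytest.approx(total)

    def test_insufficient_flank_errors(self):
        m = self._profile(1.0, 1.0, flank=1000)
        with pytest.raises(ValueError):
            decompose_profile(m, flank_range=(250, 3000))


class TestStrengthCorrelation:
    def _table(self, rng, n=50):
        import pandas as pd

        x = rng.normal(size=n)
        return pd.DataFrame({"x": x, "y": x + rng.normal(size=n), "neg": -x})

    def test_self_correlation_is_one(self, rng):
        t = self._table(rng)
        assert strength_correlation(t, "x", "x")["rho"] == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        t = self._table(rng)
        assert strength_correlation(t, "x", "neg")["rho"] == pytest.approx(-1.0)

    def test_constant_metric_errors(self, rng):
        t = self._table(rng)
        t["c"] = 1.0
        with pytest.raises(ValueError):
            strength_correlation(t, "x", "c")

    def test_toy_p_matches_exhaustive_permutation(self, rng):
        import pandas as pd

        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        t = pd.DataFrame({"x": x, "y": y})
        res = strength_correlation(t, "x", "y", min_n=6)

        def rho_of(perm):
            rx = stats.rankdata(x)
            ry = stats.rankdata(y[list(perm)])
            return np.corrcoef(rx, ry)[0, 1]

        obs = abs(rho_of(range(6)))
        perms = list(itertools.permutations(range(6)))
        exact = np.mean([abs(rho_of(p)) >= obs - 1e-12 for p in perms])
        assert res["p"] == pytest.approx(exact, rel=0.10)
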
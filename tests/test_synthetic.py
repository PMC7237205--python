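import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meiohot import synthetic as syn
from meiohot.coexpression import spearman_coexpression
from meiohot.hotspots import SpikeSpec
from meiohot.itc import BindingParams, TitrationSchedule, forward_one_set_of_sites

RC = str.maketrans("ACGT", "TGCA")


class TestGenerateGenome:
    def test_declared_length_and_seed_determinism(self):
        g1 = syn.generate_genome(1, {"chr1": 100_000})
        g2 = syn.generate_genome(1, {"chr1": 100_000})
        assert len(g1.chroms["chr1"]) == 100_000
        assert g1.chroms == g2.chroms

    def test_different_seeds_differ(self):
        a = syn.generate_genome(1, {"chr1": 10_000}).chroms["chr1"]
        b = syn.generate_genome(2, {"chr1": 10_000}).chroms["chr1"]
        assert sum(x != y for x, y in zip(a, b)) > 0

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_genome(1, {"chr1": 0})


class TestPlantHotspots:
    def test_multi_motif_count_exact(self):
        g = syn.generate_genome(3, {"chr1": 1_000_000})
        _, truth = syn.plant_hotspots(g, n=50, multi_motif_fraction=0.1, seed=4)
        assert (truth.table["n_motifs"] == 2).sum() == 5

    def test_motif_written_at_center_on_declared_strand(self):
        g = syn.generate_genome(3, {"chr1": 500_000})
        planted, truth = syn.plant_hotspots(g, n=20, seed=5)
        for r in truth.table.itertuples():
            motif = truth.motifs[r.allele]
            expected = motif if r.strand == "+" else motif.translate(RC)[::-1]
            start = r.center - len(motif) // 2
            assert planted.chroms[r.chrom][start: start + len(motif)] == expected

    def test_single_hotspot_changes_only_motif_window(self):
        g = syn.generate_genome(3, {"chr1": 100_000})
        planted, truth = syn.plant_hotspots(g, n=1, seed=6)
        center = int(truth.table["center"].iloc[0])
        L = len(truth.motifs[truth.table["allele"].iloc[0]])
        diff = [i for i, (a, b) in enumerate(zip(g.chroms["chr1"],
                                                 planted.chroms["chr1"])) if a != b]
        lo, hi = center - L // 2, center - L // 2 + L
        assert all(lo <= i < hi for i in diff)

    def test_allele_mix_within_binomial_bound(self):
        g = syn.generate_genome(3, {"chr1": 2_000_000})
        _, truth = syn.plant_hotspots(
            g, n=100, allele_mix={"Dom2": 0.5, "Cast": 0.5},
            min_spacing=8000, seed=7,
        )
        n_dom = (truth.table["allele"] == "Dom2").sum()
        # binomial(100, 0.5) 99% interval
        lo, hi = stats.binom.interval(0.99, 100, 0.5)
        assert lo <= n_dom <= hi

    def test_spacing_respected_and_overplacement_errors(self):
        g = syn.generate_genome(3, {"chr1": 100_000})
        planted, truth = syn.plant_hotspots(g, n=5, min_spacing=10_000, seed=8)
        pos = np.sort(truth.table["center"].to_numpy())
        assert (np.diff(pos) >= 10_000).all()
        with pytest.raises(ValueError):
            syn.plant_hotspots(g, n=500, min_spacing=10_000, seed=8)


class TestSimulateCutrun:
    def test_pure_background_is_uniform(self, small_genome):
        genome, truth = small_genome
        frags = syn.simulate_cutrun(genome, truth, 20_000, signal_fraction=0.0, seed=9)
        mids = frags.midpoints
        ks = stats.kstest(mids / 200_000, "uniform")
        assert ks.pvalue > 0.01

    def test_pure_signal_avoids_ndr(self, small_genome):
        genome, truth = small_genome
        frags = syn.simulate_cutrun(
            genome, truth, 20_000, signal_fraction=1.0, ndr_halfwidth=75, seed=10
        )
        centers = truth.table["center"].to_numpy()
        mids = frags.midpoints
        dist_to_center = np.min(np.abs(mids[:, None] - centers[None, :]), axis=1)
        assert (dist_to_center > 75).all()

    def test_retained_fraction_matches_truncated_normal_mass(self, small_genome):
        genome, truth = small_genome
        frags = syn.simulate_cutrun(genome, truth, 100_000, seed=11)
        retained = ((frags.lengths >= 130) & (frags.lengths <= 200)).mean()
        a, b = (100 - 165) / 15, (250 - 165) / 15
        expected = (stats.truncnorm.cdf((200.5 - 165) / 15, a, b)
                    - stats.truncnorm.cdf((129.5 - 165) / 15, a, b))
        assert retained == pytest.approx(expected, abs=0.02)

    def test_hotspot_too_close_to_edge_errors(self):
        g = syn.generate_genome(1, {"chr1": 20_000})
        planted, truth = syn.plant_hotspots(
            g, n=1, min_spacing=1000, edge_margin=300, seed=1
        )
        # force the hotspot near the edge
        truth.table.loc[0, "center"] = 100
        with pytest.raises(ValueError):
            syn.simulate_cutrun(planted, truth, 100, seed=1)


class TestSimulateEndseq:
    def test_central_only_stays_within_halfwidth(self, small_genome):
        genome, truth = small_genome
        reads = syn.simulate_endseq(
            genome, truth, 5000, central_fraction=1.0, central_halfwidth=50, seed=12
        )
        centers = truth.table["center"].to_numpy()
        d = np.min(np.abs(reads["pos"].to_numpy()[:, None] - centers[None, :]), axis=1)
        assert (d <= 50).all()

    def test_flank_scale_doubles_flank_central_ratio(self, small_genome):
        genome, truth = small_genome

        def ratio(scale, seed):
            reads = syn.simulate_endseq(
                genome, truth, 200_000, genotype_flank_scale=scale, seed=seed
            )
            counts = reads["origin"].value_counts()
            return counts["flank"] / counts["central"]

        r1, r2 = ratio(1.0, 13), ratio(2.0, 14)
        assert r2 / r1 == pytest.approx(2.0, rel=0.05)

    def test_spike_count_within_poisson_bound(self, small_genome):
        genome, truth = small_genome
        spike = SpikeSpec("chrSpike", 50_000, 0.05)
        reads = syn.simulate_endseq(genome, truth, 1_000_000, spike=spike, seed=15)
        n_spike = (reads["origin"] == "spike").sum()
        expected = 0.05 * 1_000_000
        assert abs(n_spike - expected) <= 3 * np.sqrt(expected)

    def test_resection_mean_beyond_max_flank_rejected(self, small_genome):
        genome, truth = small_genome
        with pytest.raises(ValueError):
            syn.simulate_endseq(genome, truth, 100, resection_mean=5000,
                                max_flank=3000, seed=1)


class TestSimulateScCounts:
    def test_null_genes_near_zero_rho(self):
        mat = syn.simulate_sc_counts(30, 500, planted_rho={}, seed=16)
        out = spearman_coexpression(mat.astype(float), "Prdm9")
        null = out[out["gene"] != "Prdm9"]
        assert (null["rho"].abs() < 0.1).mean() >= 0.95

    def test_duplicated_target_has_unit_rho(self):
        mat = syn.simulate_sc_counts(10, 200, seed=17).astype(float)
        mat.loc["dup"] = mat.loc["Prdm9"]
        out = spearman_coexpression(mat, "Prdm9")
        assert out.loc[out["gene"] == "dup", "rho"].iloc[0] == pytest.approx(1.0)

    def test_planted_rho_recovered(self):
        mat = syn.simulate_sc_counts(
            50, 1000, planted_rho={"Zcwpw1": 0.5}, seed=18
        ).astype(float)
        out = spearman_coexpression(mat, "Prdm9")
        got = out.loc[out["gene"] == "Zcwpw1", "rho"].iloc[0]
        assert 0.4 <= got <= 0.6

    def test_extreme_rho_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_sc_counts(10, 100, planted_rho={"x": 0.99}, seed=1)


class TestSimulateProteinFamilies:
    def test_domain_blocks_invariant_at_full_conservation(self):
        msa, _, _ = syn.simulate_protein_families(5, 5, seed=19)
        block = range(90, 140)  # default zf-CW block, conservation 1.0
        family_ids = [i for i in msa.ids if i != "outgroup"]
        for j in block:
            residues = {msa.sequences[i][j] for i in family_ids}
            assert len(residues) == 1

    def test_catalytic_states_respected(self):
        states = {"family1_sp2": [True, True, False]}
        msa, _, truth = syn.simulate_protein_families(
            3, 3, catalytic_states=states, seed=20
        )
        row = truth[truth["id"] == "family1_sp2"]
        assert row["n_catalytic"].iloc[0] == 2
        seq = msa.sequences["family1_sp2"]
        assert seq[59] == "Y" and seq[69] == "Y" and seq[79] == "F"

    def test_within_clade_identity_exceeds_between(self):
        msa, _, _ = syn.simulate_protein_families(4, 4, seed=21)
        from meiohot.evolution import percent_identity

        within = percent_identity(msa, "family1_sp1", "family1_sp2")
        between = percent_identity(msa, "family1_sp1", "family2_sp1")
        assert within > between

    def test_some_interdomain_distances_exceed_screen_threshold(self):
        _, hits, _ = syn.simulate_protein_families(12, 12, seed=22)
        from meiohot.evolution import pair_domain_hits

        all_pairs = pair_domain_hits(hits, max_distance=10**9)
        assert (all_pairs["distance"] > 50_000).any()
        assert (all_pairs["distance"] <= 50_000).any()

    def test_bad_conservation_level_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_protein_families(
                2, 2, conservation_levels={"background": 1.5}, seed=1
            )


class TestSimulateItc:
    def test_zero_noise_equals_forward_model(self):
        params = BindingParams(kd=2.0, dh=-10.0)
        schedule = TitrationSchedule.uniform()
        sim = syn.simulate_itc(params, schedule, noise_sd=0.0, seed=1)
        fwd = forward_one_set_of_sites(params, schedule)
        np.testing.assert_array_equal(sim.heats, fwd.heats)

    def test_zero_enthalpy_all_zero(self):
        sim = syn.simulate_itc(BindingParams(kd=2.0, dh=0.0),
                               TitrationSchedule.uniform(), 0.0, 1)
        np.testing.assert_allclose(sim.heats, 0.0)

    def test_saturating_schedule_late_heats_near_baseline(self):
        params = BindingParams(kd=0.5, dh=-12.0, baseline=0.3)
        schedule = TitrationSchedule.uniform(n=30)
        sim = syn.simulate_itc(params, schedule, 0.0, 1)
        assert abs(sim.heats[-1] - 0.3) < 0.05 * abs(sim.heats[0] - 0.3)


class TestDeterminism:
    def test_generators_reproducible_by_seed(self, small_genome):
        genome, truth = small_genome
        a = syn.simulate_cutrun(genome, truth, 1000, seed=42)
        b = syn.simulate_cutrun(genome, truth, 1000, seed=42)
        np.testing.assert_array_equal(a.starts, b.starts)
        r1 = syn.simulate_endseq(genome, truth, 1000, seed=42)
        r2 = syn.simulate_endseq(genome, truth, 1000, seed=42)
        pd.testing.assert_frame_equal(r1, r2)
        m1 = syn.simulate_sc_counts(5, 50, seed=42)
        m2 = syn.simulate_sc_counts(5, 50, seed=42)
        pd.testing.assert_frame_equal(m1, m2)
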
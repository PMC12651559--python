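import numpy as np
import pytest

from replireset.coverage import normalize_track, origin_terminus_ratio, smooth_and_trim
from replireset.fluctuation import luria_delbruck_pmf
from replireset.screen import estimate_size_factors
from replireset.synth import (
    FATE_FROZEN,
    FATE_NONE,
    FATE_RESET,
    EndednessTruth,
    FluctuationTruth,
    ReplicationTruth,
    ScreenTruth,
    read_truth,
    render_dapi_intensities,
    render_runout_coverage,
    simulate_endseq_track,
    simulate_luria_delbruck,
    simulate_replication_cells,
    simulate_screen_counts,
    write_truth,
)


class TestScreenGenerator:
    def test_deterministic_under_seed(self):
        truth = ScreenTruth.random(n_genes=20, guides_per_gene=3, seed=0,
                                   library_size=200_000)
        a = simulate_screen_counts(truth, 2, seed=5)
        b = simulate_screen_counts(truth, 2, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_no_growth_no_effect_gives_null_lfc(self):
        truth = ScreenTruth.random(n_genes=50, guides_per_gene=4, seed=1,
                                   doublings=0.0, dispersion=0.0,
                                   library_size=2_000_000)
        cm = simulate_screen_counts(truth, 1, seed=2)
        sf = estimate_size_factors(cm.counts)
        norm = cm.counts / sf[None, :]
        pre = norm[:, cm.columns("control", "pre")].mean(axis=1)
        post = norm[:, cm.columns("control", "post")].mean(axis=1)
        lfc = np.log2((post + 0.5) / (pre + 0.5))
        assert abs(np.median(lfc)) < 0.1

    def test_lethal_gene_depleted_thousandfold(self):
        """s=-1, e=1 guides deplete ~2^-10 over 10 doublings."""
        truth = ScreenTruth.random(n_genes=50, guides_per_gene=4, seed=3,
                                   doublings=10.0, dispersion=0.0,
                                   library_size=20_000_000)
        truth.guide_efficacy[:] = 1.0
        s = np.zeros(50)
        s[0] = -1.0
        truth.fitness_effect["control"] = s
        cm = simulate_screen_counts(truth, 1, seed=4)
        pre = cm.counts[:, cm.columns("control", "pre")[0]].astype(float)
        post = cm.counts[:, cm.columns("control", "post")[0]].astype(float)
        sick = slice(0, 4)
        neutral = slice(4, None)
        # relative abundance ratio sick vs neutral, post over pre
        rel = (post[sick].sum() / post[neutral].sum()) / (
            pre[sick].sum() / pre[neutral].sum()
        )
        assert rel == pytest.approx(2.0**-10, rel=0.5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScreenTruth.random(n_genes=5, guides_per_gene=2, seed=0, dispersion=-0.1)
        truth = ScreenTruth.random(n_genes=5, guides_per_gene=2, seed=0)
        with pytest.raises(ValueError):
            truth.fitness_effect["control"] = np.full(5, -2.0)
            ScreenTruth(
                n_genes=5, guides_per_gene=2,
                baseline_abundance=truth.baseline_abundance,
                guide_efficacy=truth.guide_efficacy,
                fitness_effect=truth.fitness_effect,
            )


class TestLuriaDelbruckGenerator:
    def test_zero_m_all_zero(self):
        counts, titers = simulate_luria_delbruck(
            FluctuationTruth(m=0.0, n_cultures=100), seed=0
        )
        assert np.all(counts == 0)
        assert np.all(titers == 1e9)

    def test_p_zero_matches_poisson(self):
        counts, _ = simulate_luria_delbruck(
            FluctuationTruth(m=1.0, n_cultures=100_000), seed=1
        )
        assert np.mean(counts == 0) == pytest.approx(np.exp(-1), abs=0.005)

    def test_empirical_pmf_matches_recursion(self):
        m, n = 1.0, 150_000
        counts, _ = simulate_luria_delbruck(
            FluctuationTruth(m=m, n_cultures=n), seed=2
        )
        K = 100
        emp = np.bincount(np.minimum(counts, K + 1), minlength=K + 2) / n
        dist = luria_delbruck_pmf(m, K)
        theory = np.r_[dist.p, dist.tail_mass()]
        tv = 0.5 * np.abs(emp - theory).sum()
        assert tv < 0.02

    def test_plating_thins_counts(self):
        full, _ = simulate_luria_delbruck(
            FluctuationTruth(m=2.0, n_cultures=2_000), seed=3
        )
        thin, _ = simulate_luria_delbruck(
            FluctuationTruth(m=2.0, n_cultures=2_000, plating_fraction=0.1), seed=3
        )
        assert thin.sum() < full.sum()

    def test_deterministic_under_seed(self):
        a, _ = simulate_luria_delbruck(FluctuationTruth(m=1.0, n_cultures=500), seed=9)
        b, _ = simulate_luria_delbruck(FluctuationTruth(m=1.0, n_cultures=500), seed=9)
        np.testing.assert_array_equal(a, b)


class TestReplicationSimulator:
    def test_single_round_runout_gives_two_chromosomes(self, ecoli):
        truth = ReplicationTruth(genome=ecoli, generations_overlap=0)
        pop = simulate_replication_cells(truth, 500, seed=1)
        np.testing.assert_allclose(pop.chromosome_equivalents(), 2.0)

    def test_reset_reverts_chromosome_count(self, ecoli):
        """Rear-ended cells degrade the stalled round and finish with the
        pre-initiation chromosome count (4 -> 2)."""
        truth = ReplicationTruth(
            genome=ecoli, generations_overlap=1,
            stall_locus=ecoli.loci["invD"], p_stall=1.0,
            p_rearend_given_stall=1.0,
        )
        pop = simulate_replication_cells(truth, 600, seed=2)
        eq = pop.chromosome_equivalents()
        reset = pop.fate == FATE_RESET
        assert reset.any() and (~reset).any()
        np.testing.assert_allclose(eq[reset], 2.0)
        np.testing.assert_allclose(eq[~reset], 4.0)

    def test_gam_mode_preserves_noninteger_intermediates(self, ecoli):
        truth = ReplicationTruth(
            genome=ecoli, generations_overlap=1,
            stall_locus=ecoli.loci["invD"], p_stall=1.0,
            p_rearend_given_stall=1.0, gam_mode=True,
        )
        pop = simulate_replication_cells(truth, 600, seed=3)
        eq = pop.chromosome_equivalents()
        frozen = pop.fate == FATE_FROZEN
        assert frozen.any()
        assert np.all(np.abs(eq[frozen] - np.round(eq[frozen])) > 0.01)

    def test_parental_chromosome_never_degraded(self, ecoli):
        truth = ReplicationTruth(
            genome=ecoli, generations_overlap=1,
            stall_locus=ecoli.loci["invD"], p_stall=1.0,
            p_rearend_given_stall=1.0, end_resection_bp=50_000,
        )
        pop = simulate_replication_cells(truth, 300, seed=4)
        profile = pop.copy_number_profile(bin_width=5_000)
        assert np.all(profile >= 1.0)

    def test_stall_locus_outside_genome_rejected(self, ecoli):
        with pytest.raises(ValueError):
            ReplicationTruth(genome=ecoli, stall_locus=ecoli.length + 5)

    def test_deterministic_under_seed(self, ecoli):
        truth = ReplicationTruth(genome=ecoli, generations_overlap=1,
                                 stall_locus=ecoli.loci["invD"], p_stall=0.5,
                                 p_rearend_given_stall=0.5)
        a = simulate_replication_cells(truth, 200, seed=7)
        b = simulate_replication_cells(truth, 200, seed=7)
        np.testing.assert_array_equal(a.fate, b.fate)
        np.testing.assert_array_equal(
            np.nan_to_num(a.left), np.nan_to_num(b.left)
        )


class TestRunoutRendering:
    def test_completed_population_flat_profile(self, ecoli):
        truth = ReplicationTruth(genome=ecoli, generations_overlap=0)
        pop = simulate_replication_cells(truth, 400, seed=1)
        track = render_runout_coverage(pop, bin_width=10_000, depth=300, seed=2)
        expected = 2.0 * 300
        assert track.values.mean() == pytest.approx(expected, rel=0.02)
        assert track.values.std() < 4 * np.sqrt(expected)

    def test_poisson_noise_scale(self, ecoli):
        truth = ReplicationTruth(genome=ecoli, generations_overlap=0)
        pop = simulate_replication_cells(truth, 400, seed=1)
        track = render_runout_coverage(pop, bin_width=10_000, depth=200, seed=3)
        # per-bin relative SD consistent with Poisson at the rendered depth
        mean = track.values.mean()
        assert track.values.std() == pytest.approx(np.sqrt(mean), rel=0.15)

    def test_exponential_phase_origin_bias(self, ecoli):
        truth = ReplicationTruth(genome=ecoli, generations_overlap=0)
        pop = simulate_replication_cells(truth, 12_000, seed=5, stage="exponential")
        track = render_runout_coverage(pop, bin_width=5_000, depth=400, seed=6)
        ratio = origin_terminus_ratio(
            smooth_and_trim(normalize_track(track, "cpm+terminus")), window=100_000
        )
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_empty_population_rejected(self, ecoli):
        truth = ReplicationTruth(genome=ecoli)
        pop = simulate_replication_cells(truth, 1, seed=1)
        with pytest.raises(ValueError):
            render_runout_coverage(pop, depth=0.0)


class TestDapiRendering:
    def test_narrow_cv_point_mass(self):
        vals = render_dapi_intensities(np.ones(200), au_per_chromosome=100.0,
                                       cv=1e-4, seed=1)
        np.testing.assert_allclose(vals, 100.0, rtol=1e-3)

    def test_mixture_is_bimodal(self):
        eq = np.r_[np.full(3_000, 2.0), np.full(3_000, 4.0)]
        vals = render_dapi_intensities(eq, 100.0, cv=0.1, seed=2)
        from replireset.cyto import detect_peaks

        peaks = detect_peaks(vals, bandwidth=15.0)
        assert len(peaks) == 2
        np.testing.assert_allclose(peaks.positions, [200, 400], rtol=0.05)

    def test_truncated_at_zero(self):
        vals = render_dapi_intensities(np.full(5_000, 0.05), 100.0, cv=0.9, seed=3)
        assert np.all(vals >= 0.0)


class TestEndseqGenerator:
    def test_fully_one_ended_is_single_stranded(self, ecoli):
        truth = EndednessTruth(end_sites=[2_000_000, 3_000_000, 4_200_000],
                               one_ended_fraction=1.0, depth=100, noise=0.0)
        track = simulate_endseq_track(truth, ecoli, seed=1)
        signal = (track.fwd > 0) | (track.rev > 0)
        assert np.all((track.fwd[signal] == 0) | (track.rev[signal] == 0))

    def test_two_ended_sites_balanced(self, ecoli):
        truth = EndednessTruth(end_sites=[2_000_000] , one_ended_fraction=0.0,
                               depth=50_000, noise=0.0)
        track = simulate_endseq_track(truth, ecoli, seed=2)
        b = 2_000_000 // 1_000
        assert track.fwd[b] / track.rev[b] == pytest.approx(1.0, rel=0.05)

    def test_one_ended_faces_away_from_origin(self, ecoli):
        truth = EndednessTruth(end_sites=[3_000_000], one_ended_fraction=1.0,
                               depth=100, noise=0.0)
        track = simulate_endseq_track(truth, ecoli, seed=3)
        b = 3_000_000 // 1_000
        # 3.0 Mb is on the left replichore: away-facing is the reverse strand
        assert ecoli.replichore(3_000_000) == "left"
        assert track.rev[b] > 0 and track.fwd[b] == 0

    def test_site_outside_genome_rejected(self, ecoli):
        with pytest.raises(ValueError):
            simulate_endseq_track(
                EndednessTruth(end_sites=[ecoli.length + 1]), ecoli, seed=1
            )


class TestTruthSidecars:
    def test_round_trips(self, tmp_path, ecoli):
        truths = [
            ScreenTruth.random(n_genes=4, guides_per_gene=2, seed=0),
            FluctuationTruth(m=1.5, n_cultures=10),
            ReplicationTruth(genome=ecoli, generations_overlap=2,
                             stall_locus=ecoli.loci["invD"], p_stall=0.5,
                             p_rearend_given_stall=0.25, sister_escape=True),
            EndednessTruth(end_sites=[1, 2, 3], one_ended_fraction=0.7),
        ]
        for i, truth in enumerate(truths):
            path = tmp_path / f"truth{i}.yaml"
            write_truth(truth, path)
            back = read_truth(path)
            assert type(back) is type(truth)
        back = read_truth(tmp_path / "truth2.yaml")
        assert back.stall_locus == ecoli.loci["invD"]
        assert back.sister_escape is True
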
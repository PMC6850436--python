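"""The synthetic-data generator: genotypes, reads, likelihoods,
ascertainment and window subsetting."""

import numpy as np
import pytest

from pairkin import (PairSimConfig, ReadSimConfig, RELATIONSHIPS,
                     SpectrumModel, ascertain_sites, call_genotypes,
                     demography_spectrum, expected_stats, king_kinship,
                     jackknife_pair_stats, lee_statistic, pair_gl_data,
                     pair_stats, r0, simulate_cross_population_pair,
                     simulate_pair_genotypes, simulate_reads_and_gls,
                     subset_windows)
from pairkin.simulate import _gl_log_emission_matrix
from pairkin.gl import GENOTYPE10_NAMES


def make_pair(relationship="UR", n=50_000, seed=1, **kw):
    return simulate_pair_genotypes(PairSimConfig(
        relationship=relationship, n_sites=n,
        spectrum=kw.pop("spectrum", demography_spectrum("constant")),
        seed=seed, **kw))


class TestGenotypeSimulation:
    def test_po_realized_ibd_is_all_state_one(self):
        pair = make_pair("PO", n=20_000)
        assert pair.realized_k == (0.0, 1.0, 0.0)
        # a PO pair can never carry opposing homozygotes
        assert pair_stats(pair.counts()).r0 == 0.0

    def test_realized_k_converges_binomially(self):
        pair = make_pair("FS", n=200_000)
        assert np.allclose(pair.realized_k, (0.25, 0.5, 0.25), atol=0.005)

    def test_seed_determinism(self):
        a, b = make_pair(seed=9), make_pair(seed=9)
        assert (a.g1 == b.g1).all() and (a.g2 == b.g2).all()
        assert (a.positions == b.positions).all()

    def test_ur_null_statistic(self):
        stats = jackknife_pair_stats(make_pair("UR", n=200_000).block_counts())
        assert abs(stats.r0 - 0.5) < 3 * stats.se["r0"] + 1e-9
        assert abs(stats.king_kinship) < 3 * stats.se["king_kinship"] + 1e-9

    def test_fs_point_mass_kinship_matches_expected_cells(self):
        pair = make_pair("FS", n=200_000,
                         spectrum=SpectrumModel.point_mass(0.5))
        stats = jackknife_pair_stats(pair.block_counts())
        assert abs(stats.king_kinship - 0.25) < 3 * stats.se["king_kinship"]

    @pytest.mark.parametrize("label", ["FS", "HS", "C1"])
    @pytest.mark.parametrize("demography", ["constant", "expansion",
                                            "decline"])
    def test_simulated_statistics_match_theory(self, label, demography):
        """For every relationship x demography, simulated genotype
        statistics agree with the analytic expectation under that
        spectrum within Monte-Carlo error."""
        spectrum = demography_spectrum(demography)
        pair = make_pair(label, n=150_000, seed=3, spectrum=spectrum)
        stats = jackknife_pair_stats(pair.block_counts())
        er1, er0, ekin = expected_stats(RELATIONSHIPS[label], spectrum)
        assert abs(stats.r1 - er1) < 3 * stats.se["r1"]
        assert abs(stats.r0 - er0) < 3 * stats.se["r0"]
        assert abs(stats.king_kinship - ekin) < 3 * stats.se["king_kinship"]

    def test_site_layout(self):
        pair = make_pair(n=10_000, n_chromosome_labels=5)
        assert len(set(pair.contigs)) == 5
        for lab in set(pair.contigs):
            pos = pair.positions[pair.contigs == lab]
            assert (np.diff(pos) > 0).all()

    def test_invalid_config(self):
        sp = demography_spectrum("constant")
        with pytest.raises(ValueError):
            PairSimConfig("UR", 0, sp, 1)
        with pytest.raises(ValueError):
            PairSimConfig("XX", 100, sp, 1).k


class TestCrossPopulation:
    def test_fst_zero_collapses_to_same_population(self):
        pair = simulate_cross_population_pair(
            0.0, demography_spectrum("constant"), 400_000, 0)
        stats = jackknife_pair_stats(pair.block_counts())
        assert abs(stats.r0 - 0.5) < 3 * stats.se["r0"]
        assert abs(stats.lee - 2 / 3) < 3 * stats.se["lee"]

    def test_divergent_populations_shift_r0_and_lee(self):
        pair = simulate_cross_population_pair(
            0.2, demography_spectrum("constant"), 150_000, 5)
        counts = pair.counts()
        assert r0(counts) > 0.5
        assert lee_statistic(counts) < 2 / 3
        assert king_kinship(counts) < 0

    def test_invalid_fst(self):
        with pytest.raises(ValueError):
            simulate_cross_population_pair(
                1.5, demography_spectrum("constant"), 10, 1)


class TestReadsAndLikelihoods:
    def test_emission_model_single_read(self):
        """One 'A' read: GL(AA) = 0.99 and GL(AC) = (0.99 + 0.01/3)/2."""
        M = np.exp(_gl_log_emission_matrix(0.01))
        gAA = GENOTYPE10_NAMES.index("AA")
        gAC = GENOTYPE10_NAMES.index("AC")
        assert M[0, gAA] == pytest.approx(0.99)
        assert M[0, gAC] == pytest.approx(0.5 * 0.99 + 0.5 * 0.01 / 3)

    def test_zero_depth_site_has_flat_likelihoods(self):
        pair = make_pair(n=2000)
        res = simulate_reads_and_gls(pair.g1, pair.alleles,
                                     ReadSimConfig(0.3, 0.01, seed=2))
        empty = res.depth == 0
        assert empty.any()
        assert np.allclose(res.gl10[empty], 1.0)

    def test_high_depth_argmax_recovers_genotypes(self):
        pair = make_pair(n=5000)
        res = simulate_reads_and_gls(pair.g1, pair.alleles,
                                     ReadSimConfig(100.0, 0.01, seed=2))
        called = call_genotypes(res.gl3, res.depth)
        ok = res.depth > 0
        assert (called[ok] == pair.g1[ok]).mean() > 0.999

    def test_read_counts_match_depth(self):
        pair = make_pair(n=2000)
        res = simulate_reads_and_gls(pair.g1, pair.alleles,
                                     ReadSimConfig(4.0, 0.01, seed=2))
        assert (res.base_counts.sum(axis=1) == res.depth).all()

    def test_gl_modes_share_metadata(self):
        pair = make_pair(n=1000)
        gls = pair_gl_data(pair, ReadSimConfig(4.0, 0.01, seed=3))
        assert gls["sfs"].n_sites == gls["ibs"].n_sites == 1000
        assert (gls["sfs"].contigs == pair.contigs).all()

    def test_invalid_read_config(self):
        with pytest.raises(ValueError):
            ReadSimConfig(0.0, 0.01)
        with pytest.raises(ValueError):
            ReadSimConfig(4.0, 0.0)


class TestAscertainment:
    def test_minor_count_rule_boundary(self):
        # minor count 2 of 40 excluded, 3 of 40 included (rule is "> 2")
        panel = np.zeros((2, 40), dtype=int)
        panel[0, :2] = 1
        panel[1, :3] = 1
        assert list(ascertain_sites(panel, 2)) == [False, True]

    def test_disabled_rule_keeps_everything(self):
        assert ascertain_sites(np.array([0, 1, 5]), None).all()

    def test_recorded_panel_matches_mask(self):
        pair = make_pair(n=20_000, record_panel=True)
        mask = ascertain_sites(pair, 2)
        assert mask.sum() == (pair.panel_minor_count > 2).sum()

    def test_ascertained_simulation_respects_rule(self):
        pair = make_pair(n=5000, min_minor_ac=2, record_panel=True)
        assert (pair.panel_minor_count > 2).all()

    def test_impossible_rule_errors(self):
        # a panel of 40 cannot have minor count above 20
        with pytest.raises(RuntimeError, match="ascertainment"):
            make_pair(n=100, min_minor_ac=25)

    def test_ascertainment_shifts_ibs_but_not_ratio_statistics(self):
        pair = make_pair("UR", n=300_000, record_panel=True, seed=8)
        full = pair_stats(pair.counts())
        sub = pair_stats(pair.subset(ascertain_sites(pair, 2)).counts())
        assert abs(sub.r0 - full.r0) < 0.02
        assert abs(sub.king_kinship - full.king_kinship) < 0.01
        assert sub.ibs0 / full.ibs0 > 1.25


class TestWindowSubsetting:
    def test_candidate_basepairs_and_containment(self):
        pair = make_pair(n=100_000)
        mask = subset_windows(pair.contigs, pair.positions,
                              pair.contig_lengths, n_windows=10_000,
                              window_bp=200, seed=4)
        # 10k windows x 200 bp = 2M candidate bp of a 50M genome: ~4% kept
        assert 0.02 < mask.mean() < 0.06
        assert mask.sum() > 0

    def test_identity_subset(self):
        pair = make_pair(n=2000)
        total_slots = sum(L // 200 for L in pair.contig_lengths.values())
        mask = subset_windows(pair.contigs, pair.positions,
                              pair.contig_lengths, total_slots, 200, seed=4)
        assert mask.all()

    def test_too_many_windows_errors(self):
        pair = make_pair(n=1000)
        with pytest.raises(ValueError, match="exceed"):
            subset_windows(pair.contigs, pair.positions, pair.contig_lengths,
                           10 ** 9, 200, seed=4)

    def test_two_seeds_agree_within_uncertainty(self):
        pair = make_pair("HS", n=200_000, seed=6)
        vals = []
        for seed in (1, 2):
            mask = subset_windows(pair.contigs, pair.positions,
                                  pair.contig_lengths, 50_000, 200, seed)
            sub = pair.subset(mask)
            vals.append(jackknife_pair_stats(sub.block_counts()))
        assert abs(vals[0].r0 - vals[1].r0) < 2 * (vals[0].se["r0"]
                                                   + vals[1].se["r0"])
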
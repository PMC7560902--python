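"""Synthetic library, selection, and genome fixture generators."""

import numpy as np
import pytest

import oriselect as o
from oriselect.simulate import (
    SYNTHETIC_ARS_WT,
    default_truth_motif,
    make_genome_fixture,
    make_variant_library,
    simulate_selection,
)
from scipy.stats import spearmanr


class TestVariantLibrary:
    def test_rate_zero_gives_wild_type_only(self):
        sc = o.SelectionScenario(rate=0.0, n_variants=50, depth=1000)
        variants, counts = make_variant_library(sc, seed=0)
        assert variants == [SYNTHETIC_ARS_WT]
        assert counts.sum() == 1000

    def test_rate_one_never_keeps_wild_type_base(self):
        sc = o.SelectionScenario(rate=1.0, n_variants=20, depth=100)
        variants, _ = make_variant_library(sc, seed=1)
        for v in variants:
            assert all(a != b for a, b in zip(v, SYNTHETIC_ARS_WT))

    def test_mean_substitution_rate_matches_design(self):
        sc = o.SelectionScenario(n_variants=10_000, depth=10_000)
        variants, _ = make_variant_library(sc, seed=2)
        mism = np.mean([
            sum(a != b for a, b in zip(v, SYNTHETIC_ARS_WT)) / len(v)
            for v in variants
        ])
        assert mism == pytest.approx(0.15, abs=0.01)

    def test_silent_convention_lowers_observed_mismatches(self):
        sc = o.SelectionScenario(n_variants=5000, depth=5000,
                                 include_silent=True)
        variants, _ = make_variant_library(sc, seed=3)
        mism = np.mean([
            sum(a != b for a, b in zip(v, SYNTHETIC_ARS_WT)) / len(v)
            for v in variants
        ])
        assert mism == pytest.approx(0.15 * 0.75, abs=0.01)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            o.SelectionScenario(rate=1.5)


class TestSelection:
    def test_null_truth_gives_no_enrichment(self):
        sc = o.SelectionScenario(
            truth=o.Motif(theta=np.zeros((4, 50))),
            n_variants=500, depth=100_000,
        )
        tab = o.simulate_mpos(sc, seed=4).window(1, 50)
        theta = o.er_motif(tab).theta
        assert np.abs(theta).max() < 0.15  # sampling noise only

    def test_strong_motif_rank_correlates_with_enrichment(self):
        sc = o.SelectionScenario(n_variants=1000, depth=100_000)
        tab = o.simulate_mpos(sc, seed=5)
        w = tab.window(1, 50)
        a_true = sc.truth_motif.activities(w.indices())
        ratio = (w.frame["selected_count"] + 1) / (w.frame["library_count"] + 1)
        rho = spearmanr(a_true, ratio).statistic
        assert rho > 0.8

    def test_distorted_selection_shares_bins_but_not_er(self):
        """g(x)=x vs g(x)=x^3 on identical seeds: same variants, hence
        identical IM bin assignments for any fixed motif, but different
        (steeper) ER motifs."""
        lin = o.SelectionScenario()
        cub = o.SelectionScenario(distortion=lambda x: x**3)
        t_lin = o.simulate_mpos(lin, seed=6).window(1, 50)
        t_cub = o.simulate_mpos(cub, seed=6).window(1, 50)
        assert t_lin.frame["sequence"].tolist() == t_cub.frame["sequence"].tolist()
        truth = lin.truth_motif.normalize()
        b_lin = o.bin_activities(t_lin, truth, n_bins=100, sigma=0)
        b_cub = o.bin_activities(t_cub, truth, n_bins=100, sigma=0)
        assert (b_lin.bin_of_variant == b_cub.bin_of_variant).all()
        er_lin = o.er_motif(t_lin).theta
        er_cub = o.er_motif(t_cub).theta
        assert not np.allclose(er_lin, er_cub)
        # monotone sharpening steepens the raw ER parameters
        assert np.linalg.norm(er_cub) > np.linalg.norm(er_lin)

    def test_decreasing_distortion_rejected(self):
        sc = o.SelectionScenario(distortion=lambda x: -x, n_variants=50,
                                 depth=100)
        variants, counts = make_variant_library(sc, seed=7)
        with pytest.raises(ValueError, match="increasing"):
            simulate_selection(sc, variants, counts, seed=7)

    def test_reproducible_under_seed(self):
        sc = o.SelectionScenario(n_variants=100, depth=1000)
        a = o.simulate_mpos(sc, seed=8)
        b = o.simulate_mpos(sc, seed=8)
        assert a.frame.equals(b.frame)


class TestTruthMotif:
    def test_consensus_positions_carry_weight(self):
        truth = default_truth_motif()
        window = SYNTHETIC_ARS_WT[:50]
        # the planted dinucleotide positions reward the WT bases
        for pos in (29, 30):
            base_idx = "ACGT".index(window[pos - 1])
            assert truth.theta[base_idx, pos - 1] == 1.0
        assert truth.theta[:, 0].sum() == 0.0  # outside elements: no weight

    def test_wild_type_is_activity_optimal_within_one_substitution(self):
        truth = default_truth_motif()
        window = SYNTHETIC_ARS_WT[:50]
        wt_act = truth.activity(window)
        rng = np.random.default_rng(9)
        for _ in range(50):
            pos = int(rng.integers(50))
            alt = "ACGT"[int(rng.integers(4))]
            mutant = window[:pos] + alt + window[pos + 1:]
            assert truth.activity(mutant) <= wt_act


class TestGenomeFixture:
    def test_zero_noise_equal_effects_give_equal_heights(self):
        track, acs = make_genome_fixture(noise_sigma=0, seed=10)
        proc = track.smooth(5000).normalize()
        heights = [
            proc.peak_height_at(r.chrom, (r.start + r.end) // 2)
            for r in acs.itertuples()
        ]
        assert max(heights) - min(heights) < 1e-3

    def test_overlapping_origins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_genome_fixture(chrom_length=50_000, origins_per_chrom=20,
                                peak_sd=2000, seed=11)

    def test_emitted_files_reproducible_byte_for_byte(self, tmp_path):
        from oriselect.simulate import write_genome_fixture
        for sub in ("a", "b"):
            track, acs = make_genome_fixture(
                n_chrom=1, chrom_length=100_000, origins_per_chrom=4, seed=12
            )
            write_genome_fixture(tmp_path / sub, track, acs)
        for name in ("coverage.bedgraph", "acs.tsv", "acs.bed", "acs.fasta"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_annotations_round_trip_through_dinucleotide_extraction(self):
        _, acs = make_genome_fixture(seed=13)
        for r in acs.itertuples():
            assert o.extract_dinucleotide(r.sequence, r.strand) == r.dinucleotide
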
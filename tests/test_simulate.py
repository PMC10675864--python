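"""Synthetic-data generators: determinism, ground-truth structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from goosepan import pangenome
from goosepan.expression import cpm, group_means, tau_table
from goosepan.pav_call import build_pav_matrix
from goosepan.popgen import select_sweep_regions, wc_fst
from goosepan.simulate import (
    SimConfig,
    simulate_contig_scenario,
    simulate_depth_tracks,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes_bn,
    simulate_pav_population,
    simulate_phenotype,
    simulate_selection_scores,
)


class TestConfig:
    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(class_spec=(("core", 0.5, 1.0), ("shell", 0.4, 0.5)))

    def test_fst_range_validated(self):
        with pytest.raises(ValueError):
            SimConfig(fst_target=1.0)

    def test_named_streams_are_independent(self):
        cfg = SimConfig(seed=42)
        a = cfg.rng("x").random(5)
        b = cfg.rng("y").random(5)
        assert not np.allclose(a, b)
        assert np.allclose(a, SimConfig(seed=42).rng("x").random(5))


class TestPavPopulation:
    def test_all_core_spec_all_present(self):
        cfg = SimConfig(seed=0, n_samples=50, n_genes=40,
                        class_spec=(("core", 1.0, 1.0),))
        m, truth = simulate_pav_population(cfg)
        assert (m.df.to_numpy() == 1).all()
        assert (truth["true_class"] == "core").all()

    def test_realized_frequency_concentrates(self):
        cfg = SimConfig(seed=1, n_samples=200, n_genes=1000,
                        class_spec=(("shell", 1.0, 0.5),))
        m, _ = simulate_pav_population(cfg)
        assert abs(m.frequencies().mean() - 0.5) < 0.05

    def test_determinism(self):
        cfg = SimConfig(seed=9, n_samples=30, n_genes=20)
        a, _ = simulate_pav_population(cfg)
        b, _ = simulate_pav_population(cfg)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestDepthTracks:
    def test_present_gene_poisson_tail(self):
        # P(depth >= 2) at mean 10 is 1 - e^-10 * 11 ~ 0.9995
        cfg = SimConfig(seed=2, n_samples=1, n_genes=1,
                        class_spec=(("core", 1.0, 1.0),), mean_depth=10)
        genes = simulate_gene_models(1, n_exons=2, exon_len=500)
        m, _ = simulate_pav_population(cfg)
        track = next(simulate_depth_tracks(m, genes, cfg))
        g = genes[0]
        covered = sum(
            (track.depth(g.chrom, s, e) >= 2).mean() * (e - s) for s, e in g.exons
        )
        assert covered / g.exon_length > 0.95

    def test_absent_gene_zero_noise_all_zero(self):
        cfg = SimConfig(seed=3, n_samples=2, n_genes=3,
                        class_spec=(("cloud", 1.0, 0.0),),
                        noise_depth_fraction=0.0)
        genes = simulate_gene_models(3)
        m, _ = simulate_pav_population(cfg)
        for track in simulate_depth_tracks(m, genes, cfg):
            assert all(arr.sum() == 0 for arr in track.depths.values())

    def test_absent_gene_noise_stays_below_cutoff(self):
        cfg = SimConfig(seed=4, n_samples=3, n_genes=5,
                        class_spec=(("cloud", 1.0, 0.0),),
                        noise_depth_fraction=0.05)
        genes = simulate_gene_models(5)
        m, _ = simulate_pav_population(cfg)
        called = build_pav_matrix(genes, simulate_depth_tracks(m, genes, cfg))
        assert (called.df.to_numpy() == 0).all()

    def test_gene_without_model_rejected(self):
        cfg = SimConfig(seed=5, n_samples=2, n_genes=3)
        genes = simulate_gene_models(2)  # one model missing
        m, _ = simulate_pav_population(cfg)
        with pytest.raises(ValueError, match="without exon models"):
            next(simulate_depth_tracks(m, genes, cfg))


class TestGenotypes:
    def test_no_differentiation_limit(self):
        cfg = SimConfig(seed=6, n_samples=200, n_sites=5000, fst_target=0.0)
        gm = simulate_genotypes_bn(cfg)
        _, weighted, _ = wc_fst(gm, "popA", "popB")
        assert abs(weighted) < 0.01

    def test_single_population_rejected(self):
        cfg = SimConfig(seed=7)
        with pytest.raises(ValueError):
            simulate_genotypes_bn(cfg, pop_names=("solo",), pop_sizes=(10,))

    def test_determinism(self):
        cfg = SimConfig(seed=8, n_samples=20, n_sites=50)
        a = simulate_genotypes_bn(cfg)
        b = simulate_genotypes_bn(cfg)
        np.testing.assert_array_equal(a.gt, b.gt)


class TestPhenotype:
    def test_null_effect_p_values_roughly_uniform(self):
        from goosepan.freq_diff import pav_phenotype_assoc

        cfg = SimConfig(seed=10, n_samples=200, n_genes=1000,
                        class_spec=(("shell", 1.0, 0.5),), effect_size=0.0)
        m, _ = simulate_pav_population(cfg)
        y = simulate_phenotype(m, [], cfg)
        res = pav_phenotype_assoc(m, y)
        frac = (res.table["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_missing_causal_gene_rejected(self):
        cfg = SimConfig(seed=11, n_samples=10, n_genes=5)
        m, _ = simulate_pav_population(cfg)
        with pytest.raises(ValueError, match="absent"):
            simulate_phenotype(m, ["not_a_gene"], cfg)

    def test_determinism(self):
        cfg = SimConfig(seed=12, n_samples=20, n_genes=10)
        m, _ = simulate_pav_population(cfg)
        a = simulate_phenotype(m, m.genes[:1], cfg)
        b = simulate_phenotype(m, m.genes[:1], cfg)
        pd.testing.assert_series_equal(a, b)


class TestExpression:
    def test_fold_one_no_enriched_tail(self):
        cfg = SimConfig(seed=13, n_genes=500, n_groups=5, specific_fold=1.0)
        counts, labels, truth = simulate_expression(cfg)
        taus = tau_table(group_means(cpm(counts), labels))
        planted = truth["planted_specific"]
        # planted genes are indistinguishable from background at fold 1
        assert taus.loc[planted.to_numpy(), "tau"].median() < 0.6
        assert (taus["tau"] >= 0.9).mean() < 0.05

    def test_planted_specific_separate_from_background(self):
        cfg = SimConfig(seed=14, n_genes=500, n_groups=5, specific_fold=50.0)
        counts, labels, truth = simulate_expression(cfg)
        taus = tau_table(group_means(cpm(counts), labels))
        planted = truth["planted_specific"].to_numpy()
        assert (taus.loc[planted, "tau"] > 0.9).all()
        assert taus.loc[~planted, "tau"].median() < 0.5
        # assigned group matches the planted group
        got = taus.loc[planted, "group"]
        want = truth.loc[planted, "planted_group"]
        assert (got == want).all()

    def test_determinism(self):
        cfg = SimConfig(seed=15, n_genes=50, n_groups=4)
        a, _, _ = simulate_expression(cfg)
        b, _, _ = simulate_expression(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestContigScenario:
    def test_forced_categories(self):
        sc = simulate_contig_scenario(SimConfig(seed=16))
        truth = sc.truth.set_index("contig_id")["category"]
        assert (truth == "too_short").sum() == 8
        short_ids = truth[truth == "too_short"].index
        assert all(
            c.length < 500 for c in sc.contigs if c.id in set(short_ids)
        )
        # redundant pairs are identical sequences
        seqs = {c.id: c.sequence for c in sc.contigs}
        for i in range(1, 7):
            assert seqs[f"zdup{i:02d}"] == seqs[f"upartner{i:02d}"]

    def test_full_scenario_written_and_readable(self, tmp_path):
        from goosepan import io

        sc = simulate_contig_scenario(SimConfig(seed=17))
        sc.write(tmp_path)
        contigs = io.read_contig_fasta(tmp_path / "contigs.fa")
        assert len(contigs) == 60
        assert io.read_taxonomy(tmp_path / "taxonomy.tsv")["contam01"] == "bacteria"

    def test_determinism(self):
        a = simulate_contig_scenario(SimConfig(seed=18))
        b = simulate_contig_scenario(SimConfig(seed=18))
        assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]


class TestSelectionScores:
    def test_planted_windows_in_top_5_percent(self):
        cfg = SimConfig(seed=19)
        track = simulate_selection_scores(1_000_000, [10, 40, 70], cfg, shift=20.0)
        win, regions = select_sweep_regions(track)
        strong = set(win.loc[win["strong"], "window"])
        assert {10, 40, 70} <= strong

    def test_no_planting_no_overrepresented_window(self):
        # across replicate tracks, top-5% calls should spread over windows
        hits = np.zeros(20, dtype=int)
        for rep in range(50):
            cfg = SimConfig(seed=1000 + rep)
            track = simulate_selection_scores(200_000, [], cfg)
            win, _ = select_sweep_regions(track)
            for w in win.loc[win["strong"], "window"]:
                hits[w - 1] += 1
        assert hits.max() <= 10  # ~Binomial(50, 1/20) under uniformity

    def test_determinism(self):
        cfg = SimConfig(seed=20)
        a = simulate_selection_scores(50_000, [2], cfg)
        b = simulate_selection_scores(50_000, [2], cfg)
        pd.testing.assert_frame_equal(a, b)


class TestTriageComposition:
    def test_pipeline_reproduces_truth_categories(self):
        sc = simulate_contig_scenario(SimConfig(seed=21))
        res = pangenome.triage_contigs(
            sc.contigs, sc.blocks, sc.taxonomy, sc.self_hits
        )
        merged = res.categories.merge(sc.truth, on="contig_id",
                                      suffixes=("_got", "_true"))
        assert (merged["category_got"] == merged["category_true"]).all()
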
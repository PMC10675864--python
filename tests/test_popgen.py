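"""Weir-Cockerham Fst, windowed pi, and sweep-window aggregation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from goosepan.pav_call import GeneModel
from goosepan.popgen import (
    GenotypeMatrix,
    merge_top_windows,
    region_gene_flank_stats,
    select_sweep_regions,
    top_fraction_threshold,
    wc_fst,
    window_mean_scores,
    windowed_pi,
)


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = make_genotypes([[2] * 10 + [0] * 10] * 3, pops="a" * 10 + "b" * 10)
        table, weighted, mean_site = wc_fst(gm, "a", "b")
        assert weighted == pytest.approx(1.0)
        assert mean_site == pytest.approx(1.0)

    def test_identical_compositions_near_zero(self):
        # both populations carry the same genotype multiset at every site;
        # the estimator's small negative finite-sample term shrinks as 1/n
        row = [0, 0, 1, 1, 2] * 40  # 100 diploids per population
        gm = make_genotypes([row, row, row[::-1]], pops="a" * 100 + "b" * 100)
        _, weighted, _ = wc_fst(gm, "a", "b")
        assert abs(weighted) <= 0.01

    def test_per_site_ratio_bounded_by_one(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 3, size=(200, 30))
        gm = make_genotypes(gt, pops="a" * 15 + "b" * 15)
        table, _, _ = wc_fst(gm, "a", "b")
        assert (table["fst"].dropna() <= 1.0 + 1e-12).all()

    def test_requires_two_distinct_populations(self):
        gm = make_genotypes([[0, 1, 2, 1]], pops="aabb")
        with pytest.raises(ValueError):
            wc_fst(gm, "a", "a")

    def test_undersized_sites_skipped(self):
        # one missing call leaves pop b with a single genotyped sample
        gm = make_genotypes([[0, 2, 1, -1]], pops="aabb")
        table, weighted, _ = wc_fst(gm, "a", "b")
        assert np.isnan(table["fst"]).all() and np.isnan(weighted)


class TestWindowedPi:
    def test_single_het_site_in_100bp_window(self):
        # one diploid sample heterozygous at one site: site pi = 1
        gm = make_genotypes([[1]], positions=[10])
        out = windowed_pi(gm, window=100)
        assert out["pi"].iloc[0] == pytest.approx(0.01)

    def test_monomorphic_window_zero(self):
        gm = make_genotypes([[0, 0, 0], [2, 2, 2]], positions=[5, 50])
        out = windowed_pi(gm, window=100)
        assert out["pi"].iloc[0] == pytest.approx(0.0)

    def test_two_two_split_of_four_copies(self):
        # two diploid samples, both het: 4 allele copies split 2/2
        gm = make_genotypes([[1, 1]], positions=[10])
        out = windowed_pi(gm, window=100)
        assert out["pi"].iloc[0] == pytest.approx((4 / 3) * 0.5 / 100)

    def test_invariant_under_sample_relabeling(self):
        gt = np.array([[0, 1, 2, 1], [2, 2, 0, 0]])
        a = windowed_pi(make_genotypes(gt), window=1000)
        b = windowed_pi(make_genotypes(gt[:, ::-1]), window=1000)
        pd.testing.assert_series_equal(a["pi"], b["pi"])

    def test_duplicating_sites_scales_linearly(self):
        gt = [[1, 0, 2, 1]]
        one = windowed_pi(make_genotypes(gt, positions=[10]), window=100)
        two = windowed_pi(
            make_genotypes(gt * 2, positions=[10, 20]), window=100
        )
        assert two["pi"].iloc[0] == pytest.approx(2 * one["pi"].iloc[0])


class TestWindowMeans:
    def test_mean_within_first_window(self):
        scores = pd.DataFrame(
            {"chrom": ["c", "c"], "pos": [1, 9999], "score": [2.0, 4.0]}
        )
        out = window_mean_scores(scores)
        assert len(out) == 1 and out["mean_score"].iloc[0] == pytest.approx(3.0)
        assert out["window"].iloc[0] == 1 and out["end"].iloc[0] == 10000

    def test_tiling_boundary(self):
        scores = pd.DataFrame({"chrom": ["c"], "pos": [10001], "score": [1.0]})
        assert window_mean_scores(scores)["window"].iloc[0] == 2

    def test_empty_track(self):
        out = window_mean_scores(pd.DataFrame(columns=["chrom", "pos", "score"]))
        assert out.empty

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            {"chrom": "c", "pos": np.arange(1, 50_001, 37), "score": rng.random(1352)}
        )
        shuffled = scores.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(
            window_mean_scores(scores).reset_index(drop=True),
            window_mean_scores(shuffled).reset_index(drop=True),
        )


class TestTopFraction:
    def test_distinct_means_exact_count(self):
        thr, flags = top_fraction_threshold(np.arange(1, 101), 0.05)
        assert thr == 96 and flags.sum() == 5

    def test_ties_all_flagged(self):
        thr, flags = top_fraction_threshold([7.0] * 10, 0.05)
        assert flags.all()

    def test_single_window_flagged(self):
        _, flags = top_fraction_threshold([3.0], 0.05)
        assert flags.all()


def windows_df(indices, means, chrom="c"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "window": indices,
            "start": [(w - 1) * 10000 + 1 for w in indices],
            "end": [w * 10000 for w in indices],
            "mean_score": means,
            "n_sites": 1,
        }
    )


class TestMergeRegions:
    def test_adjacent_windows_merge_with_max_score(self):
        win = windows_df([3, 4], [5.0, 9.0])
        regions = merge_top_windows(win, np.array([True, True]))
        assert len(regions) == 1
        r = regions[0]
        assert (r.window_from, r.window_to, r.score) == (3, 4, 9.0)

    def test_gap_of_one_window_bridged(self):
        win = windows_df([3, 5], [5.0, 9.0])
        regions = merge_top_windows(win, np.array([True, True]))
        assert len(regions) == 1
        assert (regions[0].window_from, regions[0].window_to) == (3, 5)
        assert (regions[0].start, regions[0].end) == (20001, 50000)

    def test_gap_of_two_windows_splits(self):
        win = windows_df([3, 6], [5.0, 9.0])
        regions = merge_top_windows(win, np.array([True, True]))
        assert len(regions) == 2

    def test_regions_disjoint_each_window_once(self):
        rng = np.random.default_rng(2)
        idx = np.sort(rng.choice(np.arange(1, 200), 40, replace=False))
        win = windows_df(list(idx), list(rng.random(40)))
        regions = merge_top_windows(win, np.ones(40, dtype=bool))
        members = [w for r in regions for w in r.member_windows]
        assert sorted(members) == sorted(idx)  # every flagged window exactly once
        spans = sorted((r.start, r.end) for r in regions)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
        for r in regions:
            assert r.score == max(
                win.set_index("window").loc[r.member_windows, "mean_score"]
            )

    def test_chromosomes_never_merge(self):
        win = pd.concat(
            [windows_df([3], [1.0], "c1"), windows_df([4], [2.0], "c2")],
            ignore_index=True,
        )
        regions = merge_top_windows(win, np.array([True, True]))
        assert len(regions) == 2


class TestRegionGeneStats:
    def test_gene_in_sweep_region_has_max_fst(self):
        # sites inside the sweep window are fixed differences; background shared
        n = 20
        pops = "a" * 10 + "b" * 10
        rows, positions = [], []
        rng = np.random.default_rng(3)
        for pos in range(500, 30_000, 500):
            positions.append(pos)
            if 10_000 < pos <= 20_000:  # window 2 = the sweep
                rows.append([2] * 10 + [0] * 10)
            else:
                g = rng.integers(0, 3, n).tolist()
                rows.append(g)
        gm = make_genotypes(rows, positions=positions)
        gm.populations = pd.Series(list(pops), index=gm.samples)

        scores = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "score": [30.0 if 10_000 < p <= 20_000 else 0.1 for p in positions],
            }
        )
        win, regions = select_sweep_regions(scores, window=10_000)
        assert any(r.strong for r in regions)

        genes = [
            GeneModel("swept", "chr1", "+", [(12_000, 13_000)]),
            GeneModel("background", "chr1", "+", [(25_000, 26_000)]),
        ]
        stats = region_gene_flank_stats(regions, genes, gm, "a", "b", flank=1000)
        got = stats.set_index("gene_id")["fst"]
        assert "swept" in got.index
        if "background" in got.index:
            assert got["swept"] > got["background"]
        assert got["swept"] == pytest.approx(1.0, abs=0.05)

    def test_gene_without_sites_gets_nan(self):
        gm = make_genotypes([[0, 1, 2, 1]], positions=[100], pops="aabb")
        win = windows_df([1], [5.0])
        regions = merge_top_windows(win, np.array([True]))
        gene = GeneModel("far", "c", "+", [(9000, 9500)])
        stats = region_gene_flank_stats(regions, [gene], gm, "a", "b", flank=100)
        assert len(stats) == 1 and np.isnan(stats["fst"].iloc[0])


class TestVcfRoundTrip:
    def test_write_then_read_preserves_genotypes(self, tmp_path):
        gt = np.array([[0, 1, 2, -1], [2, 2, 0, 1]], dtype=np.int8)
        gm = make_genotypes(gt, positions=[100, 200], pops="aabb")
        path = tmp_path / "sites.vcf"
        gm.to_vcf(path)
        back = GenotypeMatrix.from_vcf(path, gm.populations)
        np.testing.assert_array_equal(back.gt, gt)
        np.testing.assert_array_equal(back.pos, gm.pos)
        assert back.samples == gm.samples
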
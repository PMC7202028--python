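"""Weighted methylation ratios, tiling, filters, and differential calls."""

import numpy as np
import pandas as pd
import pytest

from abarddm import methylation as meth
from abarddm.core import AnalysisConfig, GeneModel, GenomicInterval
from abarddm.methylation import (
    MethylomeIndex,
    RegionMethylation,
    absolute_diff,
    call_differential_promoter,
    conversion_rate,
    metagene_profile,
    passes_filters,
    relative_diff,
    tile_promoter,
    weighted_mc,
)


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )


def random_calls(rng, n, chrom="c", span=2000, context="CHH"):
    pos = np.sort(rng.choice(span, size=n, replace=False))
    total = rng.integers(1, 20, size=n)
    methylated = rng.binomial(total, 0.3)
    return calls_frame(
        [
            (chrom, int(p), "+", context, int(m), int(t))
            for p, m, t in zip(pos, methylated, total)
        ]
    )


class TestWeightedMc:
    def test_pooled_not_mean_of_ratios(self):
        # sites (#C, #T): (3,1) and (0,4) -> 3/8, not mean(3/4, 0/4)
        calls = calls_frame(
            [("c", 10, "+", "CG", 3, 4), ("c", 20, "+", "CG", 0, 4)]
        )
        rm = weighted_mc(calls, GenomicInterval("c", 0, 100), "CG")
        assert rm.mc == pytest.approx(3 / 8)
        assert rm.n_sites == 2

    def test_single_fully_methylated_site(self):
        calls = calls_frame([("c", 10, "+", "CHH", 5, 5)])
        rm = weighted_mc(calls, GenomicInterval("c", 0, 100), "CHH")
        assert rm.mc == 1.0

    def test_no_sites_non_evaluable(self):
        calls = calls_frame([("c", 500, "+", "CG", 1, 2)])
        rm = weighted_mc(calls, GenomicInterval("c", 0, 100), "CG")
        assert not rm.evaluable
        assert np.isnan(rm.mc)

    def test_meth_exceeding_total_rejected_naming_site(self):
        calls = calls_frame([("c", 42, "+", "CG", 5, 2)])
        with pytest.raises(ValueError, match="c:42"):
            MethylomeIndex(calls)

    def test_pooling_identity_over_disjoint_regions(self):
        rng = np.random.default_rng(7)
        calls = random_calls(rng, 200)
        index = MethylomeIndex(calls)
        left = GenomicInterval("c", 0, 900)
        right = GenomicInterval("c", 900, 2000)
        whole = GenomicInterval("c", 0, 2000)
        ml, tl, _ = index.region_counts(left, "CHH")
        mr, tr, _ = index.region_counts(right, "CHH")
        rm = weighted_mc(index, whole, "CHH")
        assert rm.mc == pytest.approx((ml + mr) / (tl + tr))

    def test_always_within_unit_interval(self):
        rng = np.random.default_rng(8)
        index = MethylomeIndex(random_calls(rng, 300))
        for _ in range(50):
            a = int(rng.integers(0, 1900))
            b = int(rng.integers(a + 1, 2001))
            rm = weighted_mc(index, GenomicInterval("c", a, b), "CHH")
            if rm.evaluable:
                assert 0.0 <= rm.mc <= 1.0


class TestConversionRate:
    def test_fully_converted(self):
        calls = calls_frame([("chrC", i, "+", "CHH", 0, 10) for i in range(5)])
        assert conversion_rate(calls, "chrC") == 1.0

    def test_pooled_arithmetic(self):
        calls = calls_frame(
            [("chrC", 1, "+", "CG", 5, 500), ("chrC", 2, "+", "CHH", 0, 500)]
        )
        assert conversion_rate(calls, "chrC") == pytest.approx(0.995)

    def test_zero_coverage_raises(self):
        calls = calls_frame([("chr1", 1, "+", "CG", 1, 2)])
        with pytest.raises(ValueError, match="chrC"):
            conversion_rate(calls, "chrC")

    def test_recovers_simulated_nonconversion(self, small_bundle):
        calls = meth.read_cytosine_calls(small_bundle.path("meth_WT_MS"))
        rate = conversion_rate(calls, "chrC")
        # ~14k plastid cytosines at 10x: binomial error well under 0.002
        assert rate == pytest.approx(0.995, abs=0.002)


class TestFilters:
    def region(self, coverage, n_sites, context="CG", mc=0.5):
        return RegionMethylation(
            GenomicInterval("c", 0, 100), context, mc, n_sites, coverage, True
        )

    @pytest.mark.parametrize(
        "coverage,n_sites,mode,expected",
        [
            (5.0, 2, "genome_wide", True),  # boundaries inclusive
            (4.9, 5, "genome_wide", False),
            (5.0, 1, "genome_wide", False),
            (3.0, 2, "promoter", True),
            (1.9, 2, "promoter", False),
        ],
    )
    def test_coverage_and_site_minima(self, coverage, n_sites, mode, expected):
        assert passes_filters(self.region(coverage, n_sites), mode) is expected

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="mode"):
            passes_filters(self.region(5, 5), "exome")

    def test_level_gate_is_separate(self):
        config = AnalysisConfig()
        low_cg = self.region(10, 10, context="CG", mc=0.05)
        assert passes_filters(low_cg, "genome_wide", config)
        assert not meth.is_methylated(low_cg, config)
        chh = self.region(10, 10, context="CHH", mc=0.02)
        assert meth.is_methylated(chh, config)


class TestDiffs:
    def test_relative_diff_examples(self):
        assert relative_diff(0.0032, 0.0100) == pytest.approx(-68.0)
        assert relative_diff(0.10, 0.10) == 0.0
        assert relative_diff(0.0222, 0.0200) == pytest.approx(11.0)

    def test_relative_diff_zero_reference_undefined(self):
        with pytest.raises(ZeroDivisionError):
            relative_diff(0.1, 0.0)

    def test_absolute_diff_antisymmetric(self):
        assert absolute_diff(0.55, 0.10) == pytest.approx(45.0)
        assert absolute_diff(0.10, 0.55) == pytest.approx(-45.0)
        assert absolute_diff(0.3, 0.3) == 0.0


class TestTiling:
    def test_tile_one_is_tss_proximal(self):
        gene = GeneModel("g", "c", "+", 1000, 1500)
        # methylation only in [900, 1000) = the 100 bp next to the TSS
        calls = calls_frame(
            [("c", p, "+", "CHH", 2, 4) for p in range(900, 1000, 10)]
        )
        config = AnalysisConfig(promoter_len=500, tile_len=100)
        tiles = [
            t for t in tile_promoter(gene, calls, config)
            if t.context == "CHH"
        ]
        assert len(tiles) == 5
        assert tiles[0].tile_index == 1 and tiles[0].evaluable
        assert tiles[0].mc == pytest.approx(0.5)
        assert all(not t.evaluable for t in tiles[1:])

    def test_minus_strand_tiles_mirror(self):
        gene = GeneModel("g", "c", "-", 1000, 1500)
        # minus-strand promoter is [1500, 2000); tile 1 is [1500, 1600)
        calls = calls_frame(
            [("c", p, "-", "CHH", 3, 3) for p in range(1500, 1600, 20)]
        )
        config = AnalysisConfig(promoter_len=500, tile_len=100)
        tiles = [t for t in tile_promoter(gene, calls, config) if t.context == "CHH"]
        assert tiles[0].tile_index == 1
        assert tiles[0].mc == pytest.approx(1.0)

    def test_non_evaluable_tiles_excluded_from_gene_average(self):
        gene = GeneModel("g", "c", "+", 1000, 1500)
        calls = calls_frame([("c", 950, "+", "CG", 1, 2)])
        config = AnalysisConfig(promoter_len=300, tile_len=100)
        tiles = tile_promoter(gene, calls, config)
        assert meth.promoter_mean_mc(tiles, "CG") == pytest.approx(0.5)

    def test_aggregation_matches_per_site_oracle(self):
        rng = np.random.default_rng(9)
        gene = GeneModel("g", "c", "+", 2000, 2500)
        calls = random_calls(rng, 400, span=2000)
        config = AnalysisConfig(promoter_len=2000, tile_len=100)
        tiles = [t for t in tile_promoter(gene, calls, config) if t.context == "CHH"]
        for tile in tiles:
            # tile i covers [2000 - i*100, 2000 - (i-1)*100)
            lo, hi = 2000 - tile.tile_index * 100, 2000 - (tile.tile_index - 1) * 100
            sub = calls[(calls.pos >= lo) & (calls.pos < hi)]
            if len(sub) == 0:
                assert not tile.evaluable
            else:
                assert tile.mc == pytest.approx(
                    sub.n_meth.sum() / sub.n_total.sum()
                )
                assert tile.n_sites == len(sub)

    def test_truncated_promoter_yields_fewer_tiles(self):
        gene = GeneModel("g", "c", "+", 250, 800)
        config = AnalysisConfig(promoter_len=2000, tile_len=100)
        calls = calls_frame([("c", 10, "+", "CG", 1, 2)])
        tiles = {t.tile_index for t in tile_promoter(gene, calls, config)}
        assert max(tiles) == 3  # 250 bp promoter -> 2 full tiles + 1 partial


class TestMetagene:
    def test_mean_across_genes(self):
        g1 = GeneModel("g1", "c", "+", 1000, 1200)
        g2 = GeneModel("g2", "c", "+", 5000, 5200)
        calls = calls_frame(
            [("c", 950, "+", "CHH", 2, 100), ("c", 4950, "+", "CHH", 4, 100)]
        )
        config = AnalysisConfig(promoter_len=200, tile_len=100)
        profile = metagene_profile([g1, g2], calls, "CHH", config)
        tile1 = profile[profile.tile_index == 1].iloc[0]
        assert tile1.mean_mc == pytest.approx(0.03)
        assert tile1.n_genes == 2

    def test_empty_gene_list_is_error_free(self):
        profile = metagene_profile([], calls_frame([]), "CHH")
        assert profile.empty

    def test_wt_aba_curve_above_control_at_most_tiles(self, small_bundle):
        from abarddm import core

        genes = core.read_gene_models(small_bundle.path("genes"))
        genome = core.read_genome_fasta(small_bundle.path("genome"))
        lengths = {c: len(s) for c, s in genome.items()}
        prof = {}
        for cond in ("WT_ABA", "WT_MS"):
            calls = meth.read_cytosine_calls(small_bundle.path(f"meth_{cond}"))
            prof[cond] = metagene_profile(
                genes, calls, "CHH", chrom_lengths=lengths
            ).set_index("tile_index")["mean_mc"]
        above = (prof["WT_ABA"] > prof["WT_MS"]).sum()
        assert above > len(prof["WT_MS"]) / 2

    def test_mutant_curve_below_wildtype_at_every_tile(self, small_bundle):
        from abarddm import core

        genes = core.read_gene_models(small_bundle.path("genes"))
        genome = core.read_genome_fasta(small_bundle.path("genome"))
        lengths = {c: len(s) for c, s in genome.items()}
        prof = {}
        for cond in ("MUT_MS", "WT_MS"):
            calls = meth.read_cytosine_calls(small_bundle.path(f"meth_{cond}"))
            prof[cond] = metagene_profile(
                genes, calls, "CHH", chrom_lengths=lengths
            ).set_index("tile_index")["mean_mc"]
        # a 68% reduction at 2% baseline separates the curves clearly
        assert (prof["MUT_MS"] < prof["WT_MS"]).all()


class TestDifferentialCalls:
    def test_cg_large_gain_is_hypermethylated(self):
        call = call_differential_promoter(0.55, 0.10, "CG")
        assert call.call == "CG_hypermethylated"

    def test_chg_requires_forty_points(self):
        assert call_differential_promoter(0.30, 0.10, "CHG").call == "none"
        assert (
            call_differential_promoter(0.55, 0.10, "CHG").call == "differential"
        )

    def test_chh_low_sample_and_fifteen_points(self):
        assert call_differential_promoter(0.03, 0.20, "CHH").call == "differential"
        # neither sample at or below 5%
        assert call_differential_promoter(0.06, 0.30, "CHH").call == "none"
        # low sample but too small a difference
        assert call_differential_promoter(0.03, 0.10, "CHH").call == "none"

    def test_unknown_context_raises(self):
        with pytest.raises(ValueError, match="context"):
            call_differential_promoter(0.1, 0.2, "CpG")
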
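"""miRNA-anchored normalization and promoter siRNA depletion calls."""

import math

import numpy as np
import pandas as pd
import pytest

from abarddm.core import AnalysisConfig
from abarddm.groups import GroupAssignment
from abarddm.sirna import (
    corrected_lfc,
    depletion_rate,
    group_depletion_table,
    mirna_norm_factor,
    profile_promoters,
)


def long_counts(rows, id_col="mirna_id"):
    return pd.DataFrame(rows, columns=[id_col, "genotype", "replicate", "count"])


def libsizes(wt=1e6, mut=1e6, reps=1):
    rows = [("WT", r + 1, wt) for r in range(reps)] + [
        ("MUT", r + 1, mut) for r in range(reps)
    ]
    return pd.DataFrame(rows, columns=["genotype", "replicate", "libsize"])


class TestNormFactor:
    def test_uniform_2p2_fold_shift(self):
        rows = []
        for i in range(5):
            rows.append((f"m{i}", "WT", 1, 1000))
            rows.append((f"m{i}", "MUT", 1, 2200))
        nf = mirna_norm_factor(long_counts(rows), libsizes())
        assert nf.value == pytest.approx(2.2)

    def test_identical_libraries_give_unity(self):
        rows = [("m1", "WT", 1, 500), ("m1", "MUT", 1, 500)]
        nf = mirna_norm_factor(long_counts(rows), libsizes())
        assert nf.value == pytest.approx(1.0)

    def test_median_of_ratios(self):
        rows = []
        for name, mut_count in (("m1", 100), ("m2", 200), ("m3", 300)):
            rows.append((name, "WT", 1, 100))
            rows.append((name, "MUT", 1, mut_count))
        nf = mirna_norm_factor(long_counts(rows), libsizes())
        assert nf.value == pytest.approx(2.0)
        assert nf.method == "median"

    def test_zero_count_mirnas_excluded(self):
        rows = [
            ("m1", "WT", 1, 100), ("m1", "MUT", 1, 300),
            ("m2", "WT", 1, 0), ("m2", "MUT", 1, 500),
        ]
        nf = mirna_norm_factor(long_counts(rows), libsizes())
        assert set(nf.per_mirna) == {"m1"}

    def test_no_usable_mirna_raises(self):
        rows = [("m1", "WT", 1, 0), ("m1", "MUT", 1, 0)]
        with pytest.raises(ValueError, match="miRNA"):
            mirna_norm_factor(long_counts(rows), libsizes())

    def test_ratio_of_sums_alternative(self):
        rows = [
            ("m1", "WT", 1, 100), ("m1", "MUT", 1, 100),
            ("m2", "WT", 1, 100), ("m2", "MUT", 1, 300),
        ]
        nf = mirna_norm_factor(long_counts(rows), libsizes(), method="ratio_of_sums")
        assert nf.value == pytest.approx(2.0)


class TestCorrectedLfc:
    def test_factor_2p2_shifts_by_its_log(self):
        assert corrected_lfc(0.0, 2.2) == pytest.approx(-math.log2(2.2))
        assert corrected_lfc(0.0, 2.2) == pytest.approx(-1.1375, abs=1e-3)

    def test_unit_factor_is_identity(self):
        assert corrected_lfc(1.7, 1.0) == 1.7

    def test_cancellation(self):
        assert corrected_lfc(math.log2(2.2), 2.2) == pytest.approx(0.0)

    def test_nonpositive_factor_raises(self):
        with pytest.raises(ValueError):
            corrected_lfc(0.0, 0.0)


class TestDepletionCalls:
    def test_strong_depletion_called(self):
        counts = long_counts(
            [("g", "WT", 1, 100), ("g", "MUT", 1, 10)], id_col="gene_id"
        )
        (p,) = profile_promoters(counts, libsizes(), 2.2)
        assert p.corrected_lfc == pytest.approx(-4.40, abs=0.05)
        assert p.depleted and p.pvalue < 1e-6

    def test_borderline_decided_by_binomial_test(self):
        # equal counts: corrected lfc ~ -1.14 passes the fold cutoff, and the
        # binomial test against the 2.2-shifted null decides
        counts = long_counts(
            [("g", "WT", 1, 100), ("g", "MUT", 1, 100)], id_col="gene_id"
        )
        (p,) = profile_promoters(counts, libsizes(), 2.2)
        assert p.corrected_lfc == pytest.approx(-math.log2(2.2), abs=0.02)
        from scipy.stats import binomtest

        expected_p = binomtest(100, 200, 2.2 / 3.2).pvalue
        assert p.pvalue == pytest.approx(expected_p)
        assert p.depleted is (p.pvalue <= 0.05)

    def test_zero_count_region_excluded_as_low_abundance(self):
        counts = long_counts(
            [("g", "WT", 1, 0), ("g", "MUT", 1, 0)], id_col="gene_id"
        )
        (p,) = profile_promoters(counts, libsizes(), 2.2)
        assert not p.evaluable and not p.depleted

    def test_mirna_like_regions_center_at_zero(self):
        # regions following the global composition shift exactly are not
        # depleted after correction
        rng = np.random.default_rng(16)
        rows = []
        for i in range(50):
            base = rng.integers(200, 2000)
            rows.append((f"g{i}", "WT", 1, int(base)))
            rows.append((f"g{i}", "MUT", 1, int(rng.poisson(base * 2.2))))
        profiles = profile_promoters(long_counts(rows, "gene_id"), libsizes(), 2.2)
        mean_corr = np.mean([p.corrected_lfc for p in profiles])
        assert abs(mean_corr) < 0.05
        assert sum(p.depleted for p in profiles) == 0


class TestDepletionRate:
    @pytest.mark.parametrize(
        "n_depleted,n_total,expected",
        [(108, 470, 22.98), (7844, 44301, 17.71), (0, 50, 0.00), (50, 50, 100.00)],
    )
    def test_two_decimal_percentages(self, n_depleted, n_total, expected):
        assert depletion_rate(n_depleted, n_total) == expected

    def test_monotone_in_depleted_count(self):
        rates = [depletion_rate(k, 200) for k in range(0, 201, 10)]
        assert rates == sorted(rates)

    def test_errors(self):
        with pytest.raises(ValueError):
            depletion_rate(1, 0)
        with pytest.raises(ValueError):
            depletion_rate(5, 3)


class TestGroupTable:
    def test_rates_and_genome_wide_row(self):
        counts = []
        for i in range(40):
            depleted = i < 10
            counts.append((f"g{i}", "WT", 1, 400))
            counts.append((f"g{i}", "MUT", 1, 880 if not depleted else 40))
        profiles = profile_promoters(
            long_counts(counts, "gene_id"), libsizes(), 2.2
        )
        assignments = [
            GroupAssignment(f"g{i}", frozenset({"V" if i < 20 else "VI"}))
            for i in range(40)
        ]
        table = group_depletion_table(assignments, profiles)
        by_label = table.set_index("label")
        assert by_label.loc["group_V", "n_depleted"] == 10
        assert by_label.loc["group_V", "pct_depleted"] == 50.00
        assert by_label.loc["group_VI", "n_depleted"] == 0
        assert by_label.loc["genome_wide", "n_genes"] == 40
        assert by_label.loc["genome_wide", "pct_depleted"] == 25.00

    def test_empty_group_row_omitted(self, caplog):
        table = group_depletion_table(
            [GroupAssignment("absent", frozenset({"I"}))], []
        )
        assert "group_I" not in set(table["label"])

    def test_recovers_simulated_depletion_fraction(self, small_bundle):
        libs = pd.read_csv(small_bundle.path("libsizes"), sep="\t")
        nf = mirna_norm_factor(
            pd.read_csv(small_bundle.path("mirna_counts"), sep="\t"), libs
        )
        # the factor is anchored on stable miRNAs under a configured 2.2x
        # composition shift
        assert nf.value == pytest.approx(2.2, rel=0.05)
        profiles = profile_promoters(
            pd.read_csv(small_bundle.path("sirna_counts"), sep="\t"), libs, nf
        )
        truth = pd.read_csv(small_bundle.path("truth_sirna"), sep="\t")
        truth_map = dict(zip(truth.gene_id, truth.sirna_depleted))
        called = {p.gene_id: p.depleted for p in profiles if p.evaluable}
        depleted_true = [g for g, d in truth_map.items() if d]
        # strong per-region depletion (0.25x at ~20 CPM) is detected for the
        # vast majority of truly depleted promoters, with few false calls
        sensitivity = np.mean([called.get(g, False) for g in depleted_true])
        false_calls = sum(
            called.get(g, False) for g, d in truth_map.items() if not d
        )
        assert sensitivity > 0.8
        assert false_calls <= 2

    def test_mean_corrected_lfc_recovers_depletion_scale(self, small_bundle):
        libs = pd.read_csv(small_bundle.path("libsizes"), sep="\t")
        nf = mirna_norm_factor(
            pd.read_csv(small_bundle.path("mirna_counts"), sep="\t"), libs
        )
        profiles = profile_promoters(
            pd.read_csv(small_bundle.path("sirna_counts"), sep="\t"), libs, nf
        )
        truth = pd.read_csv(small_bundle.path("truth_sirna"), sep="\t")
        depleted = set(truth.loc[truth.sirna_depleted, "gene_id"])
        corr_depleted = np.mean(
            [p.corrected_lfc for p in profiles if p.gene_id in depleted]
        )
        corr_stable = np.mean(
            [p.corrected_lfc for p in profiles if p.gene_id not in depleted]
        )
        assert corr_stable == pytest.approx(0.0, abs=0.15)
        assert corr_depleted == pytest.approx(math.log2(0.25), abs=0.3)
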
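"""DREAM signature classification, site tallies, calls and FDR."""

import numpy as np
import pandas as pd
import pytest

from epistate.core import GeneModel
from epistate import dream
from epistate.dream import (
    GAIN,
    LOSS,
    METHYLATED,
    NONE,
    UNCLASSIFIED,
    UNMETHYLATED,
    aggregate_region_methylation,
    call_global_change,
    call_promoter_change,
    classify_read_signature,
    estimate_call_fdr,
    filter_by_coverage,
    stratify_methylation,
    tally_sites,
)
from epistate.core import AnnotationSet, GenomicInterval


class TestSignature:
    # oracle = enzyme cut-site geometry: XmaI cuts C^CCGGG and fill-in
    # leaves reads starting CCGGG; SmaI cuts CCC^GGG blunt, reads start GGG
    @pytest.mark.parametrize(
        "prefix,expected",
        [
            ("CCGGGATTC", METHYLATED),
            ("GGGATTCAA", UNMETHYLATED),
            ("ATTCGGGCA", UNCLASSIFIED),
            ("CCGGGCCGG", METHYLATED),
            ("GGGGGGGGG", UNMETHYLATED),
            ("NCGGGATTC", UNCLASSIFIED),  # N never matches a signature
            ("CCGGN", UNCLASSIFIED),
        ],
    )
    def test_signature_cases(self, prefix, expected):
        assert classify_read_signature(prefix) == expected

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(ValueError):
            classify_read_signature("CCXGG")

    def test_noiseless_digest_classification_is_error_free(self, rng):
        # every simulated methylated-allele read carries the XmaI prefix
        # and every unmethylated-allele read the SmaI prefix
        bases = np.array(list("ACGT"))
        for sig, expected in (("CCGGG", METHYLATED), ("GGG", UNMETHYLATED)):
            for _ in range(200):
                tail = "".join(rng.choice(bases, size=30))
                assert classify_read_signature((sig + tail)[:9]) == expected


class TestTally:
    def test_counts_and_uncatalogued(self):
        tags = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5,
                "pos": [100, 100, 100, 100, 999],
                "sample": ["s1"] * 5,
                "status": [METHYLATED, METHYLATED, UNMETHYLATED, UNCLASSIFIED,
                           METHYLATED],
            }
        )
        sites, n_un = tally_sites(tags, [("chr1", 100)])
        assert n_un == 1  # the tag at the uncatalogued position 999
        row = sites.iloc[0]
        assert (row["meth_s1"], row["unmeth_s1"]) == (2, 1)

    def test_methylation_fraction_trivial_cases(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [1, 2],
             "meth_s": [0, 50], "unmeth_s": [50, 50]}
        )
        frac = dream.methylation(sites, "s")
        assert frac.tolist() == [0.0, 0.5]

    def test_binomial_sampling_recovery(self, rng):
        p, cov = 0.3, 1000
        meth = rng.binomial(cov, p)
        est = meth / cov
        se = np.sqrt(p * (1 - p) / cov)
        assert abs(est - p) < 3 * se


class TestCoverageFilter:
    def test_boundary_and_any_sample_rule(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "pos": [1, 2],
             "meth_a": [60, 50], "unmeth_a": [60, 50],
             "meth_b": [50, 50], "unmeth_b": [49, 50]}
        )
        res = filter_by_coverage(sites, 100)
        # (120, 99) dropped, (100, 100) retained (boundary inclusive)
        assert res.n_retained == 1 and res.n_dropped == 1
        assert res.sites.iloc[0]["pos"] == 2

    def test_random_table_matches_row_scan_oracle(self, rng):
        n = 300
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": np.arange(n),
                "meth_a": rng.integers(0, 120, n),
                "unmeth_a": rng.integers(0, 120, n),
                "meth_b": rng.integers(0, 120, n),
                "unmeth_b": rng.integers(0, 120, n),
            }
        )
        res = filter_by_coverage(sites, 100)
        expected = {
            int(r["pos"])
            for _, r in sites.iterrows()
            if r["meth_a"] + r["unmeth_a"] >= 100
            and r["meth_b"] + r["unmeth_b"] >= 100
        }
        assert set(res.sites["pos"]) == expected

    def test_min_coverage_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_by_coverage(pd.DataFrame({"chrom": [], "pos": []}), 0)


class TestAggregation:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "meth_s", "unmeth_s"])

    def test_promoter_mean_and_window_exclusion(self):
        g = GeneModel("G", "chr1", 10_000, 20_000, "+")  # TSS 10,000
        sites = self._sites(
            [
                ("chr1", 9_500, 10, 90),   # TSS-500, methylation 0.10
                ("chr1", 10_800, 30, 70),  # TSS+800, methylation 0.30
                ("chr1", 8_500, 90, 10),   # TSS-1500: outside the window
            ]
        )
        table, _ = aggregate_region_methylation(sites, [g], "promoter")
        assert table.iloc[0]["n_sites"] == 2
        assert table.iloc[0]["s"] == pytest.approx(0.20)

    def test_gene_without_sites_omitted_and_counted(self):
        g1 = GeneModel("G1", "chr1", 10_000, 20_000, "+")
        g2 = GeneModel("G2", "chr1", 500_000, 510_000, "+")
        sites = self._sites([("chr1", 9_500, 10, 90)])
        table, n_omitted = aggregate_region_methylation(sites, [g1, g2], "promoter")
        assert list(table["gene_id"]) == ["G1"] and n_omitted == 1

    def test_randomized_placement_matches_brute_force_scan(self, rng):
        genes = [
            GeneModel(f"G{i}", "chr1", int(s), int(s) + 5_000,
                      "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(5_000, 200_000, size=20))
        ]
        n = 500
        sites = self._sites(
            [
                ("chr1", int(p), int(m), int(u))
                for p, m, u in zip(
                    rng.integers(0, 210_000, n),
                    rng.integers(0, 50, n),
                    rng.integers(1, 50, n),
                )
            ]
        ).drop_duplicates("pos")
        for region in ("promoter", "body"):
            table, _ = aggregate_region_methylation(sites, genes, region)
            got = table.set_index("gene_id")["s"].to_dict()
            for gene in genes:
                win = gene.promoter if region == "promoter" else gene.body
                vals = [
                    r["meth_s"] / (r["meth_s"] + r["unmeth_s"])
                    for _, r in sites.iterrows()
                    if win.start <= r["pos"] < win.end
                ]
                if vals:
                    assert got[gene.gene_id] == pytest.approx(np.mean(vals))
                else:
                    assert gene.gene_id not in got


class TestCalls:
    @pytest.mark.parametrize(
        "b,c,expected",
        [
            (0.008, 0.030, GAIN),
            (0.005, 0.009, NONE),
            (0.050, 0.008, LOSS),
            (0.010, 0.021, GAIN),   # boundaries: <=1% baseline, >2% comparison
            (0.010, 0.020, NONE),
            (0.011, 0.010, LOSS),
        ],
    )
    def test_promoter_rule(self, b, c, expected):
        calls = call_promoter_change(pd.Series({"g": b}), pd.Series({"g": c}))
        assert calls["g"] == expected

    @pytest.mark.parametrize(
        "b,c,expected",
        [
            (0.80, 0.55, LOSS),
            (0.08, 0.35, GAIN),
            (0.50, 0.20, NONE),   # baseline in neither eligibility band
            (0.10, 0.30, GAIN),   # boundary inclusive
            (0.70, 0.50, LOSS),
            (0.70, 0.51, NONE),   # delta just under 20 points
        ],
    )
    def test_global_rule(self, b, c, expected):
        calls = call_global_change(pd.Series({"s": b}), pd.Series({"s": c}))
        assert calls["s"] == expected

    def test_calls_partition_the_universe(self, rng):
        b = pd.Series(rng.uniform(0, 1, 2_000))
        c = pd.Series(rng.uniform(0, 1, 2_000))
        for fn in (call_promoter_change, call_global_change):
            calls = fn(b, c)
            counts = calls.value_counts()
            assert counts.sum() == 2_000
            assert set(counts.index) <= {GAIN, LOSS, NONE}

    def test_undefined_units_skipped(self):
        calls = call_promoter_change(
            pd.Series({"a": 0.005, "b": np.nan}), pd.Series({"a": 0.05, "b": 0.5})
        )
        assert list(calls.index) == ["a"]


class TestFdr:
    def test_self_comparison_is_exactly_zero(self, rng):
        vals = pd.Series(rng.uniform(0, 0.009, 500))
        est = estimate_call_fdr(vals, vals, "promoter_gain")
        assert est.fdr == 0.0 and est.n_called == 0

    def test_reported_ratio_arithmetic(self, rng):
        # 5 spurious calls among 4,655 eligible unmethylated promoters
        n = 4_655
        baseline = pd.Series(np.full(n, 0.005))
        comparison = baseline.copy()
        comparison.iloc[:5] = 0.03
        est = estimate_call_fdr(baseline, comparison, "promoter_gain")
        assert (est.n_called, est.n_eligible) == (5, 4_655)
        assert est.fdr == pytest.approx(5 / 4_655)

    def test_empty_universe_is_an_error(self):
        vals = pd.Series([0.5, 0.6])
        with pytest.raises(ValueError):
            estimate_call_fdr(vals, vals, "promoter_gain")


class TestStratification:
    def test_class_mean_and_empty_class(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 200],
             "meth_s": [20, 40], "unmeth_s": [80, 60]}
        )
        pmd = AnnotationSet("PMD", [GenomicInterval("chr1", 0, 1_000)])
        lad = AnnotationSet("LAD", [GenomicInterval("chr1", 5_000, 6_000)])
        table = stratify_methylation(sites, {"PMD": pmd, "LAD": lad})
        inside = table[(table["in_first"]) & (~table["in_second"].astype(bool))]
        assert inside.iloc[0]["n_sites"] == 2
        assert inside.iloc[0]["s"] == pytest.approx(0.3)
        empty = table[(table["in_first"]) & (table["in_second"].astype(bool))]
        assert empty.iloc[0]["n_sites"] == 0 and np.isnan(empty.iloc[0]["s"])

    def test_generator_truth_recovered_within_binomial_error(self, small_dataset):
        ds = small_dataset
        cond = ds.config.conditions[0]
        body = ds.site_truth[ds.site_truth["site_class"] == "body"]
        for in_pmd, expected in ((True, 0.20), (False, 0.40)):
            sel = body[body["in_pmd"] == in_pmd]
            counts = ds.dream_counts.merge(sel[["chrom", "pos"]], on=["chrom", "pos"])
            frac = dream.methylation(counts, cond)
            assert frac.mean() == pytest.approx(expected, abs=0.03)
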
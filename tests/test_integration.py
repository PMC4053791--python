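"""TSS meta-profiles, occupancy tracks, cross-layer coupling."""

import numpy as np
import pandas as pd
import pytest

from epistate.chromatin import PeakSet
from epistate.core import AnnotationSet, GeneModel, GenomicInterval
from epistate.integration import (
    circular_moving_average,
    k27_intensity_track,
    methylation_gain_k27_coupling,
    methylation_k27_correlation,
    pmd_stratified_k27,
    tss_metaprofile,
)


def genes_on_grid(n, spacing=50_000, strand="+", chrom="chr1", start0=20_000):
    return [
        GeneModel(f"G{i}", chrom, start0 + i * spacing,
                  start0 + i * spacing + 5_000, strand)
        for i in range(n)
    ]


class TestSmoothing:
    def test_matches_brute_force_circular_window_oracle(self, rng):
        for _ in range(20):
            m = int(rng.integers(3, 120))
            k = int(rng.integers(1, 60))
            x = rng.normal(size=m)
            got = circular_moving_average(x, k)
            half = min(k // 2, (m - 1) // 2)  # window capped at track length
            expected = np.array(
                [
                    np.mean([x[(i + j) % m] for j in range(-half, half + 1)])
                    for i in range(m)
                ]
            )
            assert np.allclose(got, expected)

    def test_conserves_global_mean_exactly(self, rng):
        for k in (1, 5, 25, 35, 50):
            x = rng.normal(size=400)
            s = circular_moving_average(x, k)
            assert abs(s.mean() - x.mean()) <= 1e-9 * max(abs(x.mean()), 1.0)

    def test_identity_for_window_one(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(circular_moving_average(x, 1), x)


class TestMetaProfile:
    def test_constant_signal_gives_flat_profile(self, rng):
        genes = genes_on_grid(10)
        pos = rng.integers(0, 500_000, 3_000)
        obs = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "value": 0.7}
        )
        profile = tss_metaprofile(obs, genes, smoothing_neighbors=25)
        assert np.allclose(profile.raw, 0.7)
        assert np.allclose(profile.smoothed, 0.7)

    def test_signal_concentrated_at_tss(self):
        genes = genes_on_grid(20)
        rows = []
        for g in genes:
            for d in range(-2_000, 2_000, 50):
                rows.append(
                    {"chrom": "chr1", "pos": g.tss + d,
                     "value": 1.0 if -200 <= d < 200 else 0.0}
                )
        profile = tss_metaprofile(pd.DataFrame(rows), genes,
                                  smoothing_neighbors=5, max_distance=2_000)
        table = profile.table
        peak_bin = table.loc[table["smoothed"].idxmax(), "distance"]
        assert -250 <= peak_bin < 250
        far = table[abs(table["distance"]) > 1_000]
        assert np.allclose(far["raw"], 0.0)

    def test_smoothed_equals_moving_average_of_bin_means(self, rng):
        genes = genes_on_grid(5)
        pos = rng.integers(0, 260_000, 2_000)
        obs = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "value": rng.normal(size=2_000)}
        )
        k = 35
        profile = tss_metaprofile(obs, genes, smoothing_neighbors=k)
        assert np.allclose(
            profile.smoothed, circular_moving_average(profile.raw, k)
        )
        # and conservation carries over to the emitted track
        assert profile.smoothed.mean() == pytest.approx(
            profile.raw.mean(), rel=1e-9
        )

    def test_strand_mirroring_invariance(self, rng):
        plus = [GeneModel("G", "chr1", 50_000, 55_000, "+")]
        t = plus[0].tss
        minus = [GeneModel("G", "chr1", 2 * t - 55_000, 2 * t - 50_000, "-")]
        pos = rng.integers(40_000, 60_000, 500)
        vals = rng.uniform(size=500)
        obs_plus = pd.DataFrame({"chrom": "chr1", "pos": pos, "value": vals})
        # mirror observations about the TSS: p -> 2t - 1 - p
        obs_minus = pd.DataFrame(
            {"chrom": "chr1", "pos": 2 * t - 1 - pos, "value": vals}
        )
        p1 = tss_metaprofile(obs_plus, plus, smoothing_neighbors=7)
        p2 = tss_metaprofile(obs_minus, minus, smoothing_neighbors=7)
        assert np.array_equal(p1.distances, p2.distances)
        assert np.allclose(p1.raw, p2.raw)

    def test_empty_subset_is_an_error(self):
        obs = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "value": [1.0]})
        with pytest.raises(ValueError):
            tss_metaprofile(obs, [])


class TestOccupancy:
    def test_inside_and_outside_peaks(self):
        ps = PeakSet("H3K27me3", "c", [GenomicInterval("chr1", 100, 200)])
        occ = k27_intensity_track(ps, ["chr1", "chr1", "chr2"], np.array([150, 250, 150]))
        assert occ.tolist() == [1.0, 0.0, 0.0]

    def test_random_positions_match_bitmap_oracle(self, rng):
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 9_000, 40), rng.integers(1, 700, 40))
        ]
        ps = PeakSet("H3K27me3", "c", ivs)
        bitmap = np.zeros(10_000, dtype=bool)
        for iv in ivs:
            bitmap[iv.start:iv.end] = True
        pos = rng.integers(0, 10_000, 2_000)
        occ = k27_intensity_track(ps, np.repeat("chr1", 2_000), pos)
        assert np.array_equal(occ.astype(bool), bitmap[pos])


class TestCoupling:
    def _setup(self, rng, n_gain=20, n_ctrl=20, couple=True):
        genes = genes_on_grid(n_gain + n_ctrl)
        gain, ctrl = genes[:n_gain], genes[n_gain:]
        rows = []
        for g in genes:
            for d in range(-1_500, 1_500, 100):
                rows.append({"chrom": g.chrom, "pos": g.tss + d})
        sites = pd.DataFrame(rows)
        base = PeakSet("H3K27me3", "baseline", [])
        comp_ivs = [
            GenomicInterval(g.chrom, g.tss - 1_000, g.tss + 1_000)
            for g in (gain if couple else [])
        ]
        comp = PeakSet("H3K27me3", "comparison", comp_ivs)
        return gain, ctrl, sites, base, comp

    def test_planted_coupling_detected(self, rng):
        gain, ctrl, sites, base, comp = self._setup(rng)
        res = methylation_gain_k27_coupling(
            gain, ctrl, sites, base, comp, n_permutations=500, rng=rng
        )
        assert res.statistic > 0.5
        assert res.p_value <= 0.05

    def test_identical_tracks_give_zero_contrast(self, rng):
        gain, ctrl, sites, base, comp = self._setup(rng)
        res = methylation_gain_k27_coupling(
            gain, ctrl, sites, comp, comp, n_permutations=200, rng=rng
        )
        assert res.statistic == 0.0
        assert (res.contrast["delta_occupancy"] == 0).all()

    def test_label_shuffling_breaks_the_signal(self, rng):
        gain, ctrl, sites, base, comp = self._setup(rng)
        mixed = gain[:10] + ctrl[:10]
        other = gain[10:] + ctrl[10:]
        res = methylation_gain_k27_coupling(
            mixed, other, sites, base, comp, n_permutations=500, rng=rng
        )
        assert res.p_value > 0.05


class TestPmdStratification:
    def test_peaks_on_pmd_genes_only(self, rng):
        genes = genes_on_grid(30)
        pmd = AnnotationSet(
            "PMD", [GenomicInterval("chr1", 0, genes[14].end + 10_000)]
        )
        ivs = [
            GenomicInterval(g.chrom, g.tss - 1_000, g.tss + 1_000)
            for g in genes[:15]
        ]
        peaks = {"cond": PeakSet("H3K27me3", "cond", ivs)}
        profiles = pmd_stratified_k27(peaks, genes, pmd, smoothing_neighbors=5,
                                      max_distance=3_000)
        inside = profiles[("inside_pmd", "cond")]
        outside = profiles[("outside_pmd", "cond")]
        assert inside.raw.mean() > 5 * max(outside.raw.mean(), 1e-9)

    def test_no_pmds_flags_inside_empty(self):
        genes = genes_on_grid(5)
        pmd = AnnotationSet("PMD", [])
        peaks = {"c": PeakSet("H3K27me3", "c", [])}
        profiles = pmd_stratified_k27(peaks, genes, pmd, smoothing_neighbors=5,
                                      max_distance=2_000)
        assert profiles[("inside_pmd", "c")] is None
        assert profiles[("outside_pmd", "c")] is not None


class TestMethylationK27Correlation:
    def test_k27_on_top_methylated_half_matches_rank_oracle(self):
        idx = [f"g{i}" for i in range(20)]
        meth = pd.Series(np.linspace(0.0, 0.19, 20), index=idx)
        k27 = pd.Series([False] * 10 + [True] * 10, index=idx)
        res = methylation_k27_correlation(meth, k27)
        # independent oracle: Pearson correlation of the rank vectors
        r_oracle = np.corrcoef(
            pd.Series(meth).rank(), pd.Series(k27.astype(float)).rank()
        )[0, 1]
        assert res.spearman_r == pytest.approx(r_oracle)
        assert res.spearman_r > 0.5

    def test_independent_k27_within_permutation_null(self, rng):
        idx = [f"g{i}" for i in range(400)]
        meth = pd.Series(rng.uniform(0, 0.2, 400), index=idx)
        k27 = pd.Series(rng.random(400) < 0.3, index=idx)
        res = methylation_k27_correlation(meth, k27)
        assert abs(res.spearman_r) < 0.15

    def test_constant_methylation_flagged_degenerate(self):
        idx = list("abcdef")
        meth = pd.Series([0.1] * 6, index=idx)
        k27 = pd.Series([True, False] * 3, index=idx)
        res = methylation_k27_correlation(meth, k27)
        assert res.degenerate and np.isnan(res.spearman_r)
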
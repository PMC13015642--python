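"""CNV calling, LoH detection and benchmark matching."""
import numpy as np
import pytest

from somascope.cnv_loh import (
    RatioSegment,
    call_cnv,
    detect_loh,
    match_calls,
    normalize_ratio,
)
from somascope.intervals import GenomicInterval
from somascope.io import CoverageBin, SnvSite
from somascope.purity import PurityModel, expected_alt_fraction, expected_observed_cn

BIN = 1000


def coverage_track(depths_by_chrom):
    track = []
    for chrom, depths in depths_by_chrom.items():
        for i, d in enumerate(depths):
            track.append(CoverageBin(GenomicInterval(chrom, i * BIN, (i + 1) * BIN), float(d)))
    return track


def het_sites(chrom, positions, fractions, depth=30, genotype="het"):
    return [
        SnvSite(chrom, int(p), "A", "G", float(f), depth, genotype)
        for p, f in zip(positions, fractions)
    ]


class TestNormalizeRatio:
    def test_identical_tracks_give_unit_ratio(self):
        t = coverage_track({"chr1": [30] * 20})
        ratios = [b.ratio for b in normalize_ratio(t, t)]
        assert ratios == pytest.approx([1.0] * 20)

    def test_doubled_chromosome_against_hand_medians(self):
        # 10 chromosomes, tumor doubled on chr1 only: medians 30 (normal)
        # and 30 (tumor; the event covers <50% of bins), so chr1 ratio = 2
        depths = {f"chr{i}": [30] * 10 for i in range(1, 11)}
        normal = coverage_track(depths)
        tumor_depths = dict(depths, chr1=[60] * 10)
        tumor = coverage_track(tumor_depths)
        ratios = {b.interval.chrom: b.ratio for b in normalize_ratio(tumor, normal)}
        assert ratios["chr1"] == pytest.approx(2.0)
        assert ratios["chr2"] == pytest.approx(1.0)

    def test_blacklisted_bin_absent(self):
        t = coverage_track({"chr1": [30] * 10})
        out = normalize_ratio(t, t, blacklist=[GenomicInterval("chr1", 2000, 3000)])
        starts = [b.interval.start for b in out]
        assert 2000 not in starts and len(out) == 9

    def test_zero_normal_depth_bin_removed(self):
        normal = coverage_track({"chr1": [30, 0, 30, 30]})
        tumor = coverage_track({"chr1": [30, 30, 30, 30]})
        assert len(normalize_ratio(tumor, normal)) == 3

    def test_disjoint_grids_rejected(self):
        a = coverage_track({"chr1": [30] * 4})
        b = coverage_track({"chr2": [30] * 4})
        with pytest.raises(ValueError, match="grid"):
            normalize_ratio(a, b)

    def test_majority_removed_warns(self, caplog):
        t = coverage_track({"chr1": [30] * 10})
        with caplog.at_level("WARNING"):
            normalize_ratio(t, t, blacklist=[GenomicInterval("chr1", 0, 9000)])
        assert any(">50%" in r.message for r in caplog.records)


class TestCallCnv:
    def seg(self, ratio, length_bp, chrom="chr1"):
        n_bins = length_bp // BIN
        return RatioSegment(GenomicInterval(chrom, 0, length_bp), ratio, n_bins)

    def test_below_size_floor_suppressed(self):
        assert call_cnv([self.seg(1.5, 50_000)], PurityModel(0.5)) == []

    def test_neutral_ratio_no_call(self):
        assert call_cnv([self.seg(1.0, 2_000_000)], PurityModel(0.5)) == []

    def test_dup_calibrated_through_purity(self):
        (call,) = call_cnv([self.seg(1.5, 2_000_000)], PurityModel(0.5))
        assert call.cnv_type == "DUP"
        assert call.observed_cn == pytest.approx(3.0)
        assert call.calibrated_cn == 4

    def test_calibration_consistency(self):
        # every reported call's calibrated CN minimizes the residual to the
        # observed CN among integer states 0..10
        model = PurityModel(0.7)
        segs = [self.seg(r, 500_000) for r in (0.4, 0.7, 1.3, 1.6, 2.2, 3.0)]
        for call in call_cnv(segs, model):
            residuals = [
                abs(expected_observed_cn(model, c) - call.observed_cn) for c in range(11)
            ]
            assert residuals[call.calibrated_cn] == min(residuals)


class TestDetectLoh:
    def test_all_het_everywhere_no_regions(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 400, replace=False))
        normal = het_sites("chr1", pos, np.full(len(pos), 0.5))
        tumor = het_sites("chr1", pos, rng.normal(0.5, 0.02, len(pos)).clip(0, 1))
        assert detect_loh(normal, tumor, PurityModel(0.7)) == []

    def test_planted_block_recovered_at_p07(self, rng):
        # 2 Mb block, 200 normal-het sites, tumor fractions binomial around
        # the alt-retained expectation 0.85 at depth 30
        model = PurityModel(0.7)
        expected = expected_alt_fraction(model, 2, 2)
        assert expected == pytest.approx(0.85)
        pos = np.linspace(1_000_001, 3_000_000, 200).astype(int)
        normal = het_sites("chr1", pos, np.full(200, 0.5))
        tumor_af = rng.binomial(30, expected, 200) / 30
        tumor = het_sites("chr1", pos, tumor_af)
        regions = detect_loh(normal, tumor, model)
        assert len(regions) == 1
        region = regions[0]
        assert region.interval.start <= 1_100_000
        assert region.interval.end >= 2_900_000
        assert region.n_adjusted_hom_sites >= 25

    def test_same_block_invisible_at_p01(self, rng):
        # band separation p/2 = 0.05 < tolerance 0.10: no region
        model = PurityModel(0.1)
        expected = expected_alt_fraction(model, 2, 2)
        pos = np.linspace(1_000_001, 3_000_000, 200).astype(int)
        normal = het_sites("chr1", pos, np.full(200, 0.5))
        tumor = het_sites("chr1", pos, rng.binomial(30, expected, 200) / 30)
        assert detect_loh(normal, tumor, model) == []

    def test_normal_homs_do_not_seed(self, rng):
        pos = np.arange(1, 3_000_000, 10_000)
        normal = het_sites("chr1", pos, np.full(len(pos), 0.98), genotype="hom_alt")
        tumor = het_sites("chr1", pos, np.full(len(pos), 0.98), genotype="hom_alt")
        assert detect_loh(normal, tumor, PurityModel(0.9)) == []

    def test_zero_shared_sites_warns_and_returns_empty(self, caplog):
        normal = het_sites("chr1", [100], [0.5])
        tumor = het_sites("chr2", [100], [0.5])
        with caplog.at_level("WARNING"):
            assert detect_loh(normal, tumor, PurityModel(0.9)) == []
        assert any("no shared" in r.message for r in caplog.records)

    def test_sex_chromosomes_excluded_by_default(self, rng):
        pos = np.linspace(1_000_001, 3_000_000, 200).astype(int)
        normal = het_sites("chrX", pos, np.full(200, 0.5))
        tumor = het_sites("chrX", pos, np.full(200, 0.95))
        assert detect_loh(normal, tumor, PurityModel(0.9)) == []
        assert detect_loh(normal, tumor, PurityModel(0.9), include_sex_chroms=True)

    def test_tumor_only_mode_uses_megabase_floor(self, rng):
        model = PurityModel(0.9)
        band = expected_alt_fraction(model, 2, 2)
        # 800 kb of shifted sites: below the 1 Mb tumor-only floor
        pos_small = np.linspace(1_000_001, 1_800_000, 100).astype(int)
        small = het_sites("chr1", pos_small, rng.binomial(30, band, 100) / 30)
        assert detect_loh(None, small, model) == []
        # 2 Mb of shifted sites: reported
        pos_big = np.linspace(4_000_001, 6_000_000, 250).astype(int)
        big = het_sites("chr1", pos_big, rng.binomial(30, band, 250) / 30)
        (region,) = detect_loh(None, big, model)
        assert region.interval.length >= 1_000_000

    def test_no_region_crosses_chromosomes(self, rng):
        model = PurityModel(0.9)
        band = expected_alt_fraction(model, 2, 2)
        sites_n, sites_t = [], []
        for chrom in ("chr1", "chr2"):
            pos = np.linspace(1, 2_000_000, 300).astype(int)
            sites_n += het_sites(chrom, pos, np.full(300, 0.5))
            sites_t += het_sites(chrom, pos, rng.binomial(30, band, 300) / 30)
        for region in detect_loh(sites_n, sites_t, model):
            assert region.interval.end <= 2_000_000


class TestMatchCalls:
    MB = 1_000_000

    def test_identical_sets_full_recall(self):
        ivs = [GenomicInterval("chr1", 0, self.MB), GenomicInterval("chr2", 0, self.MB)]
        _, recall = match_calls(ivs, list(ivs))
        assert recall == 1.0

    def test_seventy_percent_boundary_inclusive(self):
        truth = [GenomicInterval("chr1", 0, self.MB)]
        call = [GenomicInterval("chr1", 300_000, self.MB)]  # exactly 700 kb overlap
        table, recall = match_calls(truth, call)
        assert recall == 1.0
        assert table.loc[0, "overlap_frac"] == pytest.approx(0.7)

    def test_sixty_percent_unmatched(self):
        truth = [GenomicInterval("chr1", 0, self.MB)]
        call = [GenomicInterval("chr1", 400_000, self.MB)]  # 600 kb overlap
        _, recall = match_calls(truth, call)
        assert recall == 0.0

    def test_fraction_measured_on_truth_side(self):
        # a small call inside a large truth interval: fraction is small even
        # though the call is fully covered
        truth = [GenomicInterval("chr1", 0, self.MB)]
        call = [GenomicInterval("chr1", 0, 100_000)]
        _, recall = match_calls(truth, call)
        assert recall == 0.0

    def test_empty_truth_gives_nan(self):
        _, recall = match_calls([], [GenomicInterval("chr1", 0, 1000)])
        assert np.isnan(recall)
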
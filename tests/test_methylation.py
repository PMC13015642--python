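"""Windowed methylation, cDMR calling, threshold calibration, panel reference."""
import numpy as np
import pytest

from somascope.intervals import GenomicInterval
from somascope.io import DmrCall, MethylSiteRecord
from somascope.methylation import (
    MethylWindow,
    calibrate_threshold,
    call_cdmr,
    classify_extreme,
    constitutive_regions,
    panel_reference,
    summarize_windows,
)

W = 10_000


def window_track(fractions, chrom="chr1", n_valid=100):
    """Build a track from per-window fractions (None = missing)."""
    track = {}
    for i, f in enumerate(fractions):
        iv = GenomicInterval(chrom, i * W, (i + 1) * W)
        n_mod = 0 if f is None else round(f * n_valid)
        track[(chrom, i * W)] = MethylWindow(
            iv, n_valid if f is not None else 0, n_mod, f
        )
    return track


class TestSummarizeWindows:
    def test_fully_methylated_window(self):
        sites = [MethylSiteRecord("chr1", 100, 10, 10)]
        track = summarize_windows(sites, min_valid=5)
        assert track[("chr1", 0)].fraction == 1.0

    def test_zero_valid_window_missing(self):
        track = summarize_windows([MethylSiteRecord("chr1", 100, 0, 0)], min_valid=5)
        assert track[("chr1", 0)].fraction is None

    def test_counts_pooled_not_fraction_averaged(self):
        # (3 of 10) + (0 of 5) pooled = 3/15 = 0.2, not mean(0.3, 0.0) = 0.15
        sites = [
            MethylSiteRecord("chr1", 100, 3, 10),
            MethylSiteRecord("chr1", 5000, 0, 5),
        ]
        track = summarize_windows(sites, min_valid=5)
        assert track[("chr1", 0)].fraction == pytest.approx(0.2)

    def test_windows_anchored_at_zero(self):
        sites = [MethylSiteRecord("chr1", 19_999, 1, 2), MethylSiteRecord("chr1", 20_000, 1, 2)]
        track = summarize_windows(sites, min_valid=1)
        assert set(track) == {("chr1", 10_000), ("chr1", 20_000)}


class TestCallCdmr:
    def test_forty_point_difference_called_hyper(self):
        calls = call_cdmr(window_track([0.70]), window_track([0.30]))
        assert len(calls) == 1
        assert calls[0].direction == "hyper_in_tumor"
        assert calls[0].difference_pp == pytest.approx(40.0)

    def test_equal_fractions_silent(self):
        assert call_cdmr(window_track([0.5]), window_track([0.5])) == []

    def test_threshold_boundary_inclusive(self):
        # exactly 33 pp is called ("at least 33")
        calls = call_cdmr(window_track([0.63]), window_track([0.30]))
        assert len(calls) == 1
        assert call_cdmr(window_track([0.6299]), window_track([0.30])) == []

    def test_missing_windows_never_called(self):
        calls = call_cdmr(window_track([None, 0.9]), window_track([0.1, None]))
        assert calls == []

    def test_self_comparison_empty(self):
        t = window_track(list(np.linspace(0, 1, 50)))
        assert call_cdmr(t, t) == []

    def test_antisymmetry(self):
        a = window_track([0.9, 0.2, 0.5, 0.1])
        b = window_track([0.1, 0.8, 0.5, 0.9])
        fwd = call_cdmr(a, b)
        rev = call_cdmr(b, a)
        assert len(fwd) == len(rev) > 0
        fwd_by_key = {(c.interval.chrom, c.interval.start): c for c in fwd}
        for c in rev:
            mate = fwd_by_key[(c.interval.chrom, c.interval.start)]
            assert c.difference_pp == pytest.approx(-mate.difference_pp)
            assert {c.direction, mate.direction} == {"hyper_in_tumor", "hypo_in_tumor"}

    def test_grid_mismatch_rejected(self):
        a = window_track([0.5])
        b = {("chr1", 0): MethylWindow(GenomicInterval("chr1", 0, 5000), 100, 50, 0.5)}
        with pytest.raises(ValueError, match="grid"):
            call_cdmr(a, b)


class TestCalibrateThreshold:
    def test_identical_samples_return_one(self):
        t = window_track([0.5] * 200)
        assert calibrate_threshold([t, dict(t), dict(t)], target_count=50) == 1

    def test_target_above_window_count_returns_zero(self):
        t = window_track([0.5] * 10)
        assert calibrate_threshold([t, dict(t)], target_count=10) == 0

    def test_constructed_crossing_at_33(self):
        # two samples, 10,000 windows; differences built so that 60 windows
        # exceed 32 pp and exactly 45 reach/exceed 33 pp -> threshold 33
        n = 10_000
        diffs = np.zeros(n)
        diffs[:45] = 0.35  # >= 33 pp
        diffs[45:60] = 0.325  # in [32, 33) pp
        diffs[60:200] = 0.10
        a = window_track([0.3] * n)
        b = window_track(list(0.3 + diffs))
        # brute-force tally is the oracle
        counts = {t: int(np.sum(np.round(diffs * 100, 6) >= t)) for t in (32, 33)}
        assert counts[32] == 60 and counts[33] == 45
        assert calibrate_threshold([a, b], target_count=50) == 33

    def test_monotone_in_target_count(self):
        rng = np.random.default_rng(7)
        tracks = [window_track(list(rng.random(500))) for _ in range(4)]
        thresholds = [
            calibrate_threshold(tracks, target_count=tc) for tc in (5, 20, 80, 200, 500)
        ]
        assert all(b <= a for a, b in zip(thresholds, thresholds[1:]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            calibrate_threshold([window_track([0.5])])


class TestClassifyExtreme:
    @pytest.mark.parametrize(
        "fraction,label",
        [(0.95, "high"), (0.90, "high"), (0.10, "low"), (0.05, "low"), (0.50, "intermediate")],
    )
    def test_cut_boundaries_inclusive(self, fraction, label):
        classes = classify_extreme(window_track([fraction]))
        assert classes[("chr1", 0)].label == label

    def test_missing_windows_unassessed(self):
        assert classify_extreme(window_track([None])) == {}


class TestPanelReference:
    def test_identical_samples_equal_reference(self):
        t = window_track([0.2, 0.8])
        ref = panel_reference([t, dict(t), dict(t), dict(t), dict(t)])
        assert ref[("chr1", 0)].fraction == pytest.approx(0.2)
        assert ref[("chr1", W)].fraction == pytest.approx(0.8)

    def test_odd_count_median(self):
        tracks = [window_track([f]) for f in (0.1, 0.2, 0.9)]
        assert panel_reference(tracks)[("chr1", 0)].fraction == pytest.approx(0.2)

    def test_even_count_median_is_central_mean(self):
        tracks = [window_track([f]) for f in (0.2, 0.4, 0.6, 0.8)]
        assert panel_reference(tracks)[("chr1", 0)].fraction == pytest.approx(0.5)

    def test_window_below_defined_floor_missing(self):
        tracks = [window_track([0.5]), window_track([None]), window_track([None]),
                  window_track([0.5])]
        assert ("chr1", 0) not in panel_reference(tracks, min_defined=3)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            panel_reference([])


class TestConstitutiveRegions:
    def dmr(self, start, direction="hyper_in_tumor"):
        return DmrCall(GenomicInterval("chr1", start, start + W), 0.9, 0.2, 70.0, direction)

    def test_window_in_all_samples_retained(self):
        calls = [[self.dmr(0)], [self.dmr(0)], [self.dmr(0)]]
        assert constitutive_regions(calls) == [GenomicInterval("chr1", 0, W)]

    def test_window_in_two_of_three_dropped(self):
        calls = [[self.dmr(0)], [self.dmr(0)], []]
        assert constitutive_regions(calls) == []

    def test_direction_must_match(self):
        calls = [[self.dmr(0)], [self.dmr(0, "hypo_in_tumor")]]
        assert constitutive_regions(calls) == []

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            constitutive_regions([])
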
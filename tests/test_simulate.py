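"""Synthetic-data generator: determinism, mixture behavior, export round trips."""
import json

import numpy as np
import pytest

from somascope.io import read_coverage, read_methyl_pileup, read_snvs, read_svs
from somascope.purity import PurityModel
from somascope.simulate import (
    TitrationSpec,
    TruthEvent,
    export_fixture,
    mix_titration,
    simulate_pair,
)

GENOME = {"chr1": 3_000_000, "chr2": 3_000_000}


def mean_depth(sample, chrom=None, lo=None, hi=None):
    vals = [
        b.mean_depth
        for b in sample.coverage
        if (chrom is None or b.interval.chrom == chrom)
        and (lo is None or b.interval.start >= lo)
        and (hi is None or b.interval.end <= hi)
    ]
    return float(np.mean(vals))


class TestSimulatePair:
    def test_no_events_flat_ratio_and_het_vaf(self):
        # 10 Mb genome, depth 30: genome-wide tumor/normal ratio ~ 1 and
        # mean het VAF ~ 0.5 (law of large numbers at a fixed seed)
        genome = {f"chr{i}": 2_000_000 for i in range(1, 6)}
        tumor, normal = simulate_pair([], PurityModel(0.7), seed=5, genome=genome)
        assert mean_depth(tumor) / mean_depth(normal) == pytest.approx(1.0, abs=0.05)
        assert np.mean([s.allele_fraction for s in tumor.snvs]) == pytest.approx(0.5, abs=0.02)

    def test_cn4_event_at_half_purity_shows_ratio_1_5(self):
        truth = [TruthEvent("cnv", "chr1", 500_000, 2_500_000, cn=4)]
        tumor, normal = simulate_pair(truth, PurityModel(0.5), seed=6, genome=GENOME)
        in_event = mean_depth(tumor, "chr1", 500_000, 2_500_000) / mean_depth(
            normal, "chr1", 500_000, 2_500_000
        )
        assert in_event == pytest.approx(1.5, abs=0.05)

    def test_seed_determinism_bit_for_bit(self, tmp_path):
        truth = [TruthEvent("loh", "chr2", 1_000_000, 2_000_000)]
        for run in ("a", "b"):
            t, n = simulate_pair(truth, PurityModel(0.9), seed=42, genome=GENOME)
            export_fixture(t, tmp_path / run)
            export_fixture(n, tmp_path / run)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        t1, _ = simulate_pair([], PurityModel(0.9), seed=1, genome=GENOME)
        t2, _ = simulate_pair([], PurityModel(0.9), seed=2, genome=GENOME)
        assert [b.mean_depth for b in t1.coverage] != [b.mean_depth for b in t2.coverage]

    def test_overlapping_same_kind_events_rejected(self):
        truth = [
            TruthEvent("cnv", "chr1", 0, 1_000_000, cn=3),
            TruthEvent("cnv", "chr1", 500_000, 1_500_000, cn=4),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            simulate_pair(truth, PurityModel(0.9), genome=GENOME)

    def test_hla_loss_shifts_tumor_counts(self):
        truth = [TruthEvent("hla_loh", gene="HLA-A", lost_allele=2)]
        tumor, normal = simulate_pair(truth, PurityModel(0.8), seed=9, genome=GENOME)
        (_, (t1, t2)) = tumor.hla_counts["HLA-A"]
        assert t2 / (t1 + t2) < 0.25  # expected lost fraction (1-p)/2 = 0.1
        (_, (n1, n2)) = normal.hla_counts["HLA-A"]
        assert abs(n1 / (n1 + n2) - 0.5) < 0.15


@pytest.fixture(scope="module")
def pure_pair():
    truth = [TruthEvent("cnv", "chr1", 500_000, 2_500_000, cn=4)]
    return simulate_pair(truth, PurityModel(1.0), seed=21, genome=GENOME)


class TestMixTitration:
    def test_alpha_one_returns_tumor(self, pure_pair):
        tumor, normal = pure_pair
        assert mix_titration(tumor, normal, 1.0) is tumor

    def test_alpha_zero_returns_normal(self, pure_pair):
        tumor, normal = pure_pair
        assert mix_titration(tumor, normal, 0.0) is normal

    def test_half_mix_over_cn4_event_implies_cn3(self, pure_pair):
        tumor, normal = pure_pair
        mixed = mix_titration(tumor, normal, 0.5, seed=3)
        implied_cn = 2 * mean_depth(mixed, "chr1", 500_000, 2_500_000) / mean_depth(
            mixed, "chr2"
        )
        assert implied_cn == pytest.approx(3.0, abs=0.1)
        assert mixed.purity == pytest.approx(0.5)

    def test_mixture_linearity_of_expected_coverage(self, pure_pair):
        tumor, normal = pure_pair
        mixed = mix_titration(tumor, normal, 0.3, seed=4)
        for tb, nb, mb in zip(tumor.coverage[:100], normal.coverage[:100], mixed.coverage[:100]):
            assert mb.mean_depth == pytest.approx(0.3 * tb.mean_depth + 0.7 * nb.mean_depth)

    def test_het_vaf_mixes_at_count_level(self, pure_pair):
        tumor, normal = pure_pair
        mixed = mix_titration(tumor, normal, 0.5, seed=5)
        in_loh = [
            s.allele_fraction for s in mixed.snvs
            if s.chrom == "chr1" and 500_000 < s.pos <= 2_500_000
        ]
        # pure-tumor het on a CN4 event has fraction 0.25 (1 of 4 copies);
        # at alpha 0.5 the mixture expectation is (0.5*1+0.5*1)/(0.5*4+0.5*2)
        assert np.mean(in_loh) == pytest.approx(1 / 3, abs=0.02)

    def test_invalid_alpha_rejected(self, pure_pair):
        with pytest.raises(ValueError):
            mix_titration(*pure_pair, alpha=1.5)


class TestTitrationSpec:
    def test_default_ladder(self):
        assert TitrationSpec().purity_levels == (0.9, 0.7, 0.5, 0.3, 0.1)

    @pytest.mark.parametrize("levels", [(0.5, 0.9), (0.9, 0.9), (1.2, 0.5), (0.5, 0.0)])
    def test_levels_must_strictly_decrease_in_unit_interval(self, levels):
        with pytest.raises(ValueError):
            TitrationSpec(purity_levels=levels)


@pytest.fixture(scope="module")
def exported(tmp_path_factory):
    truth = [
        TruthEvent("cnv", "chr1", 500_000, 1_500_000, cn=4),
        TruthEvent("sv", "chr2", 100_000, 105_000, sv_type="DEL", length=-5_000),
    ]
    tumor, normal = simulate_pair(truth, PurityModel(0.9), seed=33, genome=GENOME)
    out = tmp_path_factory.mktemp("fixture")
    return tumor, export_fixture(tumor, out)


class TestExportFixture:
    def test_coverage_round_trip(self, exported):
        tumor, paths = exported
        bins = read_coverage(paths["coverage"])
        assert len(bins) == len(tumor.coverage)
        assert bins[0].interval == tumor.coverage[0].interval
        assert bins[0].mean_depth == pytest.approx(tumor.coverage[0].mean_depth)

    def test_snv_round_trip(self, exported):
        tumor, paths = exported
        sites = read_snvs(paths["snv"], min_allele_fraction=0.0)
        by_pos = {(s.chrom, s.pos): s for s in sites}
        for s in tumor.snvs[:200]:
            if s.allele_fraction <= 0.0:
                continue
            got = by_pos[(s.chrom, s.pos)]
            assert got.allele_fraction == pytest.approx(s.allele_fraction, abs=1e-5)
            assert got.depth == s.depth

    def test_methyl_round_trip(self, exported):
        tumor, paths = exported
        sites = read_methyl_pileup(paths["methyl"])
        assert len(sites) == len(tumor.methyl_sites)

    def test_sv_round_trip(self, exported):
        tumor, paths = exported
        svs = read_svs(paths["sv"])
        assert [(r.chrom, r.pos, r.sv_type, r.length) for r in svs] == [
            (r.chrom, r.pos, r.sv_type, r.length) for r in sorted(
                tumor.svs, key=lambda r: (r.chrom, r.pos)
            )
        ]

    def test_truth_ledger_lists_every_event(self, exported):
        tumor, paths = exported
        ledger = json.loads(paths["truth"].read_text())
        assert len(ledger["events"]) == len(tumor.truth)
        kinds = {e["kind"] for e in ledger["events"]}
        assert kinds == {"cnv", "sv"}

    def test_empty_truth_still_valid_files(self, tmp_path):
        tumor, _ = simulate_pair([], PurityModel(0.9), seed=1,
                                 genome={"chr1": 200_000})
        paths = export_fixture(tumor, tmp_path)
        assert read_coverage(paths["coverage"])
        assert json.loads(paths["truth"].read_text())["events"] == []
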
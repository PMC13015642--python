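"""End-to-end paired and tumor-only workflows and the summary report."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import cnv_loh as _cnv
from . import hla as _hla
from . import io as _io
from . import methylation as _meth
from . import sv as _sv
from .purity import PurityModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of one workflow run.

    Thresholds default to the published operating points: 100 kb paired
    CNV floor, 1 Mb tumor-only floor, 33 pp methylation threshold,
    90%/10% extreme cuts, 1000 bp SV breakpoint distance, 0.7 overlap
    fraction.
    """

    mode: str  # paired | tumor_only
    purity: float = 1.0
    ploidy: int = 2
    tumor_cov: Optional[str] = None
    normal_cov: Optional[str] = None
    tumor_snv: Optional[str] = None
    normal_snv: Optional[str] = None
    tumor_methyl: Optional[str] = None
    normal_methyl: Optional[str] = None
    panel_dir: Optional[str] = None
    tumor_sv: Optional[str] = None
    normal_sv: Optional[str] = None
    population: Optional[str] = None
    hla_counts: Optional[str] = None
    blacklist: Optional[str] = None
    out_dir: str = "somascope_out"
    window_bp: int = _meth.DEFAULT_WINDOW_BP
    cdmr_pp: float = _meth.DEFAULT_THRESHOLD_PP
    high_cut: float = _meth.HIGH_CUT
    low_cut: float = _meth.LOW_CUT
    sv_dist: int = _sv.DEFAULT_BREAKPOINT_DIST
    overlap_frac: float = 0.7
    min_cnv_bp: int = _cnv.MIN_CNV_BP
    tumor_only_min_bp: int = _cnv.TUMOR_ONLY_MIN_BP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("paired", "tumor_only"):
            raise ValueError(f"mode must be paired or tumor_only, got {self.mode!r}")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        normals = (self.normal_cov, self.normal_snv, self.normal_methyl, self.normal_sv)
        if self.mode == "tumor_only" and any(normals):
            raise ValueError("tumor_only mode forbids normal-sample paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class ReportBundle:
    cnvs: list = field(default_factory=list)
    lohs: list = field(default_factory=list)
    dmrs: list = field(default_factory=list)
    somatic_svs: list = field(default_factory=list)
    hla_calls: list = field(default_factory=list)
    extreme_counts: dict = field(default_factory=dict)
    labels: str = "somatic"


def _require(path: Optional[str], what: str) -> str:
    if path is None:
        raise ValueError(f"missing required input: {what}")
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return path


def _log_thresholds(config: RunConfig) -> None:
    logger.info(
        "thresholds: cnv_floor=%d bp, tumor_only_floor=%d bp, cdmr=%.0f pp, "
        "extreme_cuts=%.0f%%/%.0f%%, sv_dist=%d bp, overlap=%.2f",
        config.min_cnv_bp, config.tumor_only_min_bp, config.cdmr_pp,
        config.high_cut * 100, config.low_cut * 100, config.sv_dist,
        config.overlap_frac,
    )


def run_paired(config: RunConfig) -> ReportBundle:
    """Tumor/normal workflow: somatic CNV + LoH, cDMR, HLA-LoH, somatic SVs."""
    if config.mode != "paired":
        raise ValueError("run_paired requires mode=paired")
    _log_thresholds(config)
    model = PurityModel(config.purity, config.ploidy)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(labels="somatic")

    if config.tumor_cov and config.normal_cov:
        tumor_cov = _io.read_coverage(_require(config.tumor_cov, "tumor coverage"))
        normal_cov = _io.read_coverage(_require(config.normal_cov, "normal coverage"))
        blacklist = (
            _io.read_bed_intervals(config.blacklist) if config.blacklist else None
        )
        ratio = _cnv.normalize_ratio(tumor_cov, normal_cov, blacklist)
        segments = _cnv.segment_ratio(ratio, min_segment_bp=config.min_cnv_bp)
        bundle.cnvs = _cnv.call_cnv(segments, model, min_size_bp=config.min_cnv_bp)

    if config.tumor_snv and config.normal_snv:
        tumor_snv = _io.read_snvs(_require(config.tumor_snv, "tumor SNVs"))
        normal_snv = _io.read_snvs(_require(config.normal_snv, "normal SNVs"))
        lohs = _cnv.detect_loh(normal_snv, tumor_snv, model,
                               min_size_bp=config.min_cnv_bp)
        bundle.lohs = _cnv.annotate_concurrent_cn(lohs, bundle.cnvs)

    if config.tumor_methyl and config.normal_methyl:
        t_windows = _meth.summarize_windows(
            _io.read_methyl_pileup(_require(config.tumor_methyl, "tumor methylation")),
            window_bp=config.window_bp,
        )
        n_windows = _meth.summarize_windows(
            _io.read_methyl_pileup(_require(config.normal_methyl, "normal methylation")),
            window_bp=config.window_bp,
        )
        bundle.dmrs = _meth.call_cdmr(t_windows, n_windows, threshold_pp=config.cdmr_pp)

    if config.tumor_sv and config.normal_sv:
        tumor_sv = _io.read_svs(_require(config.tumor_sv, "tumor SVs (VCF)"))
        normal_sv = _io.read_svs(_require(config.normal_sv, "normal SVs (VCF)"))
        cfg = _sv.SvMatchConfig(max_breakpoint_dist=config.sv_dist)
        report = _sv.subtract_somatic(tumor_sv, normal_sv, cfg)
        svs = report.somatic
        if config.population:
            pop = _io.read_population_annotation(config.population)
            # optional demotion of population-catalogue SVs in paired mode
            svs = _sv.classify_pseudo_somatic(svs, pop).pseudo_somatic
        bundle.somatic_svs = svs

    if config.hla_counts:
        counts = _hla.read_hla_counts(_require(config.hla_counts, "HLA counts"))
        bundle.hla_calls = [_hla.score_hla_loh(c, model) for c in counts]
        _hla.write_hla_calls(bundle.hla_calls, out_dir / "hla_loh.tsv")

    _io.write_calls(bundle.cnvs, bundle.lohs, bundle.dmrs, out_dir)
    config.to_yaml(out_dir / "config.yaml")
    render_report(bundle, out_dir)
    return bundle


def run_tumor_only(config: RunConfig) -> ReportBundle:
    """Tumor-only workflow: candidate CNV/LoH (>1 Mb), extreme methylation,
    panel comparison, pseudo-somatic SVs, HLA homozygosity hints.

    Every output is labeled candidate/pseudo-somatic, never somatic.
    """
    if config.mode != "tumor_only":
        raise ValueError("run_tumor_only requires mode=tumor_only")
    _log_thresholds(config)
    model = PurityModel(config.purity, config.ploidy)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(labels="pseudo-somatic")

    if config.tumor_cov:
        tumor_cov = _io.read_coverage(_require(config.tumor_cov, "tumor coverage"))
        blacklist = (
            _io.read_bed_intervals(config.blacklist) if config.blacklist else None
        )
        ratio = _cnv.tumor_only_ratio(tumor_cov, blacklist)
        segments = _cnv.segment_ratio(ratio, min_segment_bp=config.min_cnv_bp)
        bundle.cnvs = _cnv.call_cnv(
            segments, model, min_size_bp=config.tumor_only_min_bp
        )

    if config.tumor_snv:
        tumor_snv = _io.read_snvs(_require(config.tumor_snv, "tumor SNVs"))
        lohs = _cnv.detect_loh(None, tumor_snv, model,
                               min_size_bp=config.tumor_only_min_bp)
        bundle.lohs = _cnv.annotate_concurrent_cn(lohs, bundle.cnvs)

    if config.tumor_methyl:
        t_windows = _meth.summarize_windows(
            _io.read_methyl_pileup(_require(config.tumor_methyl, "tumor methylation")),
            window_bp=config.window_bp,
        )
        classes = _meth.classify_extreme(
            t_windows, high_cut=config.high_cut, low_cut=config.low_cut
        )
        counts = {"high": 0, "low": 0, "intermediate": 0}
        for c in classes.values():
            counts[c.label] += 1
        bundle.extreme_counts = counts
        if config.panel_dir:
            panel_tracks = [
                _meth.summarize_windows(
                    _io.read_methyl_pileup(p), window_bp=config.window_bp
                )
                for p in sorted(Path(config.panel_dir).glob("*.bedmethyl"))
            ]
            if panel_tracks:
                reference = _meth.panel_reference(panel_tracks)
                bundle.dmrs = _meth.call_cdmr(
                    t_windows, reference, threshold_pp=config.cdmr_pp
                )

    if config.tumor_sv:
        tumor_sv = _io.read_svs(_require(config.tumor_sv, "tumor SVs (VCF)"))
        if config.population:
            pop = _io.read_population_annotation(config.population)
            bundle.somatic_svs = _sv.classify_pseudo_somatic(tumor_sv, pop).pseudo_somatic
        else:
            logger.info("no population annotation given; SV prioritization skipped")

    if config.hla_counts:
        counts = _hla.read_hla_counts(_require(config.hla_counts, "HLA counts"))
        typing = {c.gene: (c.allele1, c.allele2) for c in counts}
        flags = _hla.tumor_only_homozygosity(typing)
        with open(out_dir / "hla_homozygosity_hints.tsv", "w") as fh:
            fh.write("gene\thomozygous_hint\n")
            for gene in sorted(flags):
                fh.write(f"{gene}\t{int(flags[gene])}\n")

    _io.write_calls(bundle.cnvs, bundle.lohs, bundle.dmrs, out_dir)
    config.to_yaml(out_dir / "config.yaml")
    render_report(bundle, out_dir)
    return bundle


def render_report(bundle: ReportBundle, out_dir) -> tuple[Path, Path]:
    """Summary tables (TSV) and a machine-readable JSON index; stable bytes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "summary.tsv"
    json_path = out_dir / "summary.json"

    def per_chrom(items, get_iv):
        tally: dict[str, int] = {}
        for it in items:
            iv = get_iv(it)
            tally[iv.chrom] = tally.get(iv.chrom, 0) + 1
        return dict(sorted(tally.items()))

    summary = {
        "labels": bundle.labels,
        "counts": {
            "cnv": len(bundle.cnvs),
            "loh": len(bundle.lohs),
            "dmr": len(bundle.dmrs),
            "somatic_sv": len(bundle.somatic_svs),
            "hla_loh": sum(
                1 for c in bundle.hla_calls
                if c.classification.startswith("loh_")
            ),
        },
        "per_chromosome": {
            "cnv": per_chrom(bundle.cnvs, lambda c: c.interval),
            "loh": per_chrom(bundle.lohs, lambda r: r.interval),
            "dmr": per_chrom(bundle.dmrs, lambda d: d.interval),
        },
        "size_bp": {
            "cnv_total": sum(c.interval.length for c in bundle.cnvs),
            "loh_total": sum(r.interval.length for r in bundle.lohs),
        },
        "methylation_extreme": bundle.extreme_counts,
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(tsv_path, "w") as fh:
        fh.write("category\tcount\n")
        for cat in sorted(summary["counts"]):
            fh.write(f"{cat}\t{summary['counts'][cat]}\n")
    return tsv_path, json_path
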
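"""Synthetic tumor/normal summary data with planted somatic events.

Generates the summary-level inputs the callers consume — binned
coverage, het-SNV allele counts, windowed methylation pileups, SV call
sets and HLA allele read counts — for a tumor/normal pair at a stated
purity, with a ground-truth ledger of every planted CNV, LoH, DMR, SV
and HLA-LoH event. An in-silico titration operator mixes a pure tumor
with its normal at any fraction by binomial read thinning, so allele
fractions and methylation mix at the count level rather than by
averaging fractions.

Noise model: Poisson depth per coverage bin, binomial allele counts at
SNV sites, binomial modified-call counts per methylation window.
Default genome: 10 chromosomes x 10 Mb — large enough for >= 1 Mb
events on a 1 kb bin grid and a 10 kb methylation grid, small enough
for fast tests.
"""
from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomicInterval
from .io import CoverageBin, MethylSiteRecord, SnvSite, SvRecord
from .purity import PurityModel, expected_alt_fraction, expected_observed_cn

DEFAULT_GENOME = {f"chr{i}": 10_000_000 for i in range(1, 11)}
DEFAULT_TITRATION = (0.9, 0.7, 0.5, 0.3, 0.1)


@dataclass(frozen=True)
class TruthEvent:
    """One planted ground-truth event.

    kind: cnv | loh | dmr | sv | hla_loh. Interval fields apply to the
    genomic kinds; ``gene`` to hla_loh. ``cn`` is the true tumor copy
    number (cnv), ``retained`` the kept allele in an LoH ("alt"/"ref"),
    ``delta_pp`` the planted methylation shift in percentage points,
    ``sv_type``/``length``/``somatic`` describe SVs, ``lost_allele``
    (1 or 2) the lost HLA allele.
    """

    kind: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    cn: Optional[int] = None
    retained: str = "alt"
    delta_pp: float = 40.0
    sv_type: str = "DEL"
    length: int = 0
    somatic: bool = True
    gene: Optional[str] = None
    lost_allele: int = 2

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TitrationSpec:
    purity_levels: tuple[float, ...] = DEFAULT_TITRATION
    seed: int = 0

    def __post_init__(self) -> None:
        levels = self.purity_levels
        if any(not 0 < x <= 1 for x in levels):
            raise ValueError("purity levels must lie in (0, 1]")
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("purity levels must be strictly decreasing")


@dataclass
class SimulatedSample:
    """All summary tracks of one simulated sample plus its truth ledger."""

    name: str
    purity: float
    genome: dict[str, int]
    coverage: list[CoverageBin]
    snvs: list[SnvSite]
    methyl_sites: list[MethylSiteRecord]
    svs: list[SvRecord]
    hla_counts: dict[str, tuple[tuple[str, str], tuple[int, int]]]
    truth: list[TruthEvent]
    seed: int


def _check_truth(truth: Sequence[TruthEvent]) -> None:
    by_kind: dict[str, list[TruthEvent]] = {}
    for ev in truth:
        by_kind.setdefault(ev.kind, []).append(ev)
    for kind, events in by_kind.items():
        if kind == "hla_loh":
            genes = [e.gene for e in events]
            if len(genes) != len(set(genes)):
                raise ValueError("hla_loh events must target distinct genes")
            continue
        ivs = sorted(e.interval for e in events)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping {kind} events: {a} and {b}")


def _event_lookup(events: Sequence[TruthEvent], chrom: str, length: int, scale: int):
    """Per-position event index at `scale` resolution: -1 = none, else event idx."""
    n = length // scale
    idx = np.full(n, -1, dtype=np.int64)
    for i, ev in enumerate(events):
        if ev.chrom != chrom:
            continue
        lo = ev.start // scale
        hi = min(n, -(-ev.end // scale))
        idx[lo:hi] = i
    return idx


def simulate_pair(
    truth: Sequence[TruthEvent],
    model: PurityModel,
    depth: float = 30.0,
    bin_bp: int = 1_000,
    het_density: float = 1.0,
    seed: int = 0,
    genome: Optional[dict[str, int]] = None,
    methyl_window_bp: int = 10_000,
    methyl_valid_per_window: float = 2700.0,
    base_methyl_fraction: float = 0.5,
    hla_depth: int = 200,
    sv_jitter_bp: int = 150,
) -> tuple[SimulatedSample, SimulatedSample]:
    """Simulate a (tumor, normal) pair with planted events at the model's purity.

    Normal coverage bins are Poisson(depth); tumor bins Poisson(depth x
    observed_cn / normal_ploidy) inside CNV events and Poisson(depth)
    elsewhere. Germline-het SNVs are placed at ``het_density`` sites/kb;
    normal alt counts are Binomial(d, 0.5) and tumor alt counts follow
    the purity-expected allele fraction of the local event state.
    Methylation windows draw modified counts Binomial(n_valid, base
    fraction shifted by purity x planted delta inside DMR events); the
    default valid-call mass per 10 kb window (~2700) reflects ~9 CpGs/kb
    at 30x depth. HLA counts are Binomial draws from allele copy
    proportions. Identical
    seeds reproduce identical output bit-for-bit.
    """
    _check_truth(truth)
    genome = dict(genome) if genome else dict(DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    p = model.purity
    ploidy = model.normal_ploidy

    cnv_events = [e for e in truth if e.kind == "cnv"]
    loh_events = [e for e in truth if e.kind == "loh"]
    dmr_events = [e for e in truth if e.kind == "dmr"]
    sv_events = [e for e in truth if e.kind == "sv"]
    hla_events = {e.gene: e for e in truth if e.kind == "hla_loh"}

    t_cov: list[CoverageBin] = []
    n_cov: list[CoverageBin] = []
    t_snv: list[SnvSite] = []
    n_snv: list[SnvSite] = []
    t_meth: list[MethylSiteRecord] = []
    n_meth: list[MethylSiteRecord] = []

    for chrom, length in genome.items():
        n_bins = length // bin_bp
        cnv_idx = _event_lookup(cnv_events, chrom, length, bin_bp)

        expected_t = np.full(n_bins, depth)
        for i, ev in enumerate(cnv_events):
            mask = cnv_idx == i
            if mask.any():
                expected_t[mask] = depth * expected_observed_cn(model, ev.cn) / ploidy
        t_depth = rng.poisson(expected_t).astype(float)
        n_depth = rng.poisson(np.full(n_bins, depth)).astype(float)
        for b in range(n_bins):
            iv = GenomicInterval(chrom, b * bin_bp, (b + 1) * bin_bp)
            t_cov.append(CoverageBin(iv, float(t_depth[b])))
            n_cov.append(CoverageBin(iv, float(n_depth[b])))

        # germline-het SNV sites
        n_sites = int(length / 1_000 * het_density)
        positions = np.unique(rng.integers(1, length + 1, size=n_sites))
        site_depth_n = rng.poisson(depth, size=len(positions))
        alt_n = rng.binomial(np.maximum(site_depth_n, 0), 0.5)

        # per-site expected tumor fraction and expected depth scale
        frac_t = np.full(len(positions), 0.5)
        depth_scale = np.ones(len(positions))
        for ev in loh_events:
            if ev.chrom != chrom:
                continue
            mask = (positions > ev.start) & (positions <= ev.end)
            alt_copies = 2 if ev.retained == "alt" else 0
            frac_t[mask] = expected_alt_fraction(model, alt_copies, 2)
        for ev in cnv_events:
            if ev.chrom != chrom:
                continue
            mask = (positions > ev.start) & (positions <= ev.end)
            frac_t[mask] = expected_alt_fraction(model, 1, ev.cn)
            depth_scale[mask] = expected_observed_cn(model, ev.cn) / ploidy
        site_depth_t = rng.poisson(depth * depth_scale)
        alt_t = rng.binomial(np.maximum(site_depth_t, 0), frac_t)

        for k, pos in enumerate(positions):
            dn, an = int(site_depth_n[k]), int(alt_n[k])
            dt, at = int(site_depth_t[k]), int(alt_t[k])
            n_snv.append(
                SnvSite(chrom, int(pos), "A", "G",
                        an / dn if dn else 0.0, dn, "het")
            )
            af_t = at / dt if dt else 0.0
            gt_t = "het"
            if dt and af_t > 0.9:
                gt_t = "hom_alt"
            elif dt and af_t < 0.1:
                gt_t = "hom_ref"
            t_snv.append(SnvSite(chrom, int(pos), "A", "G", af_t, dt, gt_t))

        # methylation: one pooled record per window
        n_windows = length // methyl_window_bp
        dmr_idx = _event_lookup(dmr_events, chrom, length, methyl_window_bp)
        base = np.full(n_windows, base_methyl_fraction)
        delta = np.zeros(n_windows)
        for i, ev in enumerate(dmr_events):
            delta[dmr_idx == i] = ev.delta_pp / 100.0
        frac_tumor = np.clip(base + p * delta, 0.0, 1.0)
        valid_t = rng.poisson(methyl_valid_per_window, size=n_windows)
        valid_n = rng.poisson(methyl_valid_per_window, size=n_windows)
        mod_t = rng.binomial(valid_t, frac_tumor)
        mod_n = rng.binomial(valid_n, base)
        for w in range(n_windows):
            pos = w * methyl_window_bp
            t_meth.append(MethylSiteRecord(chrom, pos, int(mod_t[w]), int(valid_t[w])))
            n_meth.append(MethylSiteRecord(chrom, pos, int(mod_n[w]), int(valid_n[w])))

    # SVs: germline events in both samples with independent jitter, somatic in tumor only
    if sv_jitter_bp > 500:
        raise ValueError("breakpoint jitter above 500 bp defeats matching")
    t_svs: list[SvRecord] = []
    n_svs: list[SvRecord] = []
    for ev in sv_events:
        jt = int(rng.integers(-sv_jitter_bp, sv_jitter_bp + 1))
        t_svs.append(SvRecord(ev.chrom, max(1, ev.start + 1 + jt), ev.sv_type, ev.length))
        if not ev.somatic:
            jn = int(rng.integers(-sv_jitter_bp, sv_jitter_bp + 1))
            n_svs.append(SvRecord(ev.chrom, max(1, ev.start + 1 + jn), ev.sv_type, ev.length))

    # HLA: two-field heterozygous typing per gene; lost allele thinned by purity
    from .hla import HLA_GENES

    t_hla: dict[str, tuple[tuple[str, str], tuple[int, int]]] = {}
    n_hla: dict[str, tuple[tuple[str, str], tuple[int, int]]] = {}
    for g_i, gene in enumerate(HLA_GENES):
        alleles = (f"{gene}*01:0{g_i + 1}", f"{gene}*02:0{g_i + 1}")
        c1n = int(rng.binomial(hla_depth, 0.5))
        n_hla[gene] = (alleles, (c1n, hla_depth - c1n))
        ev = hla_events.get(gene)
        if ev is None:
            prop1 = 0.5
        elif ev.lost_allele == 1:
            prop1 = (1 - p) / 2.0  # lost allele keeps only its normal-compartment copy
        else:
            prop1 = (1 + p) / 2.0
        c1t = int(rng.binomial(hla_depth, prop1))
        t_hla[gene] = (alleles, (c1t, hla_depth - c1t))

    tumor = SimulatedSample(
        "tumor", p, genome, t_cov, t_snv, t_meth, t_svs, t_hla, list(truth), seed
    )
    normal = SimulatedSample(
        "normal", 0.0, genome, n_cov, n_snv, n_meth, n_svs, n_hla,
        [e for e in truth if not e.somatic and e.kind == "sv"], seed
    )
    return tumor, normal


def _thin(rng: np.random.Generator, count: int, keep: float) -> int:
    return int(rng.binomial(count, keep)) if count > 0 else 0


def mix_titration(
    tumor: SimulatedSample,
    normal: SimulatedSample,
    alpha: float,
    seed: int = 0,
) -> SimulatedSample:
    """Mix a pure tumor with its matched normal at tumor fraction ``alpha``.

    Coverage mixes linearly; SNV, methylation and HLA counts mix by
    binomial thinning of each compartment's reads (keep probability
    alpha for tumor reads, 1 - alpha for normal reads), so observed
    allele fractions behave like a true sequencing mixture. When the tumor
    input is pure, the result has effective purity alpha.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 1.0:
        return tumor
    if alpha == 0.0:
        return normal
    if tumor.genome != normal.genome:
        raise ValueError("samples do not share a genome grid")
    if len(tumor.coverage) != len(normal.coverage):
        raise ValueError("coverage grids disagree")
    rng = np.random.default_rng(seed)

    coverage = []
    for tb, nb in zip(tumor.coverage, normal.coverage):
        if tb.interval != nb.interval:
            raise ValueError("coverage grids disagree")
        coverage.append(
            CoverageBin(tb.interval, alpha * tb.mean_depth + (1 - alpha) * nb.mean_depth)
        )

    normal_at = {(s.chrom, s.pos): s for s in normal.snvs}
    snvs = []
    for ts in tumor.snvs:
        ns = normal_at.get((ts.chrom, ts.pos))
        if ns is None:
            raise ValueError(f"SNV grids disagree at {ts.chrom}:{ts.pos}")
        t_alt = round(ts.allele_fraction * ts.depth)
        n_alt = round(ns.allele_fraction * ns.depth)
        alt = _thin(rng, t_alt, alpha) + _thin(rng, n_alt, 1 - alpha)
        ref = _thin(rng, ts.depth - t_alt, alpha) + _thin(rng, ns.depth - n_alt, 1 - alpha)
        d = alt + ref
        af = alt / d if d else 0.0
        gt = "het"
        if d and af > 0.9:
            gt = "hom_alt"
        elif d and af < 0.1:
            gt = "hom_ref"
        snvs.append(SnvSite(ts.chrom, ts.pos, ts.ref_allele, ts.alt_allele, af, d, gt))

    normal_meth = {(m.chrom, m.pos): m for m in normal.methyl_sites}
    meth = []
    for tm in tumor.methyl_sites:
        nm = normal_meth.get((tm.chrom, tm.pos))
        if nm is None:
            raise ValueError(f"methylation grids disagree at {tm.chrom}:{tm.pos}")
        mod = _thin(rng, tm.n_modified, alpha) + _thin(rng, nm.n_modified, 1 - alpha)
        unmod = _thin(rng, tm.n_valid - tm.n_modified, alpha) + _thin(
            rng, nm.n_valid - nm.n_modified, 1 - alpha
        )
        meth.append(MethylSiteRecord(tm.chrom, tm.pos, mod, mod + unmod))

    hla = {}
    for gene, (alleles, (t1, t2)) in tumor.hla_counts.items():
        (_, (n1, n2)) = normal.hla_counts[gene]
        hla[gene] = (
            alleles,
            (_thin(rng, t1, alpha) + _thin(rng, n1, 1 - alpha),
             _thin(rng, t2, alpha) + _thin(rng, n2, 1 - alpha)),
        )

    return SimulatedSample(
        name=f"titration_{alpha:g}",
        purity=alpha * tumor.purity,
        genome=dict(tumor.genome),
        coverage=coverage,
        snvs=snvs,
        methyl_sites=meth,
        svs=list(tumor.svs),
        hla_counts=hla,
        truth=list(tumor.truth),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def export_fixture(sample: SimulatedSample, out_dir) -> dict[str, Path]:
    """Write one sample's tracks as files readable by the io module.

    coverage BED.gz, SNV VCF, bedMethyl, SV VCF, HLA counts TSV and a
    truth-ledger JSON. Byte-stable for a given sample (gzip mtime fixed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coverage": out_dir / f"{sample.name}.cov.bed.gz",
        "snv": out_dir / f"{sample.name}.snv.vcf",
        "methyl": out_dir / f"{sample.name}.bedmethyl",
        "sv": out_dir / f"{sample.name}.sv.vcf",
        "hla": out_dir / f"{sample.name}.hla.tsv",
        "truth": out_dir / f"{sample.name}.truth.json",
    }

    with gzip.GzipFile(paths["coverage"], "wb", mtime=0) as gz:
        for b in sample.coverage:
            iv = b.interval
            gz.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{b.mean_depth:.4f}\n".encode())

    contigs = "".join(
        f"##contig=<ID={c},length={l}>\n" for c, l in sample.genome.items()
    )
    with open(paths["snv"], "w") as fh:
        fh.write(
            "##fileformat=VCFv4.2\n" + contigs +
            '##FILTER=<ID=PASS,Description="All filters passed">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n'
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample.name}\n"
        )
        for s in sorted(sample.snvs, key=lambda s: (s.chrom, s.pos)):
            gt = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0"}.get(s.genotype, "./.")
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\t"
                f"GT:DP:AF\t{gt}:{s.depth}:{s.allele_fraction:.6f}\n"
            )

    with open(paths["methyl"], "w") as fh:
        for m in sorted(sample.methyl_sites, key=lambda m: (m.chrom, m.pos)):
            pct = 100.0 * m.n_modified / m.n_valid if m.n_valid else 0.0
            n_unmod = m.n_valid - m.n_modified
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.pos + 1}\tm\t{m.n_valid}\t+\t{m.pos}\t"
                f"{m.pos + 1}\t255,0,0\t{m.n_valid}\t{pct:.2f}\t{m.n_modified}\t{n_unmod}\n"
            )

    with open(paths["sv"], "w") as fh:
        fh.write(
            "##fileformat=VCFv4.2\n" + contigs +
            '##FILTER=<ID=PASS,Description="All filters passed">\n'
            '##ALT=<ID=DEL,Description="Deletion">\n##ALT=<ID=DUP,Description="Duplication">\n'
            '##ALT=<ID=INS,Description="Insertion">\n##ALT=<ID=INV,Description="Inversion">\n'
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        for i, r in enumerate(sorted(sample.svs, key=lambda r: (r.chrom, r.pos))):
            end = r.pos + abs(r.length) if r.sv_type != "INS" else r.pos
            fh.write(
                f"{r.chrom}\t{r.pos}\tsv{i}\tN\t<{r.sv_type}>\t.\tPASS\t"
                f"SVTYPE={r.sv_type};SVLEN={r.length};END={end}\n"
            )

    with open(paths["hla"], "w") as fh:
        fh.write("gene\tallele1\tallele2\tnormal_c1\tnormal_c2\ttumor_c1\ttumor_c2\n")
        for gene in sorted(sample.hla_counts):
            (a1, a2), (c1, c2) = sample.hla_counts[gene]
            # single-sample export: its counts fill the role matching its name
            if sample.name == "normal":
                fh.write(f"{gene}\t{a1}\t{a2}\t{c1}\t{c2}\t0\t0\n")
            else:
                fh.write(f"{gene}\t{a1}\t{a2}\t0\t0\t{c1}\t{c2}\n")

    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "sample": sample.name,
                "purity": sample.purity,
                "seed": sample.seed,
                "events": [
                    {k: v for k, v in vars(ev).items() if v is not None}
                    for ev in sample.truth
                ],
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


def write_hla_pair_counts(tumor: SimulatedSample, normal: SimulatedSample, path) -> None:
    """Write the paired HLA counts TSV consumed by the hla module."""
    with open(path, "w") as fh:
        fh.write("gene\tallele1\tallele2\tnormal_c1\tnormal_c2\ttumor_c1\ttumor_c2\n")
        for gene in sorted(tumor.hla_counts):
            (a1, a2), (t1, t2) = tumor.hla_counts[gene]
            (_, (n1, n2)) = normal.hla_counts[gene]
            fh.write(f"{gene}\t{a1}\t{a2}\t{n1}\t{n2}\t{t1}\t{t2}\n")
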
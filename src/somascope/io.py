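"""Readers and writers for the genomic formats the pipeline touches.

Coordinate discipline: BED-family files are 0-based half-open on disk,
VCF is 1-based; everything in memory is 0-based half-open. Conversion
happens only inside this module.
"""
from __future__ import annotations

import gzip
import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .intervals import GenomicInterval


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageBin:
    """Fixed-width genomic window with mean sequencing depth."""

    interval: GenomicInterval
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError(f"mean depth must be non-negative, got {self.mean_depth}")


@dataclass(frozen=True)
class SnvSite:
    """A biallelic SNV with allele fraction, depth, genotype and optional phase.

    `pos` is 1-based (as in the source VCF); `genotype` is one of
    hom_ref/het/hom_alt/missing; `haplotype` is H1/H2 for phased het
    calls (H1 = alt allele on the first haplotype of the phased GT),
    else "unphased".
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_fraction: float
    depth: int
    genotype: str
    haplotype: str = "unphased"
    filter_pass: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele fraction outside [0,1]: {self.allele_fraction}")
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")


@dataclass(frozen=True)
class SvRecord:
    """A structural-variant call (DEL/DUP/INS/INV/BND)."""

    chrom: str
    pos: int  # 1-based
    sv_type: str
    length: int = 0  # signed bp; unused for BND
    end_chrom: Optional[str] = None
    end_pos: Optional[int] = None
    population_hits: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sv_type == "BND" and (self.end_chrom is None or self.end_pos is None):
            raise ValueError("BND records must carry a second breakpoint")

    def key(self) -> tuple[str, int, str, int]:
        return (self.chrom, self.pos, self.sv_type, self.length)


@dataclass(frozen=True)
class MethylSiteRecord:
    """Per-CpG methylation pileup counts (0-based position)."""

    chrom: str
    pos: int
    n_modified: int
    n_valid: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_modified <= self.n_valid:
            raise ValueError(
                f"need 0 <= n_modified <= n_valid, got {self.n_modified}/{self.n_valid}"
            )

    @property
    def informative(self) -> bool:
        return self.n_valid > 0


# output call types (produced by cnv_loh / methylation, serialized here)

@dataclass(frozen=True)
class CnvCall:
    interval: GenomicInterval
    observed_cn: float
    calibrated_cn: int
    cnv_type: str  # DEL or DUP
    somatic: bool = True


@dataclass(frozen=True)
class LohRegion:
    interval: GenomicInterval
    n_adjusted_hom_sites: int
    n_persistent_het_sites: int
    concurrent_cn: Optional[int] = None


@dataclass(frozen=True)
class DmrCall:
    interval: GenomicInterval
    tumor_fraction: float
    control_fraction: float
    difference_pp: float  # tumor - control, percentage points
    direction: str  # hyper_in_tumor / hypo_in_tumor


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_text(path: str | os.PathLike) -> _io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_coverage(path: str | os.PathLike) -> list[CoverageBin]:
    """Read a 4-column (optionally gzipped) coverage BED into CoverageBin records.

    Bins are returned sorted by start within each chromosome; chromosomes
    keep their order of first appearance. Overlapping bins are rejected.
    """
    by_chrom: dict[str, list[CoverageBin]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                depth = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if depth < 0:
                raise ParseError(f"{path}: line {lineno}: negative depth {depth}")
            try:
                bin_ = CoverageBin(GenomicInterval(chrom, start, end), depth)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            by_chrom.setdefault(chrom, []).append(bin_)
    out: list[CoverageBin] = []
    for chrom, bins in by_chrom.items():
        bins.sort(key=lambda b: b.interval.start)
        for prev, cur in zip(bins, bins[1:]):
            if cur.interval.start < prev.interval.end:
                raise ParseError(
                    f"{path}: overlapping coverage bins on {chrom}: "
                    f"[{prev.interval.start},{prev.interval.end}) and "
                    f"[{cur.interval.start},{cur.interval.end})"
                )
        out.extend(bins)
    return out


def _allele_fraction(rec: "pysam.VariantRecord", sample: str) -> Optional[float]:
    """AF from the caller's annotation when present, else alt depth / total depth."""
    fmt = rec.samples[sample]
    if "AF" in fmt and fmt["AF"] is not None:
        af = fmt["AF"]
        return float(af[0] if isinstance(af, tuple) else af)
    if "VAF" in fmt and fmt["VAF"] is not None:
        af = fmt["VAF"]
        return float(af[0] if isinstance(af, tuple) else af)
    if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
        ad = fmt["AD"]
        total = sum(ad)
        if total > 0:
            return float(ad[1]) / total
        return 0.0
    if "AF" in rec.info:
        af = rec.info["AF"]
        return float(af[0] if isinstance(af, tuple) else af)
    return None


def _depth(rec: "pysam.VariantRecord", sample: str) -> int:
    fmt = rec.samples[sample]
    if "DP" in fmt and fmt["DP"] is not None:
        return int(fmt["DP"])
    if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
        return int(sum(fmt["AD"]))
    return 0


def read_snvs(
    path: str | os.PathLike,
    min_allele_fraction: float = 0.10,
    pass_only: bool = True,
) -> list[SnvSite]:
    """Read biallelic SNVs from a VCF, filtering on PASS and allele fraction.

    Only records with allele fraction strictly greater than
    ``min_allele_fraction`` are kept. Multi-allelic records are rejected
    rather than decomposed. Phase is preserved from the GT field.
    """
    out: list[SnvSite] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample column")
        sample = samples[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multi-allelic or ALT-less: rejected, not decomposed
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt in (".", "*"):
                continue  # not a SNV
            filters = list(rec.filter.keys())
            is_pass = filters in ([], ["PASS"])
            if pass_only and not is_pass:
                continue
            af = _allele_fraction(rec, sample)
            if af is None:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} carries neither an "
                    "AF/VAF annotation nor an AD field; one of these is required "
                    "to compute the allele fraction"
                )
            af = min(max(af, 0.0), 1.0)
            if af <= min_allele_fraction:
                continue
            fmt = rec.samples[sample]
            gt = fmt.get("GT")
            phased = bool(getattr(fmt, "phased", False))
            if gt is None or None in gt:
                genotype = "missing"
            elif gt == (0, 0):
                genotype = "hom_ref"
            elif set(gt) == {0, 1}:
                genotype = "het"
            elif gt == (1, 1):
                genotype = "hom_alt"
            else:
                continue  # genotype refers to an allele we rejected
            haplotype = "unphased"
            if phased and genotype == "het":
                haplotype = "H1" if gt[0] == 1 else "H2"
            out.append(
                SnvSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    allele_fraction=af,
                    depth=_depth(rec, sample),
                    genotype=genotype,
                    haplotype=haplotype,
                    filter_pass=is_pass,
                )
            )
    return out


def read_methyl_pileup(path: str | os.PathLike) -> list[MethylSiteRecord]:
    """Read a bedMethyl file (modkit dialect) into per-CpG records.

    Expected columns: chrom, start, end, mod code, score, strand,
    thickStart, thickEnd, color, n_valid, percent_modified[, n_modified, ...].
    When the explicit n_modified column (12th) is absent it is recovered
    from the percent column. Sites with n_modified > n_valid are rejected.
    """
    out: list[MethylSiteRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(
                    f"{path}: line {lineno}: bedMethyl needs >= 11 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                pos = int(fields[1])
                n_valid = int(fields[9])
                if len(fields) >= 12:
                    n_mod = int(fields[11])
                else:
                    n_mod = round(float(fields[10]) / 100.0 * n_valid)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            try:
                out.append(MethylSiteRecord(chrom, pos, n_mod, n_valid))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def read_haplotagged_methyl(
    path: str | os.PathLike,
) -> dict[str, list[MethylSiteRecord]]:
    """Read a bedMethyl with a trailing haplotype column (H1/H2/unphased).

    Dialect: standard bedMethyl columns followed by one extra column
    holding the haplotype label. Unphased sites are returned under
    "unphased" and excluded from allele-specific analysis by callers.
    """
    out: dict[str, list[MethylSiteRecord]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: haplotagged bedMethyl needs >= 12 columns"
                )
            hap = fields[-1]
            if hap not in ("H1", "H2", "unphased"):
                raise ParseError(
                    f"{path}: line {lineno}: haplotype column must be H1/H2/unphased, got {hap!r}"
                )
            try:
                chrom = fields[0]
                pos = int(fields[1])
                n_valid = int(fields[9])
                n_mod = int(fields[11])
                rec = MethylSiteRecord(chrom, pos, n_mod, n_valid)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            out.setdefault(hap, []).append(rec)
    return out


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a 3+-column BED (blacklist, gene panel) into intervals."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def read_gene_panel(path: str | os.PathLike) -> dict[str, GenomicInterval]:
    """Read a 4-column BED of gene intervals (name in column 4)."""
    out: dict[str, GenomicInterval] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: gene panel BED needs 4 columns")
            out[fields[3]] = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
    return out


def read_svs(path: str | os.PathLike, pass_only: bool = True) -> list[SvRecord]:
    """Read SV calls from a VCF carrying SVTYPE / SVLEN / END INFO keys."""
    out: list[SvRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if pass_only and filters not in ([], ["PASS"]):
                continue
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            svtype = str(svtype)
            if svtype == "BND":
                # breakend mate parsed from ALT, e.g. N[chr2:321682[
                alt = rec.alts[0] if rec.alts else ""
                end_chrom, end_pos = None, None
                for sep in ("[", "]"):
                    if sep in alt:
                        inner = alt.split(sep)[1]
                        end_chrom, p = inner.split(":")
                        end_pos = int(p)
                        break
                if end_chrom is None:
                    continue
                out.append(SvRecord(rec.chrom, rec.pos, "BND", 0, end_chrom, end_pos))
            else:
                svlen = rec.info.get("SVLEN")
                if isinstance(svlen, tuple):
                    svlen = svlen[0]
                if svlen is None:
                    end = rec.info.get("END", rec.stop)
                    svlen = int(end) - rec.pos
                    if svtype == "DEL":
                        svlen = -svlen
                out.append(SvRecord(rec.chrom, rec.pos, svtype, int(svlen)))
    return out


def read_population_annotation(path: str | os.PathLike) -> dict[tuple[str, int, str, int], int]:
    """Read the population-presence TSV: chrom, pos, sv_type, length, hits."""
    out: dict[tuple[str, int, str, int], int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            try:
                key = (fields[0], int(fields[1]), fields[2], int(fields[3]))
                hits = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if hits < 0:
                raise ParseError(f"{path}: line {lineno}: negative hit count")
            out[key] = hits
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=somascope
##ALT=<ID=DEL,Description="Deletion relative to normal ploidy">
##ALT=<ID=DUP,Description="Duplication relative to normal ploidy">
##ALT=<ID=LOH,Description="Loss of heterozygosity region">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Event length in bp">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Event type">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Purity-calibrated tumor copy number">
##INFO=<ID=OBSCN,Number=1,Type=Float,Description="Observed (coverage-implied) copy number">
##INFO=<ID=SOMATIC,Number=1,Type=Integer,Description="1 when the event is somatic">
##INFO=<ID=HOMSITES,Number=1,Type=Integer,Description="Adjusted-homozygous site support (LoH)">
##INFO=<ID=HETSITES,Number=1,Type=Integer,Description="Persistent heterozygous sites inside region (LoH)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_calls(
    cnvs: Sequence[CnvCall],
    lohs: Sequence[LohRegion],
    dmrs: Sequence[DmrCall],
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Serialize call sets: CNV/LoH as VCF + BED, DMRs as BED.

    Output is byte-stable: records are sorted by (chrom, start) within
    each category and floats use a fixed format.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cnv_loh_vcf": out_dir / "cnv_loh.vcf",
        "cnv_bed": out_dir / "cnv.bed",
        "loh_bed": out_dir / "loh.bed",
        "dmr_bed": out_dir / "dmr.bed",
    }

    cnvs = sorted(cnvs, key=lambda c: (c.interval.chrom, c.interval.start))
    lohs = sorted(lohs, key=lambda r: (r.interval.chrom, r.interval.start))
    dmrs = sorted(dmrs, key=lambda d: (d.interval.chrom, d.interval.start))

    with open(paths["cnv_loh_vcf"], "w") as fh:
        fh.write(_VCF_HEADER)
        for c in cnvs:
            iv = c.interval
            info = (
                f"END={iv.end};SVLEN={iv.length};SVTYPE={c.cnv_type};"
                f"CN={c.calibrated_cn};OBSCN={c.observed_cn:.4f}"
            )
            if c.somatic:
                info += ";SOMATIC=1"
            fh.write(
                f"{iv.chrom}\t{iv.start + 1}\t.\tN\t<{c.cnv_type}>\t.\tPASS\t{info}\n"
            )
        for r in lohs:
            iv = r.interval
            info = (
                f"END={iv.end};SVLEN={iv.length};SVTYPE=LOH;"
                f"HOMSITES={r.n_adjusted_hom_sites};HETSITES={r.n_persistent_het_sites}"
            )
            if r.concurrent_cn is not None:
                info += f";CN={r.concurrent_cn}"
            info += ";SOMATIC=1"
            fh.write(f"{iv.chrom}\t{iv.start + 1}\t.\tN\t<LOH>\t.\tPASS\t{info}\n")

    with open(paths["cnv_bed"], "w") as fh:
        for c in cnvs:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cnv_type}\t"
                f"{c.calibrated_cn}\t{c.observed_cn:.4f}\t{int(c.somatic)}\n"
            )
    with open(paths["loh_bed"], "w") as fh:
        for r in lohs:
            iv = r.interval
            cn = "." if r.concurrent_cn is None else str(r.concurrent_cn)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tLOH\t"
                f"{r.n_adjusted_hom_sites}\t{r.n_persistent_het_sites}\t{cn}\n"
            )
    with open(paths["dmr_bed"], "w") as fh:
        for d in dmrs:
            iv = d.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.direction}\t"
                f"{d.tumor_fraction:.6f}\t{d.control_fraction:.6f}\t{d.difference_pp:.4f}\n"
            )
    return paths


def read_calls(out_dir: str | os.PathLike) -> tuple[list[CnvCall], list[LohRegion], list[DmrCall]]:
    """Read back a call-set directory written by :func:`write_calls`."""
    out_dir = Path(out_dir)
    cnvs: list[CnvCall] = []
    lohs: list[LohRegion] = []
    with open(out_dir / "cnv_loh.vcf") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, _ref, alt, _q, _f, info = line.rstrip("\n").split("\t")
            kv = dict(
                item.split("=", 1) if "=" in item else (item, "1")
                for item in info.split(";")
            )
            iv = GenomicInterval(chrom, int(pos) - 1, int(kv["END"]))
            if kv["SVTYPE"] == "LOH":
                cn = int(kv["CN"]) if "CN" in kv else None
                lohs.append(
                    LohRegion(iv, int(kv["HOMSITES"]), int(kv["HETSITES"]), cn)
                )
            else:
                cnvs.append(
                    CnvCall(
                        iv,
                        observed_cn=float(kv["OBSCN"]),
                        calibrated_cn=int(kv["CN"]),
                        cnv_type=kv["SVTYPE"],
                        somatic=kv.get("SOMATIC") == "1",
                    )
                )
    dmrs: list[DmrCall] = []
    with open(out_dir / "dmr.bed") as fh:
        for line in fh:
            chrom, start, end, direction, tf, cf, diff = line.rstrip("\n").split("\t")
            dmrs.append(
                DmrCall(
                    GenomicInterval(chrom, int(start), int(end)),
                    float(tf),
                    float(cf),
                    float(diff),
                    direction,
                )
            )
    return cnvs, lohs, dmrs
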
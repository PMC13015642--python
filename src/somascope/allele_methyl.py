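"""Allele-specific methylation over a configured gene panel.

For each gene (padded by 2 kb to include promoter sequence) the four
haplotype series — tumor H1/H2 and normal H1/H2 — are summarized into
methylation windows and compared all-vs-all (six unordered pairs).
Within-sample pairs test allele-specific methylation; cross-sample pairs
report haplotype-resolved tumor-normal change. A series backed by too
few haplotagged calls is not assessable, which is exactly the signature
of an allele lost to LoH: the allele is present in the normal but few
reads support it in the tumor.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval
from .io import MethylSiteRecord
from .methylation import DEFAULT_THRESHOLD_PP, WindowTrack, summarize_windows

DEFAULT_PADDING_BP = 2_000
DEFAULT_MIN_SUPPORT = 5

SERIES_LABELS = ("tumor_H1", "tumor_H2", "normal_H1", "normal_H2")
WITHIN_SAMPLE_PAIRS = {("tumor_H1", "tumor_H2"), ("normal_H1", "normal_H2")}


@dataclass(frozen=True)
class HaplotypeMethylSeries:
    """Windowed methylation of one haplotype of one sample over one gene."""

    sample: str  # tumor | normal
    haplotype: str  # H1 | H2
    gene: str
    interval: GenomicInterval  # gene +- padding
    windows: WindowTrack
    read_support: int

    @property
    def label(self) -> str:
        return f"{self.sample}_{self.haplotype}"


@dataclass(frozen=True)
class AsmResult:
    gene: str
    pair: tuple[str, str]
    max_difference_pp: float
    asm_flag: bool
    assessable: bool

    def __post_init__(self) -> None:
        if self.asm_flag and not self.assessable:
            raise ValueError("asm_flag requires an assessable pair")


def build_gene_series(
    tagged_sites: Mapping[tuple[str, str], Sequence[MethylSiteRecord]],
    gene_intervals: Mapping[str, GenomicInterval],
    padding_bp: int = DEFAULT_PADDING_BP,
    window_bp: int = 1_000,
    min_valid: int = 1,
) -> dict[str, list[HaplotypeMethylSeries]]:
    """Build per-(sample, haplotype, gene) methylation series.

    ``tagged_sites`` maps (sample, haplotype) — e.g. ("tumor", "H1") — to
    haplotagged CpG records; unphased records must already be excluded.
    Each gene interval is padded on both sides (clamped at the chromosome
    start) and windowed at ``window_bp`` (finer than the genome-wide
    10 kb grid; genes are short). Read support is the median valid-call
    count per CpG inside the gene, a proxy for haplotagged read depth.
    """
    if not gene_intervals:
        raise ValueError("gene panel is empty")
    out: dict[str, list[HaplotypeMethylSeries]] = {g: [] for g in gene_intervals}
    for gene, iv in gene_intervals.items():
        padded = iv.padded(padding_bp)
        for (sample, hap), sites in tagged_sites.items():
            inside = [
                s for s in sites
                if s.chrom == padded.chrom and padded.start <= s.pos < padded.end
            ]
            windows = summarize_windows(inside, window_bp=window_bp, min_valid=min_valid)
            support = int(np.median([s.n_valid for s in inside])) if inside else 0
            out[gene].append(
                HaplotypeMethylSeries(sample, hap, gene, padded, windows, support)
            )
    return out


def asm_compare(
    series: Sequence[HaplotypeMethylSeries],
    threshold_pp: float = DEFAULT_THRESHOLD_PP,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[AsmResult]:
    """All-vs-all comparison of the (up to four) haplotype series of one gene.

    Every unordered pair is compared window-wise; a pair's
    ``max_difference_pp`` is the largest absolute window difference over
    windows defined in both series. ``asm_flag`` is raised only for
    within-sample pairs exceeding the threshold. A pair involving a
    series below the read-support floor — or with no comparable window —
    is reported not assessable.
    """
    if not series:
        return []
    gene = series[0].gene
    by_label = {s.label: s for s in series}
    results: list[AsmResult] = []
    for la, lb in combinations(sorted(by_label), 2):
        a, b = by_label[la], by_label[lb]
        assessable = a.read_support >= min_support and b.read_support >= min_support
        max_diff = 0.0
        if assessable:
            common = [
                k for k in a.windows.keys() & b.windows.keys()
                if a.windows[k].fraction is not None and b.windows[k].fraction is not None
            ]
            if not common:
                assessable = False
            else:
                max_diff = max(
                    abs(a.windows[k].fraction - b.windows[k].fraction) * 100.0
                    for k in common
                )
        pair = tuple(sorted((la, lb)))
        within = pair in WITHIN_SAMPLE_PAIRS
        flag = bool(assessable and within and max_diff >= threshold_pp)
        results.append(AsmResult(gene, pair, max_diff, flag, assessable))
    return results
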
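"""Somatic CNV and LoH calling from binned coverage and SNV allele fractions.

Coverage is reduced to a tumor/normal depth-ratio track, segmented by
binary segmentation on the log2 ratio, and segments are converted to
purity-calibrated integer copy numbers. LoH regions are found as runs of
germline-heterozygous sites whose tumor allele fractions sit in the
purity-adjusted homozygous bands.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex
from .io import CnvCall, CoverageBin, LohRegion, SnvSite
from .purity import PurityModel, calibrate_tumor_cn, classify_site

logger = logging.getLogger(__name__)

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

# reported CNV size floors: paired mode and tumor-only prioritization
MIN_CNV_BP = 100_000
TUMOR_ONLY_MIN_BP = 1_000_000


@dataclass(frozen=True)
class RatioBin:
    interval: GenomicInterval
    ratio: float


@dataclass(frozen=True)
class RatioSegment:
    """A run of coverage bins with homogeneous tumor/normal depth ratio."""

    interval: GenomicInterval
    mean_ratio: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("segment must cover at least one bin")
        if self.mean_ratio <= 0:
            raise ValueError("segment mean ratio must be positive")


# ---------------------------------------------------------------------------
# ratio track
# ---------------------------------------------------------------------------

def normalize_ratio(
    tumor: Sequence[CoverageBin],
    normal: Sequence[CoverageBin],
    blacklist: Sequence[GenomicInterval] | None = None,
) -> list[RatioBin]:
    """Median-normalized tumor/normal depth ratio per bin.

    Both tracks must share the bin grid. Blacklisted bins and bins with
    zero normal depth are removed. Each ratio is
    (tumor depth / tumor median) / (normal depth / normal median), so a
    flat diploid genome sits at ratio ~= 1 regardless of total yield.
    """
    if len(tumor) != len(normal):
        raise ValueError(
            f"coverage tracks have different bin counts ({len(tumor)} vs {len(normal)})"
        )
    for tb, nb in zip(tumor, normal):
        if tb.interval != nb.interval:
            raise ValueError(
                f"coverage bin grids disagree at {tb.interval} vs {nb.interval}"
            )
    t_depth = np.array([b.mean_depth for b in tumor])
    n_depth = np.array([b.mean_depth for b in normal])
    t_med = float(np.median(t_depth))
    n_med = float(np.median(n_depth))
    if t_med <= 0 or n_med <= 0:
        raise ValueError("median depth is zero; cannot normalize")

    index = IntervalIndex(blacklist) if blacklist else None
    out: list[RatioBin] = []
    removed = 0
    for tb, nb in zip(tumor, normal):
        iv = tb.interval
        if nb.mean_depth <= 0 or (
            index is not None and index.overlaps_any(iv.chrom, iv.start, iv.end)
        ):
            removed += 1
            continue
        ratio = (tb.mean_depth / t_med) / (nb.mean_depth / n_med)
        if ratio <= 0:
            removed += 1
            continue
        out.append(RatioBin(iv, ratio))
    if len(tumor) and removed > 0.5 * len(tumor):
        logger.warning(
            "normalize_ratio removed %d of %d bins (>50%%)", removed, len(tumor)
        )
    return out


def tumor_only_ratio(tumor: Sequence[CoverageBin],
                     blacklist: Sequence[GenomicInterval] | None = None) -> list[RatioBin]:
    """Ratio track without a matched normal: depth over its genome-wide median."""
    depths = np.array([b.mean_depth for b in tumor])
    med = float(np.median(depths))
    if med <= 0:
        raise ValueError("median depth is zero; cannot normalize")
    index = IntervalIndex(blacklist) if blacklist else None
    out = []
    for b in tumor:
        iv = b.interval
        if b.mean_depth <= 0:
            continue
        if index is not None and index.overlaps_any(iv.chrom, iv.start, iv.end):
            continue
        out.append(RatioBin(iv, b.mean_depth / med))
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _sse(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squared deviations for y[i:j] via prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    sq = prefix_sq[j] - prefix_sq[i]
    return sq - s * s / n


def _best_split(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> tuple[int, float]:
    """Best single breakpoint k in (i, j) and its SSE reduction."""
    n = j - i
    if n < 2:
        return -1, 0.0
    ks = np.arange(i + 1, j)
    ls = prefix[ks] - prefix[i]
    lq = prefix_sq[ks] - prefix_sq[i]
    ln = ks - i
    rs = prefix[j] - prefix[ks]
    rq = prefix_sq[j] - prefix_sq[ks]
    rn = j - ks
    cost = (lq - ls * ls / ln) + (rq - rs * rs / rn)
    total = _sse(prefix, prefix_sq, i, j)
    best = int(np.argmin(cost))
    return int(ks[best]), float(total - cost[best])


def estimate_noise_sd(log_ratio: np.ndarray) -> float:
    """Per-bin noise SD from the scaled MAD of bin-to-bin log2 differences.

    Differencing removes slow copy-number structure; the MAD is scaled to
    be consistent for Gaussian noise and divided by sqrt(2) because a
    difference of two independent bins doubles the variance.
    """
    if len(log_ratio) < 3:
        return 0.0
    d = np.diff(log_ratio)
    mad = float(np.median(np.abs(d - np.median(d))))
    return mad * 1.4826 / math.sqrt(2.0)


def segment_ratio(
    track: Sequence[RatioBin],
    min_segment_bp: int = MIN_CNV_BP,
    penalty: Optional[float] = None,
) -> list[RatioSegment]:
    """Segment the log2 ratio track by recursive binary splitting.

    A split is accepted only when it reduces the within-segment sum of
    squared deviations of log2(ratio) by more than ``penalty`` (default
    10 * estimated noise variance). Segments shorter than
    ``min_segment_bp`` are merged into the neighbor with the nearest
    mean. Chromosomes are processed independently, in order of first
    appearance; no segment crosses a chromosome boundary.
    """
    if not track:
        return []
    by_chrom: dict[str, list[RatioBin]] = {}
    for b in track:
        by_chrom.setdefault(b.interval.chrom, []).append(b)

    out: list[RatioSegment] = []
    for chrom, bins in by_chrom.items():
        bins.sort(key=lambda b: b.interval.start)
        y = np.log2(np.array([b.ratio for b in bins]))
        pen = penalty
        if pen is None:
            sigma = estimate_noise_sd(y)
            pen = 10.0 * sigma * sigma
        prefix = np.concatenate(([0.0], np.cumsum(y)))
        prefix_sq = np.concatenate(([0.0], np.cumsum(y * y)))

        boundaries = [0, len(bins)]
        stack = [(0, len(bins))]
        while stack:
            i, j = stack.pop()
            k, reduction = _best_split(prefix, prefix_sq, i, j)
            if k >= 0 and reduction > pen:
                boundaries.append(k)
                stack.append((i, k))
                stack.append((k, j))
        boundaries = sorted(set(boundaries))

        # merge sub-minimum segments into the nearest-mean neighbor
        segs = [
            [boundaries[idx], boundaries[idx + 1]]
            for idx in range(len(boundaries) - 1)
        ]

        def seg_len(s: list[int]) -> int:
            return bins[s[1] - 1].interval.end - bins[s[0]].interval.start

        def seg_mean(s: list[int]) -> float:
            return float((prefix[s[1]] - prefix[s[0]]) / (s[1] - s[0]))

        while len(segs) > 1:
            lengths = [seg_len(s) for s in segs]
            shortest = int(np.argmin(lengths))
            if lengths[shortest] >= min_segment_bp:
                break
            candidates = []
            if shortest > 0:
                candidates.append(shortest - 1)
            if shortest < len(segs) - 1:
                candidates.append(shortest + 1)
            target = min(
                candidates,
                key=lambda c: abs(seg_mean(segs[c]) - seg_mean(segs[shortest])),
            )
            lo, hi = min(shortest, target), max(shortest, target)
            segs[lo] = [segs[lo][0], segs[hi][1]]
            del segs[hi]

        for s in segs:
            iv = GenomicInterval(chrom, bins[s[0]].interval.start, bins[s[1] - 1].interval.end)
            mean_ratio = float(np.mean([bins[t].ratio for t in range(s[0], s[1])]))
            out.append(RatioSegment(iv, mean_ratio, s[1] - s[0]))
    return out


# ---------------------------------------------------------------------------
# CNV calls
# ---------------------------------------------------------------------------

def call_cnv(
    segments: Sequence[RatioSegment],
    model: PurityModel,
    neutral_band: float = 0.1,
    min_size_bp: int = MIN_CNV_BP,
    somatic: bool = True,
) -> list[CnvCall]:
    """Convert ratio segments into purity-calibrated CNV calls.

    observed_cn = mean ratio x normal ploidy; segments whose calibrated
    copy number equals the normal ploidy, whose |log2 ratio| falls inside
    ``neutral_band``, or whose span is below ``min_size_bp`` emit no call.
    """
    calls: list[CnvCall] = []
    for seg in segments:
        if seg.interval.length < min_size_bp:
            continue
        if abs(math.log2(seg.mean_ratio)) <= neutral_band:
            continue
        observed = seg.mean_ratio * model.normal_ploidy
        calibrated = calibrate_tumor_cn(model, observed)
        if calibrated == model.normal_ploidy:
            continue
        cnv_type = "DEL" if calibrated < model.normal_ploidy else "DUP"
        calls.append(CnvCall(seg.interval, observed, calibrated, cnv_type, somatic))
    return calls


# ---------------------------------------------------------------------------
# LoH detection
# ---------------------------------------------------------------------------

def _scan_runs(
    positions: list[int],
    labels: list[str],
    min_sites: int,
    max_het_frac: float,
    max_ambiguous_frac: float = 0.5,
    max_gap_sites: int = 10,
) -> list[tuple[int, int, int, int]]:
    """Scan classified sites for maximal LoH runs.

    Returns (start_pos, end_pos, n_hom, n_het) tuples; positions are the
    first/last adjusted-hom supporting sites. Persistent hets interrupt
    subject to ``max_het_frac``; ambiguous sites are tolerated up to
    ``max_ambiguous_frac`` of the run (a stretch dominated by
    unclassifiable fractions — e.g. inside an unrelated CNV — is not LoH
    evidence), and a run also closes after ``max_gap_sites`` consecutive
    non-supporting sites, which stops a long run from drifting past the
    true boundary on trailing noise. A run closes when adding the next
    interrupter would violate a cap.
    """
    runs: list[tuple[int, int, int, int]] = []
    hom_positions: list[int] = []
    n_het = 0
    n_amb = 0
    gap = 0

    def close() -> None:
        nonlocal hom_positions, n_het, n_amb, gap
        if len(hom_positions) >= min_sites:
            runs.append((hom_positions[0], hom_positions[-1], len(hom_positions), n_het))
        hom_positions = []
        n_het = 0
        n_amb = 0
        gap = 0

    for pos, lab in zip(positions, labels):
        if lab in ("hom_alt_adjusted", "hom_ref_adjusted"):
            hom_positions.append(pos)
            gap = 0
            continue
        if not hom_positions:
            continue
        if gap + 1 > max_gap_sites:
            close()
            continue
        if lab == "het":
            if (n_het + 1) / (len(hom_positions) + n_het + 1) > max_het_frac:
                close()
            else:
                n_het += 1
                gap += 1
        else:  # ambiguous
            total = len(hom_positions) + n_het + n_amb + 1
            if (n_amb + 1) / total > max_ambiguous_frac:
                close()
            else:
                n_amb += 1
                gap += 1
    close()
    return runs


def detect_loh(
    normal_snvs: Optional[Sequence[SnvSite]],
    tumor_snvs: Sequence[SnvSite],
    model: PurityModel,
    min_sites: int = 25,
    max_het_frac: float = 0.15,
    min_size_bp: int = MIN_CNV_BP,
    tolerance: float = 0.10,
    include_sex_chroms: bool = False,
) -> list[LohRegion]:
    """Detect LoH regions from VAF shifts at germline-heterozygous sites.

    Paired mode: sites heterozygous in the normal (genotype het and AF in
    [0.30, 0.70]) are matched by position and classified in the tumor via
    the purity model; maximal runs of adjusted-homozygous sites with at
    most ``max_het_frac`` persistent hets become regions. Tumor-only mode
    (``normal_snvs is None``) classifies the tumor's own sites and raises
    the size floor to 1 Mb. Sex chromosomes are excluded by default.
    """
    if normal_snvs is None:
        min_size_bp = max(min_size_bp, TUMOR_ONLY_MIN_BP)
        candidates = [
            s for s in tumor_snvs
            if include_sex_chroms or s.chrom not in SEX_CHROMS
        ]
        tumor_at = {(s.chrom, s.pos): s for s in candidates}
        seeds = sorted(tumor_at, key=lambda k: (k[0], k[1]))
    else:
        tumor_at = {(s.chrom, s.pos): s for s in tumor_snvs}
        seeds = []
        for s in sorted(normal_snvs, key=lambda s: (s.chrom, s.pos)):
            if not include_sex_chroms and s.chrom in SEX_CHROMS:
                continue
            if s.genotype == "het" and 0.30 <= s.allele_fraction <= 0.70:
                if (s.chrom, s.pos) in tumor_at:
                    seeds.append((s.chrom, s.pos))
        if not seeds:
            logger.warning("detect_loh: no shared germline-het sites between samples")
            return []

    regions: list[LohRegion] = []
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos in seeds:
        site = tumor_at[(chrom, pos)]
        label = classify_site(model, site, tolerance=tolerance).label
        by_chrom.setdefault(chrom, []).append((pos, label))

    for chrom, items in by_chrom.items():
        positions = [p for p, _ in items]
        labels = [l for _, l in items]
        for start_pos, end_pos, n_hom, n_het in _scan_runs(
            positions, labels, min_sites, max_het_frac
        ):
            # VCF-style 1-based sites to half-open interval
            iv = GenomicInterval(chrom, start_pos - 1, end_pos)
            if iv.length < min_size_bp:
                continue
            regions.append(LohRegion(iv, n_hom, n_het))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def annotate_concurrent_cn(
    lohs: Sequence[LohRegion], cnvs: Sequence[CnvCall]
) -> list[LohRegion]:
    """Fill ``concurrent_cn`` where a CNV call overlaps an LoH region."""
    out = []
    for r in lohs:
        cn = None
        best = 0
        for c in cnvs:
            ov = r.interval.overlap_bp(c.interval)
            if ov > best:
                best = ov
                cn = c.calibrated_cn
        out.append(LohRegion(r.interval, r.n_adjusted_hom_sites, r.n_persistent_het_sites, cn))
    return out


# ---------------------------------------------------------------------------
# benchmark matching
# ---------------------------------------------------------------------------

def match_calls(
    truth: Sequence[GenomicInterval],
    calls: Sequence[GenomicInterval],
    min_overlap_frac: float = 0.7,
) -> tuple[pd.DataFrame, float]:
    """Match truth intervals to calls at a minimum overlap fraction.

    A truth interval is matched when some single call covers at least
    ``min_overlap_frac`` of the truth interval's length (fraction
    measured on the truth side, boundary inclusive). Returns the match
    table and recall = matched / total truth.
    """
    rows = []
    matched = 0
    for t in truth:
        best_ov = 0
        best_call = None
        for c in calls:
            ov = t.overlap_bp(c)
            if ov > best_ov:
                best_ov = ov
                best_call = c
        frac = best_ov / t.length
        hit = frac >= min_overlap_frac
        matched += hit
        rows.append(
            {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "best_call": f"{best_call.chrom}:{best_call.start}-{best_call.end}"
                if best_call
                else ".",
                "overlap_frac": frac,
                "matched": hit,
            }
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "best_call", "overlap_frac", "matched"]
    )
    recall = matched / len(truth) if truth else float("nan")
    return table, recall
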
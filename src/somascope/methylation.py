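"""Windowed methylation summarization and tumor-vs-control differential calling.

Per-CpG modified/valid counts are pooled into fixed non-overlapping
windows (default 10 kb, anchored at coordinate 0 per chromosome). A
window's methylated fraction is pooled modified calls over pooled valid
calls — robust to uneven per-site depth. Differential calls use a
percentage-point threshold calibrated on a cohort of normals so that
same-tissue inter-individual comparisons yield roughly a target number
of candidate windows.
"""
from __future__ import annotations


from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval
from .io import DmrCall, MethylSiteRecord

DEFAULT_WINDOW_BP = 10_000
DEFAULT_THRESHOLD_PP = 33.0
DEFAULT_MIN_VALID = 5
HIGH_CUT = 0.90
LOW_CUT = 0.10


@dataclass(frozen=True)
class MethylWindow:
    """Pooled methylation counts over one fixed window.

    ``fraction`` is None (missing) when ``n_valid`` is below the
    assessability floor; such windows are never compared.
    """

    interval: GenomicInterval
    n_valid: int
    n_modified: int
    fraction: Optional[float]


@dataclass(frozen=True)
class MethylClass:
    label: str  # high | low | intermediate


WindowTrack = dict[tuple[str, int], MethylWindow]  # keyed by (chrom, window start)


def summarize_windows(
    sites: Iterable[MethylSiteRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    min_valid: int = DEFAULT_MIN_VALID,
) -> WindowTrack:
    """Pool per-CpG counts into fixed non-overlapping windows.

    Windows are anchored at coordinate 0 on each chromosome. The
    methylated fraction is defined only when the pooled valid-call count
    reaches ``min_valid``.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for s in sites:
        wstart = (s.pos // window_bp) * window_bp
        acc = counts.setdefault((s.chrom, wstart), [0, 0])
        acc[0] += s.n_valid
        acc[1] += s.n_modified
    track: WindowTrack = {}
    for (chrom, wstart), (n_valid, n_mod) in counts.items():
        frac = n_mod / n_valid if n_valid >= min_valid and n_valid > 0 else None
        track[(chrom, wstart)] = MethylWindow(
            GenomicInterval(chrom, wstart, wstart + window_bp), n_valid, n_mod, frac
        )
    return track


def _check_grid(a: WindowTrack, b: WindowTrack) -> None:
    wa = {w.interval.length for w in a.values()}
    wb = {w.interval.length for w in b.values()}
    if wa and wb and wa != wb:
        raise ValueError(f"window grids disagree: widths {sorted(wa)} vs {sorted(wb)}")


def call_cdmr(
    tumor: WindowTrack,
    control: WindowTrack,
    threshold_pp: float = DEFAULT_THRESHOLD_PP,
    min_valid: int = DEFAULT_MIN_VALID,
) -> list[DmrCall]:
    """Cancer differentially methylated regions between tumor and control.

    A window is called when both fractions are defined (valid-call floor
    met on both sides) and the absolute difference reaches
    ``threshold_pp`` percentage points — boundary inclusive.
    """
    _check_grid(tumor, control)
    calls: list[DmrCall] = []
    for key in tumor.keys() & control.keys():
        tw, cw = tumor[key], control[key]
        if tw.fraction is None or cw.fraction is None:
            continue
        if tw.n_valid < min_valid or cw.n_valid < min_valid:
            continue
        diff_pp = (tw.fraction - cw.fraction) * 100.0
        if abs(diff_pp) >= threshold_pp:
            direction = "hyper_in_tumor" if diff_pp > 0 else "hypo_in_tumor"
            calls.append(DmrCall(tw.interval, tw.fraction, cw.fraction, diff_pp, direction))
    calls.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return calls


def calibrate_threshold(
    cohort: Sequence[WindowTrack],
    target_count: float = 50.0,
) -> int:
    """Smallest integer pp threshold giving at most ``target_count`` windows per pair.

    All N(N-1)/2 unordered pairs of cohort samples are compared; for each
    integer threshold t in 0..100 the mean per-pair count of windows with
    |difference| >= t pp is computed, and the smallest t whose mean count
    is <= ``target_count`` is returned. Emulates picking the threshold at
    which same-tissue different-individual comparisons leave only a
    handful of candidate regions.
    """
    if len(cohort) < 2:
        raise ValueError("threshold calibration needs at least two samples")
    for other in cohort[1:]:
        _check_grid(cohort[0], other)

    diffs: list[np.ndarray] = []
    for a, b in combinations(cohort, 2):
        vals = [
            abs(a[k].fraction - b[k].fraction) * 100.0
            for k in a.keys() & b.keys()
            if a[k].fraction is not None and b[k].fraction is not None
        ]
        diffs.append(np.array(vals))
    n_pairs = len(diffs)
    for t in range(0, 101):
        mean_count = sum(int(np.sum(d >= t)) for d in diffs) / n_pairs
        if mean_count <= target_count:
            return t
    return 100


def classify_extreme(
    windows: WindowTrack,
    high_cut: float = HIGH_CUT,
    low_cut: float = LOW_CUT,
) -> dict[tuple[str, int], MethylClass]:
    """Per-window extreme-methylation classification (tumor-only assessment).

    fraction >= ``high_cut`` -> high; fraction <= ``low_cut`` -> low;
    otherwise intermediate. Both cuts inclusive. Windows with an
    undefined fraction are skipped (unassessed).
    """
    out: dict[tuple[str, int], MethylClass] = {}
    for key, w in windows.items():
        if w.fraction is None:
            continue
        if w.fraction >= high_cut:
            out[key] = MethylClass("high")
        elif w.fraction <= low_cut:
            out[key] = MethylClass("low")
        else:
            out[key] = MethylClass("intermediate")
    return out


def panel_reference(
    panel: Sequence[WindowTrack],
    min_defined: int = 3,
) -> WindowTrack:
    """Panel-of-normals reference: per-window median of defined fractions.

    A window enters the reference only when at least ``min_defined``
    panel samples define it (or all of them, for panels smaller than the
    floor). Even-count medians are the mean of the two central values.
    """
    if not panel:
        raise ValueError("panel must contain at least one sample")
    floor = min(min_defined, len(panel))
    keys = set()
    for track in panel:
        keys |= track.keys()
    out: WindowTrack = {}
    for key in keys:
        fracs = [
            t[key].fraction for t in panel if key in t and t[key].fraction is not None
        ]
        if len(fracs) < floor:
            continue
        med = float(np.median(fracs))
        iv = next(t[key].interval for t in panel if key in t)
        # counts synthesized to keep the track shape; fraction carries the signal
        out[key] = MethylWindow(iv, n_valid=len(fracs), n_modified=0, fraction=med)
    return out


def constitutive_regions(
    per_sample_calls: Sequence[Sequence[DmrCall]],
    direction: str = "hyper_in_tumor",
) -> list[GenomicInterval]:
    """Windows called with the given direction in every sample of a cohort."""
    if not per_sample_calls:
        raise ValueError("cohort of call sets is empty")
    sets = []
    intervals: dict[tuple[str, int], GenomicInterval] = {}
    for calls in per_sample_calls:
        s = set()
        for c in calls:
            if c.direction == direction:
                key = (c.interval.chrom, c.interval.start)
                s.add(key)
                intervals[key] = c.interval
        sets.append(s)
    common = set.intersection(*sets) if sets else set()
    return sorted((intervals[k] for k in common), key=lambda iv: (iv.chrom, iv.start))
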
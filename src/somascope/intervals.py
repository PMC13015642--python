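"""Genomic interval primitives.

All in-memory coordinates in this package are 0-based half-open
(BED convention). Conversion to 1-based happens only at the VCF boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def padded(self, padding: int) -> "GenomicInterval":
        """Expand by `padding` bp each side, clamped at the chromosome start."""
        return GenomicInterval(self.chrom, max(0, self.start - padding), self.end + padding)


class IntervalIndex:
    """Overlap queries against a fixed set of intervals, per chromosome.

    Backed by sorted numpy arrays; sufficient for blacklist/gene-panel
    lookups without an external interval-tree dependency.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            # running max of ends supports overlap queries on possibly
            # nested intervals with one searchsorted
            ends = np.maximum.accumulate(np.array([p[1] for p in pairs], dtype=np.int64))
            self._starts[chrom] = starts
            self._ends[chrom] = ends

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        ends = self._ends[chrom]
        i = np.searchsorted(starts, end, side="left")  # intervals starting before `end`
        if i == 0:
            return False
        return bool(ends[i - 1] > start)

    def overlaps_mask(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized overlap test for parallel start/end arrays on one chromosome."""
        bstarts = self._starts.get(chrom)
        if bstarts is None:
            return np.zeros(len(starts), dtype=bool)
        bends = self._ends[chrom]
        idx = np.searchsorted(bstarts, ends, side="left")
        mask = idx > 0
        safe = np.where(mask, idx - 1, 0)
        return mask & (bends[safe] > starts)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals; output sorted by (chrom, start)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out
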
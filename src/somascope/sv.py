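"""Somatic structural-variant subtraction and tumor-only prioritization.

Paired mode: tumor SVs with no matching normal SV (same type, breakpoints
within a distance cap, similar size) are somatic. Tumor-only mode: SVs
absent from a population-presence annotation are pseudo-somatic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .io import SvRecord

DEFAULT_BREAKPOINT_DIST = 1_000
DEFAULT_SIZE_SIMILARITY = 0.7


@dataclass(frozen=True)
class SvMatchConfig:
    max_breakpoint_dist: int = DEFAULT_BREAKPOINT_DIST
    require_same_type: bool = True
    min_size_similarity: float = DEFAULT_SIZE_SIMILARITY

    def __post_init__(self) -> None:
        if self.max_breakpoint_dist < 0:
            raise ValueError("breakpoint distance must be >= 0")
        if not 0 < self.min_size_similarity <= 1:
            raise ValueError("size similarity must be in (0, 1]")


@dataclass
class SomaticSvReport:
    somatic: list[SvRecord]
    shared: list[SvRecord]
    normal_only_count: int


@dataclass
class PseudoSomaticReport:
    pseudo_somatic: list[SvRecord]
    in_population: list[SvRecord]
    unknown: list[SvRecord]


def _interval(rec: SvRecord) -> Optional[tuple[int, int]]:
    """Affected reference interval when both ends are known (DEL/DUP/INV)."""
    if rec.sv_type in ("DEL", "DUP", "INV") and rec.length != 0:
        return rec.pos, rec.pos + abs(rec.length)
    return None


def match_sv(a: SvRecord, b: SvRecord, cfg: SvMatchConfig = SvMatchConfig()) -> bool:
    """Do two SV records describe the same event?

    Base rule: same chromosome, breakpoints within
    ``max_breakpoint_dist`` (inclusive), same type when required, and
    size similarity min(|len|)/max(|len|) at least
    ``min_size_similarity``. The size check is skipped for BND. For
    DEL/DUP/INV whose spans dwarf the breakpoint-distance cap (> 10x),
    reciprocal interval overlap at the similarity fraction also
    satisfies the match — large events jitter more at the breakpoint
    than they move as intervals. Insertions are judged by position and
    length only.
    """
    if a.chrom != b.chrom:
        return False
    if cfg.require_same_type and a.sv_type != b.sv_type:
        return False
    size_ok = True
    if a.sv_type != "BND" and b.sv_type != "BND":
        la, lb = abs(a.length), abs(b.length)
        if max(la, lb) > 0:
            size_ok = min(la, lb) / max(la, lb) >= cfg.min_size_similarity
    if abs(a.pos - b.pos) <= cfg.max_breakpoint_dist and size_ok:
        return True
    # secondary path: reciprocal overlap of the affected intervals,
    # restricted to events much larger than the breakpoint-distance cap
    ia, ib = _interval(a), _interval(b)
    if (
        ia is not None
        and ib is not None
        and min(abs(a.length), abs(b.length)) > 10 * cfg.max_breakpoint_dist
    ):
        ov = max(0, min(ia[1], ib[1]) - max(ia[0], ib[0]))
        if ov > 0:
            frac = ov / max(ia[1] - ia[0], ib[1] - ib[0])
            if frac >= cfg.min_size_similarity:
                return True
    return False


def subtract_somatic(
    tumor: Sequence[SvRecord],
    normal: Sequence[SvRecord],
    cfg: SvMatchConfig = SvMatchConfig(),
) -> SomaticSvReport:
    """Partition tumor SVs into somatic (tumor-only) and shared (germline).

    Matching is greedy nearest-first on breakpoint distance, each normal
    record consumable once. |somatic| + |shared| = |tumor| always.
    """
    pairs: list[tuple[int, int, int]] = []  # (distance, tumor idx, normal idx)
    for i, t in enumerate(tumor):
        for j, n in enumerate(normal):
            if match_sv(t, n, cfg):
                pairs.append((abs(t.pos - n.pos), i, j))
    pairs.sort()
    matched_t: set[int] = set()
    matched_n: set[int] = set()
    for _, i, j in pairs:
        if i in matched_t or j in matched_n:
            continue
        matched_t.add(i)
        matched_n.add(j)
    somatic = [t for i, t in enumerate(tumor) if i not in matched_t]
    shared = [t for i, t in enumerate(tumor) if i in matched_t]
    return SomaticSvReport(somatic, shared, len(normal) - len(matched_n))


def classify_pseudo_somatic(
    tumor: Sequence[SvRecord],
    population: Mapping[tuple[str, int, str, int], int],
) -> PseudoSomaticReport:
    """Tumor-only prioritization against a population-presence annotation.

    Records with zero population hits are pseudo-somatic; records seen in
    the population are excluded; records the annotation cannot resolve
    are labeled unknown and conservatively kept out of the
    pseudo-somatic set.
    """
    pseudo: list[SvRecord] = []
    known: list[SvRecord] = []
    unknown: list[SvRecord] = []
    for rec in tumor:
        hits = rec.population_hits
        if hits is None:
            hits = population.get(rec.key())
        if hits is None:
            unknown.append(rec)
        elif hits == 0:
            pseudo.append(rec)
        else:
            known.append(rec)
    return PseudoSomaticReport(pseudo, known, unknown)
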
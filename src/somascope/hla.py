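"""HLA loss-of-heterozygosity scoring from per-allele read counts.

Upstream typing assigns each of the classical HLA genes two alleles at
two-field resolution; reads from tumor and normal are re-mapped to the
two allele references and counted. Under copy-neutral LoH at purity p
the lost allele keeps its one normal-compartment copy while the retained
allele carries 2p + (1 - p) copies, so the lost-allele read fraction
shifts from 1/2 toward (1 - p) / 2. The allele-ratio difference between
tumor and normal is the LoH score.
"""
from __future__ import annotations


from dataclasses import dataclass
from typing import Mapping, Optional

from scipy.stats import fisher_exact

from .purity import PurityModel

HLA_GENES = (
    "HLA-A", "HLA-B", "HLA-C",
    "HLA-DPA1", "HLA-DPB1", "HLA-DQA1", "HLA-DQB1", "HLA-DRB1",
)

DEFAULT_MIN_TOTAL_READS = 10


def two_field(allele: str) -> str:
    """Truncate an HLA allele name to two-field resolution.

    "HLA-A*03:01:01:02" -> "HLA-A*03:01". Long-read typing is not
    reliable beyond the protein level, so comparisons happen at two
    fields.
    """
    if "*" not in allele:
        return allele
    gene, fields = allele.split("*", 1)
    parts = fields.split(":")
    return f"{gene}*{':'.join(parts[:2])}"


@dataclass(frozen=True)
class HlaAlleleCounts:
    """Per-gene two-allele read counts in tumor and normal."""

    gene: str
    allele1: str
    allele2: str
    normal_counts: tuple[int, int]
    tumor_counts: tuple[int, int]

    def __post_init__(self) -> None:
        for c in (*self.normal_counts, *self.tumor_counts):
            if c < 0:
                raise ValueError("read counts must be non-negative")

    @property
    def germline_homozygous(self) -> bool:
        return two_field(self.allele1) == two_field(self.allele2)


@dataclass(frozen=True)
class HlaLohCall:
    gene: str
    ratio_normal: Optional[float]
    ratio_tumor: Optional[float]
    ratio_difference: Optional[float]
    classification: str  # loh_allele1_lost | loh_allele2_lost | none | germline_homozygous | no_call
    p_value: Optional[float] = None  # auxiliary two-sided Fisher test, not used for classification


def allele_ratio(counts: tuple[int, int]) -> Optional[float]:
    """Fraction of reads supporting allele 1: c1 / (c1 + c2); None when depthless."""
    c1, c2 = counts
    total = c1 + c2
    if total == 0:
        return None
    return c1 / total


def score_hla_loh(
    counts: HlaAlleleCounts,
    model: PurityModel,
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
    delta_cut: Optional[float] = None,
) -> HlaLohCall:
    """Classify HLA LoH from the tumor-vs-normal allele-ratio difference.

    The default decision threshold is p/4 — half the expected full
    copy-neutral-LoH ratio shift of p/2 — so sensitivity scales with the
    stated tumor purity. Germline-homozygous genes short-circuit; genes
    with fewer than ``min_total_reads`` in either sample are no_call.
    """
    if counts.germline_homozygous:
        return HlaLohCall(counts.gene, None, None, None, "germline_homozygous")
    rn = allele_ratio(counts.normal_counts)
    rt = allele_ratio(counts.tumor_counts)
    if (
        rn is None
        or rt is None
        or sum(counts.normal_counts) < min_total_reads
        or sum(counts.tumor_counts) < min_total_reads
    ):
        return HlaLohCall(counts.gene, rn, rt, None, "no_call")
    if delta_cut is None:
        delta_cut = model.purity / 4.0
    delta = rt - rn
    if delta >= delta_cut:
        classification = "loh_allele2_lost"
    elif delta <= -delta_cut:
        classification = "loh_allele1_lost"
    else:
        classification = "none"
    _, p_value = fisher_exact(
        [list(counts.normal_counts), list(counts.tumor_counts)], alternative="two-sided"
    )
    return HlaLohCall(counts.gene, rn, rt, delta, classification, float(p_value))


def tumor_only_homozygosity(typing: Mapping[str, tuple[str, str]]) -> dict[str, bool]:
    """Flag genes typed homozygous at two fields as candidate-LoH hints.

    Without a matched normal, homozygous typing cannot distinguish
    germline homozygosity from somatic allele loss — the flag is a hint,
    never a call.
    """
    return {
        gene: two_field(a1) == two_field(a2)
        for gene, (a1, a2) in typing.items()
    }


def read_hla_counts(path) -> list[HlaAlleleCounts]:
    """Read the per-gene counts TSV: gene, allele1, allele2, n_c1, n_c2, t_c1, t_c2.

    Allele names are truncated to two fields on input.
    """
    out: list[HlaAlleleCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns")
            out.append(
                HlaAlleleCounts(
                    gene=f[0],
                    allele1=two_field(f[1]),
                    allele2=two_field(f[2]),
                    normal_counts=(int(f[3]), int(f[4])),
                    tumor_counts=(int(f[5]), int(f[6])),
                )
            )
    return out


def write_hla_calls(calls, path) -> None:
    """Write HLA LoH calls as TSV with ratios, difference and classification."""
    with open(path, "w") as fh:
        fh.write("gene\tratio_normal\tratio_tumor\tratio_difference\tclassification\tp_value\n")
        for c in calls:
            def fmt(x):
                return "." if x is None else f"{x:.4f}"
            fh.write(
                f"{c.gene}\t{fmt(c.ratio_normal)}\t{fmt(c.ratio_tumor)}\t"
                f"{fmt(c.ratio_difference)}\t{c.classification}\t{fmt(c.p_value)}\n"
            )
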
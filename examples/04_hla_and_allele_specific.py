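"""HLA loss-of-heterozygosity and allele-specific methylation.

Scores HLA-LoH from tumor/normal allele read-count imbalance, and runs
the four-series (tumor H1/H2, normal H1/H2) all-vs-all methylation
comparison over a small gene panel.
"""
from somascope.allele_methyl import asm_compare, build_gene_series
from somascope.hla import HlaAlleleCounts, score_hla_loh, tumor_only_homozygosity
from somascope.intervals import GenomicInterval
from somascope.io import MethylSiteRecord
from somascope.purity import PurityModel

model = PurityModel(0.8)

# --- HLA-LoH from read counts ------------------------------------------
counts = HlaAlleleCounts(
    "HLA-A", "HLA-A*01:01", "HLA-A*24:02",
    normal_counts=(105, 95),   # balanced in the normal
    tumor_counts=(170, 28),    # allele 2 depleted in the tumor
)
call = score_hla_loh(counts, model)
print(f"{call.gene}: normal ratio {call.ratio_normal:.3f}, tumor ratio "
      f"{call.ratio_tumor:.3f}, difference {call.ratio_difference:+.3f} "
      f"-> {call.classification} (p = {call.p_value:.2e})")

# tumor-only: homozygous two-field typing is only a hint, never a call
hints = tumor_only_homozygosity({"HLA-B": ("HLA-B*07:02", "HLA-B*07:02:01")})
print("tumor-only homozygosity hints:", hints)

# --- allele-specific methylation over one gene -------------------------
gene = {"TAP1": GenomicInterval("chr6", 100_000, 110_000)}

def series(fraction):
    return [MethylSiteRecord("chr6", p, round(fraction * 20), 20)
            for p in range(98_000, 112_000, 250)]

tagged = {
    ("tumor", "H1"): series(0.15),   # tumor H1 hypomethylated
    ("tumor", "H2"): series(0.80),
    ("normal", "H1"): series(0.75),
    ("normal", "H2"): series(0.80),
}
results = asm_compare(build_gene_series(tagged, gene)["TAP1"], threshold_pp=33)
for r in sorted(results, key=lambda r: r.pair):
    flag = "ASM" if r.asm_flag else ("ok" if r.assessable else "not assessable")
    print(f"  {r.pair[0]} vs {r.pair[1]}: max |difference| "
          f"{r.max_difference_pp:.0f} pp [{flag}]")

# The tumor H1-vs-H2 pair crosses the 33-pp threshold (allele-specific
# methylation), and the tumor-H1-vs-normal-H1 pair shows the same loss of
# methylation as a haplotype-resolved somatic change.
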
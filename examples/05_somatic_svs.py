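"""Somatic SV subtraction and tumor-only pseudo-somatic prioritization."""
from somascope.io import SvRecord
from somascope.sv import SvMatchConfig, classify_pseudo_somatic, subtract_somatic

tumor = [
    SvRecord("chr1", 100_200, "DEL", -5_000),   # germline (jittered breakpoint)
    SvRecord("chr1", 500_000, "INS", 320),      # somatic
    SvRecord("chr2", 2_000_000, "DUP", 150_000),  # somatic
]
normal = [
    SvRecord("chr1", 100_650, "DEL", -5_100),
    SvRecord("chr3", 900_000, "INV", 40_000),   # normal-only
]

report = subtract_somatic(tumor, normal, SvMatchConfig(max_breakpoint_dist=1000))
print(f"{len(report.somatic)} somatic, {len(report.shared)} shared, "
      f"{report.normal_only_count} normal-only")
for r in report.somatic:
    print(f"  somatic {r.sv_type} {r.chrom}:{r.pos} len {r.length}")

# tumor-only mode: keep only SVs absent from a population catalogue
population = {
    ("chr1", 500_000, "INS", 320): 7,      # seen in 7 population genomes
    ("chr2", 2_000_000, "DUP", 150_000): 0,
}
tonly = classify_pseudo_somatic([tumor[1], tumor[2]], population)
print(f"pseudo-somatic: {[(r.chrom, r.pos) for r in tonly.pseudo_somatic]}, "
      f"in population: {len(tonly.in_population)}")

# The germline DEL is subtracted by breakpoint matching (450 bp apart,
# similar size); without a normal, the population index demotes the INS
# seen in healthy genomes, leaving the DUP as pseudo-somatic.
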
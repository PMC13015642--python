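"""Somatic CNV/LoH calling across an in-silico purity titration.

Simulates a pure tumor with one amplification and one copy-neutral LoH
block, mixes it with its matched normal at decreasing tumor fractions,
and calls events at each level — showing how detection degrades with
normal-cell contamination while the calibrated copy number stays right.
"""
from somascope import cnv_loh
from somascope.purity import PurityModel
from somascope.simulate import TruthEvent, mix_titration, simulate_pair

genome = {f"chr{i}": 5_000_000 for i in range(1, 5)}
truth = [
    TruthEvent("cnv", "chr1", 1_000_000, 3_500_000, cn=4),
    TruthEvent("loh", "chr2", 1_000_000, 3_000_000, retained="alt"),
]
tumor, normal = simulate_pair(truth, PurityModel(1.0), seed=7, genome=genome)

for alpha in (0.9, 0.7, 0.5, 0.3):
    mixed = mix_titration(tumor, normal, alpha, seed=17)
    model = PurityModel(alpha)
    ratio = cnv_loh.normalize_ratio(mixed.coverage, normal.coverage)
    cnvs = cnv_loh.call_cnv(cnv_loh.segment_ratio(ratio), model)
    lohs = cnv_loh.detect_loh(normal.snvs, mixed.snvs, model)
    cnv_desc = ", ".join(
        f"{c.cnv_type} {c.interval.chrom}:{c.interval.start}-{c.interval.end}"
        f" observed CN {c.observed_cn:.2f} calibrated CN {c.calibrated_cn}"
        for c in cnvs
    ) or "none"
    loh_desc = ", ".join(
        f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}"
        f" ({r.n_adjusted_hom_sites} supporting sites)"
        for r in lohs
    ) or "none"
    print(f"tumor fraction {alpha:.1f}")
    print(f"  CNV: {cnv_desc}")
    print(f"  LoH: {loh_desc}")

# The CN=4 call persists down the ladder (its observed CN shrinking toward
# 2 but calibrating back to 4), while LoH detection collapses below 50%
# purity as the shifted allele-fraction bands merge into the het band.
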
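"""Purity-aware copy-number calibration.

A sequenced tumor sample is a mixture of malignant and normal cells, so
the copy number implied by coverage is diluted toward the normal ploidy.
This example shows the forward model and its inverse for the canonical
half-purity case.
"""
from somascope.purity import PurityModel, calibrate_tumor_cn, expected_observed_cn

model = PurityModel(purity=0.5, normal_ploidy=2)

observed = expected_observed_cn(model, cn_tumor=4)
print(f"true tumor CN 4 at 50% purity is observed as CN {observed:.1f}")

recovered = calibrate_tumor_cn(model, observed_cn=3.0)
print(f"inverse calibration of observed CN 3.0 recovers tumor CN {recovered}")

# the observed copy number of a single-copy gain shrinks with purity:
for p in (0.9, 0.7, 0.5, 0.3, 0.1):
    print(f"  purity {p:.1f}: CN 3 event observed as {expected_observed_cn(PurityModel(p), 3):.2f}")

# A CN=4 event in a 50%-pure sample looks like a CN=3 duplication in raw
# coverage; supplying the tumor content recovers the true triplication.
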
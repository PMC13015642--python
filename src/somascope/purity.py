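"""Tumor-purity mixture model.

A sequenced tumor sample is a mixture of malignant cells (fraction ``p``,
the tumor purity or tumor content) and normal cells (fraction ``1 - p``)
at a fixed normal ploidy (2 for autosomes). Observed coverage-implied
copy number and observed variant allele fractions are convex combinations
of the tumor and normal states; this module provides the forward model
and its inverse, used to calibrate observed copy numbers back to true
tumor states and to classify SNV sites after accounting for tumor
content. Example: a true tumor CN of 4 in a 50%-purity sample appears as
observed CN 3 (0.5*4 + 0.5*2); the inverse calibration recovers CN 4.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .io import SnvSite


@dataclass(frozen=True)
class PurityModel:
    """Mixture of malignant (fraction ``purity``) and normal cells.

    Parameters
    ----------
    purity:
        Fraction of malignant cells in the sample, in [0, 1].
    normal_ploidy:
        Copy number of the normal compartment (2 for human autosomes).
    """

    purity: float
    normal_ploidy: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0,1], got {self.purity}")
        if self.normal_ploidy < 1:
            raise ValueError(f"normal ploidy must be >= 1, got {self.normal_ploidy}")


@dataclass(frozen=True)
class SiteClass:
    """Classification of one SNV site after accounting for tumor content."""

    label: str  # het | hom_alt_adjusted | hom_ref_adjusted | ambiguous

    LABELS = ("het", "hom_alt_adjusted", "hom_ref_adjusted", "ambiguous")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ValueError(f"unknown site class {self.label!r}")


def expected_observed_cn(model: PurityModel, cn_tumor: float) -> float:
    """Coverage-implied copy number of a region with true tumor CN ``cn_tumor``.

    observed = p * cn_tumor + (1 - p) * normal_ploidy
    """
    if cn_tumor < 0:
        raise ValueError(f"tumor copy number must be >= 0, got {cn_tumor}")
    p = model.purity
    return p * cn_tumor + (1.0 - p) * model.normal_ploidy


def calibrate_tumor_cn(model: PurityModel, observed_cn: float) -> int:
    """Invert the purity mixture: nearest integer tumor CN for an observed CN.

    Rounding ties (residual exactly .5) round half away from the normal
    ploidy, favoring reporting an event over no event. Result clamped at 0.
    """
    p = model.purity
    if p == 0:
        raise ValueError("tumor content must be positive for calibration")
    raw = (observed_cn - (1.0 - p) * model.normal_ploidy) / p
    frac = raw - math.floor(raw)
    if abs(frac - 0.5) < 1e-9:
        # tie: away from normal ploidy
        cn = math.ceil(raw) if raw > model.normal_ploidy else math.floor(raw)
    else:
        cn = round(raw)
    return max(0, int(cn))


def expected_alt_fraction(
    model: PurityModel,
    alt_copies_tumor: int,
    total_copies_tumor: int,
    alt_copies_normal: int = 1,
    total_copies_normal: int = 2,
) -> float:
    """Observed alt-allele fraction for given allele copy states.

    (p * alt_t + (1-p) * alt_n) / (p * tot_t + (1-p) * tot_n)
    """
    if not 0 <= alt_copies_tumor <= total_copies_tumor:
        raise ValueError("need 0 <= alt copies <= total copies (tumor)")
    if not 0 <= alt_copies_normal <= total_copies_normal:
        raise ValueError("need 0 <= alt copies <= total copies (normal)")
    p = model.purity
    denom = p * total_copies_tumor + (1.0 - p) * total_copies_normal
    if denom == 0:
        raise ValueError("homozygous deletion has no allele fraction")
    return (p * alt_copies_tumor + (1.0 - p) * alt_copies_normal) / denom


def loh_expected_fractions(model: PurityModel, deletion: bool = False) -> tuple[float, float]:
    """Expected VAF bands for (ref-retained, alt-retained) LoH at germline-het sites.

    Copy-neutral LoH keeps two tumor copies of the retained allele
    (default); deletion-LoH keeps one.
    """
    total = 1 if deletion else 2
    ref_retained = expected_alt_fraction(model, 0, total)
    alt_retained = expected_alt_fraction(model, total, total)
    return ref_retained, alt_retained


def classify_site(
    model: PurityModel,
    site: SnvSite,
    tolerance: float = 0.10,
    deletion_loh: bool = False,
) -> SiteClass:
    """Classify a germline-het site in the tumor after purity adjustment.

    Compares the observed allele fraction to three expected bands:
    ref-retained LoH, persistent het (0.5), and alt-retained LoH, and
    returns the nearest band within ``tolerance`` in VAF space, else
    ambiguous. The het band takes precedence: a fraction within
    tolerance of 0.5 is het even when a hom band (collapsed toward 0.5
    at low purity) is nearer — below a band separation of ``tolerance``
    the classes are genuinely indistinguishable and het is the
    conservative call. A site with zero depth is uninformative
    (ambiguous).
    """
    if site.depth == 0:
        return SiteClass("ambiguous")
    if abs(site.allele_fraction - 0.5) <= tolerance:
        return SiteClass("het")
    ref_band, alt_band = loh_expected_fractions(model, deletion=deletion_loh)
    bands = (("hom_ref_adjusted", ref_band), ("hom_alt_adjusted", alt_band))
    label, dist = min(
        ((name, abs(site.allele_fraction - f)) for name, f in bands),
        key=lambda t: t[1],
    )
    if dist > tolerance:
        return SiteClass("ambiguous")
    return SiteClass(label)


def binomial_tolerance(allele_fraction: float, depth: int) -> float:
    """Depth-aware alternative tolerance: two binomial standard errors."""
    if depth <= 0:
        return 0.5
    f = min(max(allele_fraction, 0.0), 1.0)
    return 2.0 * math.sqrt(f * (1.0 - f) / depth)
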
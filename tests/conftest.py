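import numpy as np
import pytest

from somascope.purity import PurityModel
from somascope.simulate import TruthEvent, simulate_pair

SMALL_GENOME = {"chr1": 2_000_000, "chr2": 2_000_000}


@pytest.fixture(scope="session")
def small_pair():
    """A small tumor/normal pair (2 x 2 Mb) with one CNV and one LoH event."""
    truth = [
        TruthEvent("cnv", "chr1", 500_000, 1_500_000, cn=4),
        TruthEvent("loh", "chr2", 400_000, 1_600_000, retained="alt"),
        TruthEvent("sv", "chr1", 100_000, 150_000, sv_type="DEL", length=-50_000, somatic=True),
        TruthEvent("sv", "chr2", 200_000, 210_000, sv_type="DUP", length=10_000, somatic=False),
        TruthEvent("hla_loh", gene="HLA-A", lost_allele=2),
    ]
    model = PurityModel(0.7)
    return simulate_pair(truth, model, seed=11, genome=SMALL_GENOME), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
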
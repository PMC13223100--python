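import numpy as np
import pytest

from crotomr.sumstats import HarmonizedPair, SummaryDataset, VariantAssociation


def make_variant(variant_id="rs1", chromosome="1", position=1_000_000,
                 effect_allele="A", other_allele="G", eaf=0.3,
                 beta=0.1, se=0.02, pvalue=1e-9, n=10_000.0) -> VariantAssociation:
    return VariantAssociation(variant_id, chromosome, position, effect_allele,
                              other_allele, eaf, beta, se, pvalue, n)


def make_pairs(bx, by, sy, sx=None) -> list[HarmonizedPair]:
    """Harmonized pairs straight from effect arrays."""
    sx = sx if sx is not None else [0.01] * len(bx)
    return [
        HarmonizedPair(f"rs{i + 1}", float(x), float(s_x), float(y), float(s_y), "kept")
        for i, (x, y, s_y, s_x) in enumerate(zip(bx, by, sy, sx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_dataset():
    records = [
        make_variant("rs1", "1", 1_000_000, "A", "G", 0.3, 0.12, 0.02, 1e-12),
        make_variant("rs2", "1", 1_050_000, "T", "C", 0.2, 0.10, 0.02, 1e-9),
        make_variant("rs3", "2", 5_000_000, "A", "C", 0.4, -0.08, 0.02, 1e-10),
    ]
    return SummaryDataset("demo", "continuous", records)
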
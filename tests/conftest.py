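import numpy as np
import pytest

from cpgburden import (
    Consequence,
    GeneSpec,
    Population,
    SimConfig,
    VariantRecord,
    simulate_cohort,
)


def make_variant(**kwargs) -> VariantRecord:
    """A clean rare stop-gain variant; override fields per test."""
    base = dict(
        chrom="1",
        pos=100,
        ref="G",
        alt="T",
        gene_id="GENE1",
        consequence=Consequence.STOP_GAIN,
        maf_global=0.001,
    )
    base.update(kwargs)
    return VariantRecord(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One-population cohort with one strong planted gene and 19 nulls."""
    cfg = SimConfig(
        n_cases=400,
        n_controls=400,
        populations=[Population("EUR", 1.0, 1.0, 0.0)],
        n_common_variants=150,
        genes=[GeneSpec("HIT", 0.03, 2.5)] + [GeneSpec(f"NULL{i:02d}", 0.03) for i in range(19)],
        seed=1234,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
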
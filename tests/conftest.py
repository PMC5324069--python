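import numpy as np
import pandas as pd
import pytest

from prfr.io import GenotypeMatrix, make_variant_table
from prfr.simulate import SimConfig, simulate_cohort


@pytest.fixture
def tiny_genotypes():
    """3 samples x 2 SNPs with one missing call."""
    values = np.array([[0.0, 1.0], [2.0, np.nan], [1.0, 0.0]])
    g = GenotypeMatrix(values, ["s1", "s2", "s3"], ["rs1", "rs2"])
    v = make_variant_table(["rs1", "rs2"], chrom="1", pos=[100, 500])
    return g, v


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-effect cohort shared across read-only tests."""
    cfg = SimConfig(n_samples=300, n_snps=400, n_causal=5,
                    effect_log_odds=0.8, seed=7)
    g, v, pheno, truth = simulate_cohort(cfg)
    return g, v, pheno, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No causal SNPs: outcome independent of every genotype."""
    cfg = SimConfig(n_samples=300, n_snps=400, n_causal=0, seed=11)
    g, v, pheno, truth = simulate_cohort(cfg)
    return g, v, pheno, truth
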
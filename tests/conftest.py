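import numpy as np
import pandas as pd
import pytest

from emprs import simulate
from emprs.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(n_snps=50, n_samples=400, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.simulate_cohort(small_config)


@pytest.fixture
def tiny_matrix():
    """4 samples × 3 SNPs with one missing call."""
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        snp_ids=["rs1", "rs2", "rs3"],
        dosages=[[0, 1, 2], [1, 1, 0], [2, 0, np.nan], [0, 2, 1]],
        effect_allele=["A", "C", "G"],
        other_allele=["G", "T", "A"],
    )


@pytest.fixture
def tiny_weights():
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "beta": [0.5, -0.2, 0.1],
        }
    )
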
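import numpy as np
import pandas as pd
import pytest

from telomaint import synthetic_data as sd


@pytest.fixture(scope="session")
def dependency_sim():
    """Default dependency screen: 9-gene module, one planted mutation."""
    return sd.gen_dependency(seed=11)


@pytest.fixture(scope="session")
def allele_counts_sim():
    counts, truth = sd.gen_allele_counts(seed=5, n_snps=300)
    return counts, truth


@pytest.fixture(scope="session")
def cpg_pairs_sim():
    pairs, truth = sd.gen_cpg_pairs(seed=3, n_samples=25, n_pairs=30)
    return pairs, truth


@pytest.fixture(scope="session")
def batched_content_sim():
    return sd.gen_batched_content(seed=2)


@pytest.fixture(scope="session")
def methylation_cohort_small():
    """Scaled-down enrichment cohort for unit tests."""
    return sd.gen_methylation_cohort(
        seed=4, n_cgis=500, n_mut=15, n_wt=45, n_decoys=5, set_size=40
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
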
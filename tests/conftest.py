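import numpy as np
import pandas as pd
import pytest

from brainmod.synth import SynthConfig, gen_expression, gen_gene_annotation


@pytest.fixture(scope="session")
def small_config():
    """Two planted modules over 400 genes, desk-scale but non-trivial."""
    return SynthConfig(
        n_genes=400,
        n_samples=120,
        module_sizes=(60, 50),
        noise_sd=0.4,
        n_families=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    expr, truth = gen_expression(small_config)
    return expr, truth


@pytest.fixture(scope="session")
def small_annotation(small_config):
    genes, snps = gen_gene_annotation(small_config)
    return genes, snps


@pytest.fixture(scope="session")
def enriched_config():
    """Signal planted in mod01: transmission distortion and low GWAS p-values."""
    return SynthConfig(
        n_genes=400,
        n_samples=120,
        module_sizes=(60, 50),
        noise_sd=0.4,
        n_families=400,
        transmission_prob=0.6,
        enriched_module="mod01",
        gwas_beta_a=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def labels_from_truth(small_data):
    _, truth = small_data
    return pd.Series(truth.module_of)
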
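import numpy as np
import pandas as pd
import pytest

from ccf1tx import (
    SimulationConfig,
    build_f1_diploid,
    build_strain_transcriptome,
    gen_founders,
    gen_mosaic,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_genes=20,
        n_chromosomes=2,
        chrom_length_bp=20_000,
        transcript_length_bp=300,
        snp_rate=0.02,
        n_blocks_per_chrom=4,
        read_length=43,
    )


@pytest.fixture(scope="session")
def founders(small_config):
    founders, snp_table = gen_founders(small_config)
    return founders


@pytest.fixture(scope="session")
def snp_table(small_config):
    _, snp_table = gen_founders(small_config)
    return snp_table


@pytest.fixture(scope="session")
def mosaic(small_config):
    return gen_mosaic(small_config, "CC001")


@pytest.fixture(scope="session")
def diploid(small_config, founders, mosaic):
    haploid = build_strain_transcriptome(mosaic, founders)
    return build_f1_diploid(haploid, founders=founders)


def planted_expression(n_genes=300, n_samples=40, modules=((80, 1.0), (80, 1.0)),
                       noise_sd=0.4, seed=0):
    """Gene x sample matrix with planted orthogonal module factors.

    Returns (DataFrame, truth labels array with 0 = background)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=noise_sd, size=(n_genes, n_samples))
    truth = np.zeros(n_genes, dtype=int)
    cursor = 0
    for m, (size, sd) in enumerate(modules, start=1):
        f = rng.normal(scale=sd, size=n_samples)
        X[cursor : cursor + size] += f
        truth[cursor : cursor + size] = m
        cursor += size
    df = pd.DataFrame(
        X,
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return df, truth
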
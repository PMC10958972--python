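"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acatwas.ld_reference import LDBlock
from acatwas.model_registry import WeightModel
from acatwas.synthetic_data import LdSpec, sim_genotypes, sim_models


def copula_dosage_corr(maf1: float, maf2: float, latent_rho: float) -> float:
    """Brute-force oracle for the dosage correlation implied by the Gaussian
    copula: the bivariate-normal orthant probability below the two MAF
    quantiles gives the allele-indicator covariance; the dosage (sum of two
    independent haplotypes) has the same correlation as one haplotype."""
    q1, q2 = stats.norm.ppf(maf1), stats.norm.ppf(maf2)
    p11 = stats.multivariate_normal.cdf(
        [q1, q2], mean=[0.0, 0.0], cov=[[1.0, latent_rho], [latent_rho, 1.0]]
    )
    cov = p11 - maf1 * maf2
    return cov / np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))


def analytic_ar1_block(m: int, rho: float, block_id: str = "block0000") -> LDBlock:
    """LDBlock with an exact AR(1) correlation matrix and unit SDs, for tests
    that need population LD rather than a sampled estimate."""
    idx = np.arange(m)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    variants = pd.DataFrame(
        {
            "SNP": [f"snp_b0000_{i:03d}" for i in range(m)],
            "CHR": 1,
            "POS": 1 + idx * 1000,
            "A1": "A",
            "A2": "G",
        }
    )
    return LDBlock(
        variants=variants, cov=corr.copy(), corr=corr.copy(),
        sd=np.ones(m), block_id=block_id,
    )


@pytest.fixture(scope="session")
def small_panel():
    spec = LdSpec(n_blocks=3, block_size=6, rho=0.5, maf_range=(0.1, 0.5))
    return sim_genotypes(800, spec, seed=11)


@pytest.fixture(scope="session")
def small_blocks(small_panel):
    return small_panel.ld_blocks(ridge=0.0)


@pytest.fixture(scope="session")
def small_models(small_panel):
    modelset, truth = sim_models(
        small_panel, n_genes=6, n_tissues=3, sparsity=2, weight_sd=0.1, seed=7,
        introns_per_gene=(1, 2),
    )
    return modelset, truth


def make_model(snps, weights, feature_id="GENE_T", tissue="breast",
               feature_type="gene", gene_id=None) -> WeightModel:
    return WeightModel(
        feature_id=feature_id,
        feature_type=feature_type,
        gene_id=gene_id or (feature_id if feature_type == "gene" else "GENE_T"),
        tissue=tissue,
        snps=list(snps),
        a1=["A"] * len(snps),
        a2=["G"] * len(snps),
        weights=np.asarray(weights, float),
    )
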
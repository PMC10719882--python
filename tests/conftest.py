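import numpy as np
import pytest

from pathgwa.genotype_io import build_genotype_matrix
from pathgwa.relatedness import centered_kinship, pca_covariates
from pathgwa.simulate import SimulationConfig, simulate_genotypes, simulate_phenotype


def make_matrix(dosages, chroms=None, positions=None, samples=None):
    """Small GenotypeMatrix from a raw dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    chroms = chroms or ["Chr01"] * p
    positions = positions or [100 * (j + 1) for j in range(p)]
    samples = samples or [f"s{i+1}" for i in range(n)]
    return build_genotype_matrix(samples, chroms, positions, dosages)


@pytest.fixture(scope="session")
def small_panel():
    """120 samples x 300 SNPs block-LD inbred panel with 3 sparse causals."""
    cfg = SimulationConfig(
        n_samples=120, n_snps=300, n_blocks=10, n_causal_sparse=3,
        pve_target=0.5, pge_target=1.0, seed=20231202,
    )
    G = simulate_genotypes(cfg)
    y, truth = simulate_phenotype(G, cfg)
    return cfg, G, y, truth


@pytest.fixture(scope="session")
def small_panel_model(small_panel):
    """Kinship and 4-PC covariates for the small panel."""
    _, G, _, _ = small_panel
    return centered_kinship(G), pca_covariates(G, k=4)
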
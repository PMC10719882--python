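# pathgwa

Comparative genome-wide association for quantitative traits on inbred
SNP panels: a linear mixed model (LMM) scan, a Bayesian sparse linear
mixed model (BSLMM) fitted by MCMC, and a candidate pathway association
(CPA) stage restricted to SNPs inside annotated pathway enzyme genes.

The package is aimed at plant and evolutionary geneticists who map
quantitative traits (for example, petal carotenoid content) on
resequenced diversity panels and want to go beyond the single-SNP scan:
how much trait variance do the genotypes explain, is the architecture
oligogenic or polygenic, and does restricting the test to a curated
biosynthetic pathway change the answer?

## The models

**LMM scan.** For each SNP x,

    y = Wα + xβ + u + ε,   u ~ N(0, λτ⁻¹K),   ε ~ N(0, τ⁻¹I)

with K the centered kinship `XcXcᵀ/p`, W an intercept plus the first
four principal components of a D′-pruned SNP set, and λ re-estimated
per SNP by restricted maximum likelihood after a single
eigendecomposition of K. β̂ is tested with a Wald statistic against
F(1, n−c−1). Genome-wide significance uses a Gao-style correction: the
effective number of independent tests m_eff is either the number of
haplotype blocks in a partition ("block-count") or the per-block
eigenvalue count reaching 99.5% of the correlation-matrix variance
("simpleM"); the significant line is −log10(α/m_eff) and the
suggestive line −log10(0.001).

**BSLMM.** The trait decomposes into sparse major effects plus a
polygenic background,

    y = Wα + Xβ̃ + u + ε,   β̃_j ~ π N(0, σa²τ⁻¹) + (1−π) δ₀,
    u ~ N(0, σb²τ⁻¹K)

with hyperpriors h ~ U(0,1), ρ ~ U(0,1), log π ~ U(log 1/p, 0). The
posterior is explored by Metropolis–Hastings over (γ, h, ρ, log π) with
β̃, u, τ integrated out analytically. Each recorded iteration yields the
realized variance fractions PVE (all genotypes) and PGE (sparse terms
only), the sparse-set size N.Gamma, and per-SNP posterior inclusion
probabilities (PIP, γ). A SNP's effect is summarised as |β × γ|, and a
SNP is called a **major-effect locus** when its PIP is at least 0.10
and the 2.5–97.5% interval of its effect does not overlap zero.
Analyses are repeated over independent chains (10 by default) and
summarised by medians.

**CPA.** A pathway table (EC number → enzyme → gene ID) is resolved
against a GFF3 annotation; SNPs inside the annotated gene bodies are
extracted and both models rerun on that subset, keeping the genome-wide
kinship, covariates and the genome-wide Gao threshold.

A block-LD genotype/phenotype simulator (Gaussian-copula haplotypes,
configurable inbreeding, exact in-sample PVE/PGE scaling) makes every
stage testable without external data.

## Worked example

```python
from pathgwa import (
    SimulationConfig, simulate_genotypes, simulate_phenotype,
    centered_kinship, pca_covariates, lmm_associate, gao_meff,
    blocks_from_dprime, BslmmConfig, bslmm_fit, classify_major,
)

sim = SimulationConfig(n_samples=300, n_snps=1000, n_causal_sparse=5,
                       pve_target=0.5, pge_target=0.8, seed=20231202)
G = simulate_genotypes(sim)
y, truth = simulate_phenotype(G, sim)

K = centered_kinship(G)
W = pca_covariates(G, k=4)

results = lmm_associate(G, y, K, W)
thresholds = gao_meff(G, blocks_from_dprime(G, 0.8), mode="block-count")

post = bslmm_fit(G, y, K, W, BslmmConfig(burn_in=10_000, steps=100_000,
                                         record_pace=10, chains=3, seed=1))

top = min(results, key=lambda r: r.p_wald)
print(f"top LMM hit: {top.snp_id}  beta={top.beta:+.3f}  P={top.p_wald:.2e}")
print(f"m_eff={thresholds.m_eff}  Gao line: -log10 P > {thresholds.significant_logp:.2f}")
print(f"true causals: {truth.causal_ids}")
lo, hi = post.hyperparameter_interval("pve")
print(f"PVE = {100*post.point_estimate('pve'):.0f}%  (2.5-97.5%: {100*lo:.0f}-{100*hi:.0f}%)")
print(f"PGE = {100*post.point_estimate('pge'):.0f}%   Rho = {post.point_estimate('rho'):.2f}   "
      f"N.Gamma = {post.point_estimate('n_gamma'):.0f}")
for call in classify_major(post)[:3]:
    print(f"  {call.snp_id}: PIP={call.pip:.2f} |beta*gamma|={call.sparse_effect:.3f} "
          f"major={call.is_major}")
```

Output (deterministic for these seeds):

```
top LMM hit: Chr01:18000  beta=-0.691  P=5.00e-14
m_eff=730  Gao line: -log10 P > 4.16
true causals: ['Chr01:18000', 'Chr01:248000', 'Chr02:377000', 'Chr02:481000', 'Chr02:492000']
PVE = 40%  (2.5-97.5%: 31-50%)
PGE = 95%   Rho = 0.95   N.Gamma = 5
  Chr01:18000: PIP=1.00 |beta*gamma|=0.673 major=True
  Chr01:248000: PIP=1.00 |beta*gamma|=0.362 major=True
  Chr02:377000: PIP=1.00 |beta*gamma|=0.303 major=True
```

Reading the numbers: the scan's strongest association is a true causal
SNP and clears the Gao line (14 ≫ 4.16). The BSLMM attributes ~40% of
the trait variance to genotype (the simulation planted 50%; the
interval covers the shortfall), almost all of it through sparse terms
(PGE and Rho near 1 signal an oligogenic architecture), and its
posterior expects about five major-effect loci — the number planted.
The three largest |β × γ| effects are all true causals and pass the
PIP + interval rule.

The same workflow runs from the shell: `pathgwa pipeline` drives
simulate/load → filter → kinship/PCA → LMM → thresholds → subsets →
BSLMM → CPA → tables from one YAML config, and each stage is also an
individual subcommand (`simulate`, `filter`, `kinship`, `prune`, `pca`,
`lmm`, `meff`, `subset`, `bslmm`, `cpa`, `report`).

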
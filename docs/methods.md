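# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `pathgwa`, and what the synthetic-data tests do and
do not establish about real data.

## Data model

Genotypes are biallelic SNP dosages (alt-allele counts 0/1/2, `NaN` for
missing calls) over uniquely identified samples; SNPs are unique on
(chromosome, position, alt allele) and sorted by chromosome (natural
order) then position. Positions are 1-based throughout; the only
half-open coordinates are in BED block files, converted explicitly at
the boundary. Phased and unphased genotypes are treated identically.

Panel construction follows the convention for inbred diversity panels:
SNPs with minor allele frequency below 5% **or** observed
heterozygosity above 10% are excluded (both bounds configurable).
Missing calls are mean-imputed per SNP before any linear algebra;
samples with a missing phenotype are dropped at alignment time with a
logged count, never silently inside a model fit.

## Kinship, LD pruning, structure

Kinship is the centered product `K = Xc Xcᵀ / p`. The structure
covariates are an intercept plus the first k = 4 principal components
of the centered (not standardized, matching the kinship convention;
standardization is a flag) dosages of an LD-pruned SNP set.

Pruning uses the normalized linkage-disequilibrium coefficient
D′ = |D|/Dmax in a sliding window (defaults: 50 SNPs, step 5,
threshold 0.8; within a window the later SNP of any pair at or above
the threshold is dropped — greedy, position-ordered, deterministic).
D′ between unphased dosage columns is estimated by the standard EM
two-locus haplotype-frequency algorithm with pairwise-complete
observations; for fully homozygous lines dosage/2 *is* the haplotype
and the estimate is exact. PC sign is fixed by making the
largest-magnitude score positive, for reproducibility.

## LMM scan

Per SNP, `y = Wα + xβ + u + ε` with `u ~ N(0, λτ⁻¹K)`. K is
eigendecomposed once; in the rotated basis the restricted likelihood of
λ is profiled (τ and the fixed effects integrated/profiled out) and
maximized over λ ∈ [1e−5, 1e5] by a 100-point log-grid pass — computed
for all SNPs at once via block inversion of the covariate cross-products
— followed by bounded Brent refinement per SNP. The Wald statistic
(β̂/se)² is referred to F(1, n−c−1), the convention of the standard
mixed-model association tools. P values are floored at the smallest
positive double rather than reported as 0.

**Heritability.** The null model (no SNP term) gives λ̂; with the
centered kinship above, the per-sample genetic variance is
λτ⁻¹·tr(K)/n, so we report

    h²_SNP = λ̂·mK / (λ̂·mK + 1),   mK = tr(K)/n.

The mK factor matters: tr(K)/n equals the mean SNP dosage variance
(≈0.5 for an inbred panel with MAF ∈ [0.1, 0.5]), and omitting it
biases h² downward by roughly a third in our simulations. The interval
is a Wald CI on log λ from the numerical curvature of the restricted
likelihood, transformed to the h² scale; when the likelihood is flat
(λ̂ at a search bound) the interval widens to the full range.

**Multiple testing.** `gao_meff` offers two modes. `block-count`
(default) takes m_eff as the size of a supplied haplotype-block
partition — blocks come from a BED file, from the simulator's known
blocks, or from runs of adjacent SNPs with consecutive-pair D′ ≥ 0.8.
`simpleM` computes, per block, the smallest number of eigenvalues of
the SNP correlation matrix reaching 99.5% of the total, and sums over
blocks. The significant line is −log10(α/m_eff) with α = 0.05; the
suggestive line is −log10(0.001).

**Subsets.** The three scan-derived subsets are the top 1% by smallest
P, the top 1% by |β̂| (signed ranking is a flag; magnitude is the
default since sign is arbitrary for ranking), and their union, with
ceil(fraction·p) members and ties broken by (chromosome, position).

## BSLMM

The sparse model is

    y = Wα + Xβ̃ + u + ε,  β̃_j ~ π N(0, σa²τ⁻¹) + (1−π)δ₀,
    u ~ N(0, σb²τ⁻¹K),     ε ~ N(0, τ⁻¹I)

parameterized through h (approximate PVE), ρ (approximate PGE) and π:

    σa² = ρ·h/(1−h) / (π·p·s̄x),   σb² = (1−ρ)·h/(1−h) / (tr K/n)

with s̄x the mean SNP dosage variance. Priors: h ~ U(0,1), ρ ~ U(0,1),
log π ~ U(log(1/p), 0) — the defaults of the standard implementation of
this model. Covariates enter by projection: W (intercept + PCs by
default; intercept only if disabled) is projected out of y and X before
sampling, and the τ-likelihood uses n−c degrees of freedom.

**Sampler.** Metropolis–Hastings over (γ, h, ρ, log π) with β̃, u, τ
integrated out. After rotating by the eigenvectors of K the marginal
likelihood of a sparse set γ needs only the |γ|×|γ| system
C = I + σa²·XγᵀΛ⁻¹Xγ (Λ = σb²D + I diagonal), maintained incrementally:
add/delete/swap proposals update C's ingredients in O(n|γ|), and hyper
moves rebuild them with BLAS products. Proposals are

- γ: a geometric number (p = 0.7, capped at 4) of add/delete/swap
  sub-moves, uniform over eligible SNPs, with the exact compound
  Hastings correction and a sparse-set cap s_max = 300;
- h, ρ: reflected uniform random walks on [0,1] (step 0.1);
- log π: reflected walk on [log(1/p), 0] (step 0.5 nats).

By default 90% of iterations propose a γ change and 10% a joint
(h, ρ, log π) change; with thinning ≥ 10 the hyperparameter chains
remain well mixed, and the sparse set — the harder marginal — gets most
of the proposal budget. The kernel is compiled with numba; a chain of
10⁵ iterations on n = 300, p = 1000 takes on the order of a second when
the posterior sparse set is small.

**Recording.** Every `record_pace`-th post-burn-in iteration draws τ,
β̃ and u from their exact conditionals and records h, ρ, π, |γ| and the
realized variance fractions

    PVE_t = s(Xβ̃+u) / (s(Xβ̃+u) + 1/τ),   PGE_t = s(Xβ̃) / s(Xβ̃+u)

with s(·) the in-sample variance. Per-SNP PIP is the inclusion
fraction over records; the reported per-SNP β is the mean of its effect
draws conditional on inclusion, so that |β × γ| is the
inclusion-weighted effect magnitude. The per-SNP polygenic column
(`alpha` in the parameter file) is a posterior-mean approximation
`(σb²/p)·Xᵀ(σb²K+I)⁻¹r̄` evaluated at the posterior-median h, ρ and
mean residual — a report-only convenience, not a sampled quantity.

**Intervals and major-effect calls.** The default interval is the
central 2.5–97.5% quantile pair; the shortest-interval ("hpd") variant
is also implemented. Effect intervals are computed over a SNP's
conditional (on inclusion) draws: an unconditional interval would
contain zero for any PIP below ~0.975 and make the published decision
rule vacuous. A SNP with fewer than 10 inclusion draws cannot
establish a directional effect and is never called major. The call
rule is the conjunction: PIP ≥ 0.10 **and** interval excluding zero.

**Repeat chains.** An analysis runs `chains` chains (default 10),
chain i seeded `base_seed + i`. Hyperparameter point estimates are
medians of per-chain medians; per-SNP PIPs are per-SNP medians across
chains; effect draws and hyperparameter traces are pooled, so intervals
default to pooled-sample intervals (median-of-bounds is available by
aggregating manually). Production settings are 500k burn-in, 5M steps,
thinning 100; the test suite and the acceptance script use shortened
chains (2k–20k burn-in, 20k–200k steps, thinning 10–20, 1–3 chains)
chosen so the full suite runs on one CPU in minutes — the posterior
checks below calibrate what those shortened chains deliver.

## Candidate pathway association

The pathway is a 3-column table (EC number, enzyme name, gene ID; one
row per EC–gene pair), kept as a versioned file rather than a live
database query. EC numbers must have four dot-separated fields. Gene
IDs resolve against `gene` features of a GFF3 (ID or Name attribute);
an enzyme with no annotated or polymorphic gene is logged, not an
error. SNP membership is gene-body-only by default (1-based inclusive
span; strand recorded but ignored; an optional flank widens the span),
and a SNP inside overlapping genes counts once. The CPA stage reruns
the LMM and BSLMM on the extracted subset with the *genome-wide*
kinship, covariates and Gao threshold — a pathway subset does not earn
a laxer multiple-testing burden — and reports per-gene top effects.

## Simulator

Genotypes: within each LD block, two latent haplotype vectors share a
common Gaussian factor (equicorrelation `within_block_r`, default 0.8)
and are thresholded at frequencies drawn from `maf_range` (default
U(0.10, 0.50)); an `inbreeding` fraction (default 0.95) of calls copies
one haplotype's allele onto the other, emulating inbred lines.
Defaults (n = 300, p = 1000, 20 blocks over 2 chromosomes, 1 kb SNP
spacing) are the test fixture scale.

Phenotypes: `y = Xβ̃ + u + ε` with β̃ standard-normal on the causal
set, u drawn with covariance proportional to the panel's centered
kinship, and the three components Gram–Schmidt orthogonalized and
rescaled so the in-sample variance fractions equal `pve_target` and
`pge_target` *exactly* — parameter-recovery tests are sharp at small n
because the estimand is not itself noisy. The orthogonalization
slightly distorts the polygenic component's covariance (one projection
direction removed); this is the price of exact fractions.

What the simulator does not model: demographic history and realistic
LD decay (blocks are equicorrelated, not coalescent), selection,
genotyping error, allele-frequency spectra of real panels, and
gene-density structure. Passing tests therefore establish correctness
of the estimators under the model's own assumptions and usable power
at desk scale — not performance on a real 1.4M-SNP resequencing panel.

## Calibration results the suite establishes

With shortened chains on one CPU (all seeds fixed in the tests):

- on a two-SNP problem the sampler's PIPs agree within 0.03 with the
  exact posterior computed by dense enumeration over the sparse sets
  and numerical integration of the hyperpriors;
- null Wald P values are uniform (KS < 0.05 at 2000 SNPs, n = 200);
- with a constant likelihood the sampler reproduces its U(0,1) priors
  on h and ρ (KS < 0.05 on 10,000 records);
- the 95% central PVE interval covers a true PVE of 0.5 in ≥ 8/10
  seeds (n = 500, p = 1000, 10 causals);
- posterior-median ρ orders oligogenic above polygenic architecture in
  ≥ 9/10 paired seeds (n = 300, p = 1000);
- a causal SNP planted in a pathway gene tops the CPA report by
  |β × γ| in ≥ 8/10 seeds, and a causal-free pathway yields zero
  major-effect calls in ≥ 9/10 seeds (n = 200, p = 300);
- identical config + seed reproduces every pipeline artifact
  byte-for-byte.

## Known limitations

- **Null PIPs at small p.** With a few hundred SNPs, the log-uniform π
  prior leaves substantial mass on moderately large sparse sets, and a
  chance-correlated SNP (the most extreme of p null correlations) can
  legitimately reach PIP 0.1–0.5 under a pure-noise trait. Raw PIP is
  therefore *not* a calibrated error rate at desk scale; the
  PIP + interval conjunction is, and it produced zero false
  major-effect calls in all null replicates. At genome scale (p ≫ 10⁴)
  the prior odds per SNP shrink and raw PIPs become conservative.
- **Sparse-set mixing in the prior-plateau regime.** Under polygenic or
  null traits the posterior over |γ| has a broad plateau; finite chains
  traverse it slowly, so N.Gamma summaries in that regime depend on
  chain length more than the variance-fraction summaries do.
- **Per-SNP λ at scale.** λ is re-optimized per SNP (grid + Brent);
  the scan is vectorized over the grid but the refinement loops per
  SNP, so million-SNP panels would want the usual null-λ approximation
  (not implemented).
- **Projection approximation.** Projecting covariates out of y and X
  while keeping the original K eigenbasis is the standard equivalence
  and is exact for the intercept under a centered K; for PCs it is an
  approximation accepted by the reference implementation of this model
  class as well.
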
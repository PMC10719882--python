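"""Per-SNP linear mixed model association scan.

For each SNP the model is

    y = Wα + xβ + u + ε,   u ~ N(0, λ τ⁻¹ K),   ε ~ N(0, τ⁻¹ I)

with W the structure covariates (intercept + PCs) and K the centered
kinship.  K is eigendecomposed once; in the rotated basis the covariance
is diagonal, the variance ratio λ is profiled out by restricted maximum
likelihood (coarse log-grid then Brent refinement), and β̂ is tested with
a Wald statistic against F(1, n − c − 1), c = covariate count.

Multiple testing uses an effective number of independent tests m_eff:
either the size of a haplotype-block partition ("block-count") or the
eigenvalue-based simpleM count per block ("simpleM").  Genome-wide
significance is declared at −log10 P above −log10(α / m_eff); the
suggestive line is −log10(0.001).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix, PhenotypeVector, _chrom_sort_key
from .relatedness import KinshipMatrix, StructureCovariates

logger = logging.getLogger("pathgwa")

__all__ = [
    "LmmSnpResult",
    "ScanThresholds",
    "SnpSubset",
    "lmm_associate",
    "reml_lambda",
    "estimate_h2",
    "gao_meff",
    "blocks_from_dprime",
    "blocks_from_bed",
    "subset_by_rank",
    "subset_union",
    "results_frame",
]

LAMBDA_BOUNDS = (1e-5, 1e5)
GRID_POINTS = 100


@dataclass
class LmmSnpResult:
    snp_id: str
    chrom: str
    pos: int
    maf: float
    beta: float
    se: float
    p_wald: float
    lambda_reml: float


@dataclass
class ScanThresholds:
    """Gao-corrected and suggestive −log10 P significance lines."""

    m_eff: int
    alpha: float = 0.05
    mode: str = "block-count"

    @property
    def significant_logp(self) -> float:
        return -math.log10(self.alpha / self.m_eff)

    @property
    def suggestive_logp(self) -> float:
        return -math.log10(0.001)


@dataclass
class SnpSubset:
    """An ordered, duplicate-free SNP selection with its provenance."""

    name: str
    snp_ids: list[str]
    keys: list[tuple[str, int]]  # (chrom, pos) per id, for deterministic sorting
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("subset contains duplicate SNP ids")
        if len(self.keys) != len(self.snp_ids):
            raise ValueError("keys and snp_ids must be parallel")

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# subset: {self.name}; {self.provenance}\n")
            for s in self.snp_ids:
                fh.write(s + "\n")


# ---------------------------------------------------------------------------
# restricted likelihood machinery
# ---------------------------------------------------------------------------


def _eigen_rotate(K: np.ndarray, y: np.ndarray, W: np.ndarray, X: np.ndarray | None):
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -1e-8:
        raise ValueError(f"kinship not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    Xt = U.T @ X if X is not None else None
    return d, U.T @ y, U.T @ W, Xt


def _profile_reml(lam: float, d: np.ndarray, yt: np.ndarray, Ft: np.ndarray) -> float:
    """Profile restricted log-likelihood of λ (additive constants dropped)."""
    v = lam * d + 1.0
    w = 1.0 / v
    FtF = Ft.T @ (w[:, None] * Ft)
    Fty = Ft.T @ (w * yt)
    yy = float(yt @ (w * yt))
    sign, logdet = np.linalg.slogdet(FtF)
    if sign <= 0:
        return -np.inf
    sol = np.linalg.solve(FtF, Fty)
    rss = yy - float(Fty @ sol)
    if rss <= 0:
        rss = 1e-300
    df = len(yt) - Ft.shape[1]
    return -0.5 * float(np.sum(np.log(v))) - 0.5 * logdet - 0.5 * df * math.log(rss)


def _brent_lambda(d, yt, Ft, grid_loglik, grid) -> float:
    j = int(np.argmax(grid_loglik))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[j])
    res = optimize.minimize_scalar(
        lambda t: -_profile_reml(10.0**t, d, yt, Ft),
        bounds=(math.log10(lo), math.log10(hi)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    lam = float(10.0**res.x)
    return lam if -res.fun >= grid_loglik[j] else float(grid[j])


def reml_lambda(
    y: np.ndarray,
    x: np.ndarray | None,
    W: np.ndarray,
    eigen_K: tuple[np.ndarray, np.ndarray] | None = None,
    K: np.ndarray | None = None,
) -> float:
    """REML variance-ratio estimate λ̂ for one design (x may be None).

    Searches λ ∈ [1e-5, 1e5]: a 100-point log-grid pass followed by
    bounded Brent refinement around the grid maximum.
    """
    if eigen_K is None:
        if K is None:
            raise ValueError("supply eigen_K or K")
        d, U = np.linalg.eigh((K + K.T) / 2.0)
        d = np.clip(d, 0.0, None)
    else:
        d, U = eigen_K
    F = np.column_stack([W, x]) if x is not None else np.asarray(W, float)
    yt = U.T @ np.asarray(y, float)
    Ft = U.T @ F
    grid = np.logspace(math.log10(LAMBDA_BOUNDS[0]), math.log10(LAMBDA_BOUNDS[1]), GRID_POINTS)
    ll = np.array([_profile_reml(l, d, yt, Ft) for l in grid])
    if not np.isfinite(ll).any():
        raise ValueError("restricted likelihood non-finite over the entire λ grid")
    return _brent_lambda(d, yt, Ft, ll, grid)


def lmm_associate(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    K: KinshipMatrix,
    W: StructureCovariates,
    fix_lambda: float | None = None,
) -> list[LmmSnpResult]:
    """Scan every SNP with the mixed model; λ re-estimated per SNP by REML.

    ``fix_lambda`` skips the REML search and evaluates every SNP at the
    given variance ratio (generalized least squares with covariance
    λK + I) — used for validation against direct dense solves.
    """
    if not (G.samples == y.samples == K.samples == W.samples):
        raise ValueError("sample order differs between genotypes, phenotype, kinship, covariates")
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("lmm_associate requires imputed dosages")
    yv = np.asarray(y.values, float)
    Wm = W.W
    n, c = Wm.shape
    if np.linalg.matrix_rank(Wm) < c:
        raise ValueError("covariate matrix is singular")
    d, yt, Wt, Xt = _eigen_rotate(K.K, yv, Wm, X)

    if fix_lambda is not None:
        lam_grid = np.array([float(fix_lambda)])
    else:
        lam_grid = np.logspace(
            math.log10(LAMBDA_BOUNDS[0]), math.log10(LAMBDA_BOUNDS[1]), GRID_POINTS
        )

    p = G.n_snps
    df_res = n - c - 1
    if df_res < 1:
        raise ValueError("not enough samples for the covariate count")

    # vectorized grid pass: profile REML for every (λ, SNP) pair
    grid_ll = np.empty((len(lam_grid), p))
    cache = []
    for gi, lam in enumerate(lam_grid):
        v = lam * d + 1.0
        w = 1.0 / v
        Ww = w[:, None] * Wt
        A = Wt.T @ Ww                      # c×c
        Ainv = np.linalg.inv(A)
        Wy = Wt.T @ (w * yt)               # c
        yy = float(yt @ (w * yt))
        signA, logdetA = np.linalg.slogdet(A)
        rss0 = yy - float(Wy @ Ainv @ Wy)
        xx = w @ (Xt**2)                   # p
        xy = (w * yt) @ Xt                 # p
        B = Ww.T @ Xt                      # c×p, Wᵀ Λ⁻¹ x per SNP
        AinvB = Ainv @ B
        schur = xx - np.einsum("ij,ij->j", B, AinvB)
        schur = np.where(schur > 1e-12, schur, np.nan)
        bnum = xy - Wy @ AinvB             # x'Py numerator
        rss = rss0 - bnum**2 / schur
        rss = np.where(rss > 0, rss, 1e-300)
        grid_ll[gi] = (
            -0.5 * np.sum(np.log(v)) - 0.5 * (logdetA + np.log(schur)) - 0.5 * df_res * np.log(rss)
        )
        cache.append((w, Ainv, Wy, rss0, logdetA))

    results: list[LmmSnpResult] = []
    for j in range(p):
        xt = Xt[:, j]
        col_var = float(np.var(G.dosages[:, j]))
        if col_var == 0.0:
            results.append(
                LmmSnpResult(G.snps[j].id, G.snps[j].chrom, G.snps[j].pos, G.snps[j].maf,
                             0.0, float("nan"), 1.0, float("nan"))
            )
            continue
        lls = grid_ll[:, j]
        if fix_lambda is not None:
            lam = float(fix_lambda)
        else:
            Ft = np.column_stack([Wt, xt])
            lam = _brent_lambda(d, yt, Ft, lls, lam_grid)
        # final fit at λ̂
        v = lam * d + 1.0
        w = 1.0 / v
        Ft = np.column_stack([Wt, xt])
        FtF = Ft.T @ (w[:, None] * Ft)
        Fty = Ft.T @ (w * yt)
        sol = np.linalg.solve(FtF, Fty)
        rss = float(yt @ (w * yt)) - float(Fty @ sol)
        rss = max(rss, 1e-300)
        tau_inv = rss / df_res
        cov = tau_inv * np.linalg.inv(FtF)
        beta = float(sol[-1])
        se = float(math.sqrt(max(cov[-1, -1], 0.0)))
        if se > 0:
            fstat = (beta / se) ** 2
            pval = float(stats.f.sf(fstat, 1, df_res))
            pval = max(pval, 5e-324)
        else:
            pval = 1.0
        results.append(
            LmmSnpResult(G.snps[j].id, G.snps[j].chrom, G.snps[j].pos, G.snps[j].maf,
                         beta, se, pval, lam)
        )
    return results


def estimate_h2(
    y: PhenotypeVector, K: KinshipMatrix, W: StructureCovariates
) -> tuple[float, tuple[float, float]]:
    """SNP heritability from the null mixed model (no SNP fixed effect).

    With K = Xc Xcᵀ / p the per-sample genetic variance is λ τ⁻¹ tr(K)/n,
    so h² = λ̂·mK / (λ̂·mK + 1) with mK = tr(K)/n.  The interval is a
    Wald CI on log λ from the curvature of the restricted likelihood,
    transformed to the h² scale.
    """
    yv = np.asarray(y.values, float)
    d, U = np.linalg.eigh((K.K + K.K.T) / 2.0)
    d = np.clip(d, 0.0, None)
    lam = reml_lambda(yv, None, W.W, eigen_K=(d, U))
    mK = float(np.trace(K.K)) / len(yv)

    def h2_of(l: float) -> float:
        return l * mK / (l * mK + 1.0)

    yt, Wt = U.T @ yv, U.T @ W.W
    t0 = math.log(lam)
    h = 0.05
    f = lambda t: _profile_reml(math.exp(t), d, yt, Wt)
    curv = (f(t0 + h) - 2.0 * f(t0) + f(t0 - h)) / h**2
    if curv < 0:
        se_t = math.sqrt(-1.0 / curv)
        lo, hi = math.exp(t0 - 1.96 * se_t), math.exp(t0 + 1.96 * se_t)
    else:  # flat likelihood (e.g. λ at a search bound)
        lo, hi = LAMBDA_BOUNDS
    return h2_of(lam), (h2_of(max(lo, LAMBDA_BOUNDS[0])), h2_of(min(hi, LAMBDA_BOUNDS[1])))


# ---------------------------------------------------------------------------
# effective number of tests
# ---------------------------------------------------------------------------


def gao_meff(
    G: GenotypeMatrix,
    blocks: list[list[int]],
    mode: str = "block-count",
    variance_fraction: float = 0.995,
    alpha: float = 0.05,
) -> ScanThresholds:
    """Effective number of independent tests from a block partition.

    ``"block-count"`` takes m_eff as the number of blocks in the
    partition.  ``"simpleM"`` computes, per block, the smallest number of
    correlation-matrix eigenvalues whose sum reaches
    ``variance_fraction`` of the total, and sums over blocks.
    """
    if not blocks or any(len(b) == 0 for b in blocks):
        raise ValueError("blocks must be a non-empty partition with non-empty blocks")
    flat = sorted(j for b in blocks for j in b)
    if flat != list(range(G.n_snps)):
        raise ValueError("blocks must partition the SNP index range exactly")
    if mode == "block-count":
        return ScanThresholds(m_eff=len(blocks), alpha=alpha, mode=mode)
    if mode != "simpleM":
        raise ValueError(f"unknown m_eff mode {mode!r}")
    m_eff = 0
    for idx in blocks:
        sub = G.dosages[:, idx]
        sd = sub.std(axis=0)
        sub = sub[:, sd > 0]
        if sub.shape[1] == 0:
            continue
        if sub.shape[1] == 1:
            m_eff += 1
            continue
        corr = np.corrcoef(sub, rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        ev = np.clip(ev, 0.0, None)
        cum = np.cumsum(ev)
        m_eff += int(np.searchsorted(cum, variance_fraction * cum[-1]) + 1)
    return ScanThresholds(m_eff=m_eff, alpha=alpha, mode=mode)


def blocks_from_dprime(G: GenotypeMatrix, threshold: float = 0.8) -> list[list[int]]:
    """Haplotype blocks as maximal runs of adjacent same-chromosome SNPs
    whose consecutive-pair D′ is at least ``threshold``."""
    from .relatedness import dprime_matrix

    blocks: list[list[int]] = []
    cur = [0]
    for j in range(1, G.n_snps):
        same_chrom = G.snps[j].chrom == G.snps[j - 1].chrom
        linked = False
        if same_chrom:
            dp = dprime_matrix(G.dosages[:, [j - 1, j]])[0, 1]
            linked = bool(np.isfinite(dp) and dp >= threshold)
        if linked:
            cur.append(j)
        else:
            blocks.append(cur)
            cur = [j]
    blocks.append(cur)
    return blocks


def blocks_from_bed(G: GenotypeMatrix, bed: pd.DataFrame) -> list[list[int]]:
    """Assign SNPs to 0-based half-open BED intervals; SNPs not covered
    by any interval become singleton blocks."""
    blocks = []
    assigned = np.zeros(G.n_snps, dtype=bool)
    for _, row in bed.iterrows():
        idx = [
            j for j in range(G.n_snps)
            if not assigned[j]
            and G.snps[j].chrom == str(row["chrom"])
            and int(row["start"]) < G.snps[j].pos <= int(row["end"])
        ]
        if idx:
            for j in idx:
                assigned[j] = True
            blocks.append(idx)
    blocks.extend([[j] for j in range(G.n_snps) if not assigned[j]])
    return blocks


# ---------------------------------------------------------------------------
# LMM-derived SNP subsets
# ---------------------------------------------------------------------------


def subset_by_rank(
    results: list[LmmSnpResult],
    fraction: float = 0.01,
    criterion: str = "lowest_p",
    signed: bool = False,
) -> SnpSubset:
    """Top-fraction SNP subset by P value or effect size.

    Selects ceil(fraction × p) SNPs; ``"lowest_p"`` ranks ascending by
    Wald P, ``"largest_abs_beta"`` descending by |β| (or signed β with
    ``signed=True``).  Ties break by (chrom, pos) ascending.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(results))
    if criterion == "lowest_p":
        key = lambda r: (r.p_wald, _chrom_sort_key(r.chrom), r.pos)
        name = "p_values_1pct" if fraction == 0.01 else f"p_values_{fraction:g}"
    elif criterion == "largest_abs_beta":
        val = (lambda r: -r.beta) if signed else (lambda r: -abs(r.beta))
        key = lambda r: (val(r), _chrom_sort_key(r.chrom), r.pos)
        name = "effect_size_1pct" if fraction == 0.01 else f"effect_size_{fraction:g}"
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    ranked = sorted(results, key=key)[:k]
    return SnpSubset(
        name=name,
        snp_ids=[r.snp_id for r in ranked],
        keys=[(r.chrom, r.pos) for r in ranked],
        provenance=f"criterion={criterion}, fraction={fraction}",
    )


def subset_union(a: SnpSubset, b: SnpSubset) -> SnpSubset:
    """Union of two subsets from the same scan, sorted by (chrom, pos)."""
    merged = {sid: key for sid, key in zip(a.snp_ids, a.keys)}
    merged.update(dict(zip(b.snp_ids, b.keys)))
    order = sorted(merged, key=lambda sid: (_chrom_sort_key(merged[sid][0]), merged[sid][1]))
    return SnpSubset(
        name="combination",
        snp_ids=order,
        keys=[merged[s] for s in order],
        provenance=f"union of '{a.name}' and '{b.name}'",
    )


def results_frame(results: list[LmmSnpResult]) -> pd.DataFrame:
    """Association table (chrom, pos, id, maf, beta, se, p_wald, lambda)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "id": [r.snp_id for r in results],
            "maf": [r.maf for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p_wald": [r.p_wald for r in results],
            "lambda": [r.lambda_reml for r in results],
        }
    )
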
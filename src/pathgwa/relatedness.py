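"""Kinship, LD pruning and population-structure covariates.

Relatedness is summarised by the centered kinship matrix
``K = Xc Xcᵀ / p`` (Xc = column-centered dosages).  An approximately
independent SNP set is derived by sliding-window D′ pruning, and the
first k principal components of that pruned set (k = 4 by default) serve
as fixed-effect structure covariates in the association models.

D′ between unphased dosage columns is estimated by the standard EM
two-locus haplotype-frequency estimate; for fully inbred (homozygous)
lines dosage/2 is the haplotype and the estimate is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger("pathgwa")

__all__ = [
    "KinshipMatrix",
    "StructureCovariates",
    "centered_kinship",
    "ld_dprime",
    "dprime_matrix",
    "prune_by_dprime",
    "pca_covariates",
]


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix over an ordered sample list."""

    samples: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=np.float64)
        n = len(self.samples)
        if self.K.shape != (n, n):
            raise ValueError(f"kinship shape {self.K.shape} != ({n}, {n})")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    def validate_psd(self, tol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -tol:
            raise ValueError(f"kinship not PSD: min eigenvalue {w.min():.3g}")

    def write(self, path: str) -> None:
        df = pd.DataFrame(self.K, index=self.samples, columns=self.samples)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        K = df.to_numpy(dtype=np.float64)
        K = (K + K.T) / 2.0  # symmetrize away round-tripped text precision
        return cls(samples=[str(s) for s in df.columns], K=K)


@dataclass
class StructureCovariates:
    """Intercept plus k principal-component score columns per sample."""

    samples: list[str]
    W: np.ndarray  # (n, 1 + k); first column all ones
    k: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.shape != (len(self.samples), 1 + self.k):
            raise ValueError("covariate matrix shape mismatch")
        if not np.allclose(self.W[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")

    def write(self, path: str) -> None:
        cols = ["intercept"] + [f"PC{i+1}" for i in range(self.k)]
        df = pd.DataFrame(self.W, index=self.samples, columns=cols)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str) -> "StructureCovariates":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(samples=[str(s) for s in df.index], W=df.to_numpy(np.float64), k=df.shape[1] - 1)


def centered_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Centered relatedness ``K = Xc Xcᵀ / p`` from imputed dosages.

    A monomorphic SNP centers to a zero column and contributes nothing;
    an input of only monomorphic SNPs is rejected because K would vanish.
    """
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("kinship requires imputed dosages (no missing entries)")
    if G.n_snps < 2:
        raise ValueError("kinship needs at least 2 SNPs")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("all SNPs are monomorphic; kinship would be zero")
    K = (Xc @ Xc.T) / G.n_snps
    K = (K + K.T) / 2.0
    return KinshipMatrix(samples=list(G.samples), K=K)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def dprime_matrix(dosages: np.ndarray, n_iter: int = 64, tol: float = 1e-12) -> np.ndarray:
    """Pairwise D′ for all columns of a dosage block (EM haplotype estimate).

    Missing calls are handled by pairwise-complete observation masks.
    Monomorphic columns yield NaN rows/columns (D′ undefined).
    """
    A = np.asarray(dosages, dtype=np.float64)
    n, w = A.shape
    M = (~np.isnan(A)).astype(np.float64)
    A0 = np.where(np.isnan(A), 0.0, A)
    H = (A0 == 1.0).astype(np.float64) * M  # double-het indicator support

    n_pair = M.T @ M  # complete pairs per column pair
    with np.errstate(invalid="ignore", divide="ignore"):
        # pairwise alt-allele frequencies
        pa = (A0.T @ M) / (2.0 * n_pair)      # freq of col-j alt over pairs with col-k
        pb = pa.T
        s_ab = A0.T @ A0                       # Σ a·b
        n_dh = H.T @ H                         # double-heterozygote pair counts
        known11 = (s_ab - n_dh) / 2.0          # unambiguous alt-alt haplotypes

        p11 = pa * pb  # independence start
        for _ in range(n_iter):
            p10 = pa - p11
            p01 = pb - p11
            p00 = 1.0 - pa - pb + p11
            num = p11 * p00
            den = num + p10 * p01
            frac = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            new11 = (known11 + frac * n_dh) / (2.0 * n_pair)
            new11 = np.clip(new11, np.maximum(0.0, pa + pb - 1.0), np.minimum(pa, pb))
            if np.nanmax(np.abs(new11 - p11)) < tol:
                p11 = new11
                break
            p11 = new11

        D = p11 - pa * pb
        dmax_pos = np.minimum(pa * (1.0 - pb), (1.0 - pa) * pb)
        dmax_neg = np.minimum(pa * pb, (1.0 - pa) * (1.0 - pb))
        dmax = np.where(D >= 0, dmax_pos, dmax_neg)
        dp = np.where(dmax > 0, np.abs(D) / np.where(dmax > 0, dmax, 1.0), np.nan)
    poly = np.array([(pa[j, j] > 0) and (pa[j, j] < 1) for j in range(w)])
    dp[~poly, :] = np.nan
    dp[:, ~poly] = np.nan
    np.fill_diagonal(dp, 1.0)
    return np.clip(dp, 0.0, 1.0)


def ld_dprime(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Normalized LD coefficient |D|/Dmax between two dosage columns."""
    dp = dprime_matrix(np.column_stack([np.asarray(col_a, float), np.asarray(col_b, float)]))
    val = dp[0, 1]
    if np.isnan(val):
        raise ValueError("D' undefined for a monomorphic column")
    return float(val)


def prune_by_dprime(
    G: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    threshold: float = 0.8,
) -> list[int]:
    """Sliding-window D′ pruning to an approximately independent SNP set.

    Within each window the later SNP of any pair with D′ >= threshold is
    dropped (greedy, position-ordered, deterministic); windows advance by
    ``step_snps``.  Returns sorted indices of retained SNPs.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if window_snps < 2:
        raise ValueError("window must cover at least 2 SNPs")
    p = G.n_snps
    keep = np.ones(p, dtype=bool)
    starts = range(0, max(p - window_snps, 0) + 1, step_snps) if p > window_snps else [0]
    for start in starts:
        idx = [j for j in range(start, min(start + window_snps, p)) if keep[j]]
        if len(idx) < 2:
            continue
        dp = dprime_matrix(G.dosages[:, idx])
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and dp[a, b] >= threshold:
                    keep[idx[b]] = False
    retained = [j for j in range(p) if keep[j]]
    logger.info("prune_by_dprime: retained %d/%d SNPs (D' < %g)", len(retained), p, threshold)
    return retained


def pca_covariates(
    G_pruned: GenotypeMatrix,
    k: int = 4,
    standardize: bool = False,
) -> StructureCovariates:
    """Principal-component structure covariates from a pruned SNP set.

    PCs are eigenvectors of the sample covariance of the centered
    (optionally unit-variance standardized) dosage matrix, ordered by
    decreasing eigenvalue; sample scores are returned with an intercept
    column prepended.
    """
    X = G_pruned.dosages
    if np.isnan(X).any():
        raise ValueError("PCA requires imputed dosages")
    n = X.shape[0]
    if k >= min(n, X.shape[1]):
        raise ValueError(f"k={k} must be < min(n_samples, n_snps)")
    Xc = X - X.mean(axis=0, keepdims=True)
    if standardize:
        sd = Xc.std(axis=0, ddof=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k >= rank:
        raise ValueError(f"k={k} must be below the matrix rank ({rank})")
    scores = U[:, :k] * s[:k]
    # sign convention: largest-|loading| score positive, for reproducibility
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    W = np.column_stack([np.ones(n), scores])
    return StructureCovariates(samples=list(G_pruned.samples), W=W, k=k)
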
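"""Bayesian sparse linear mixed model fitted by MCMC.

The model decomposes a quantitative trait into a sparse set of
major-effect SNPs, a polygenic background, and residual noise::

    y = Wα + X β̃ + u + ε,
    β̃_j ~ π N(0, σ_a² τ⁻¹) + (1 − π) δ₀,
    u   ~ N(0, σ_b² τ⁻¹ K),
    ε   ~ N(0, τ⁻¹ I)

with hyperpriors h ~ U(0,1) (approximate PVE), ρ ~ U(0,1) (approximate
PGE, the sparse share of genetic variance) and log π uniform on
[log(1/p), 0].  σ_a² and σ_b² are deterministic functions of (h, ρ, π)
chosen so that h and ρ approximate PVE and PGE at the observed SNP
variances:

    σ_a² = ρ·h/(1−h) / (π p s̄x),    σ_b² = (1−ρ)·h/(1−h) / (tr K / n)

where s̄x is the mean SNP dosage variance.

Sampling is Metropolis–Hastings over (γ, h, ρ, log π) with β̃, u, τ and
the covariates integrated out analytically: covariates are projected out
of y and X up front, K is eigendecomposed once, and in the rotated basis
the marginal likelihood of a sparse set γ needs only a |γ| × |γ|
Cholesky.  γ moves are add/delete/swap with geometric multi-SNP
compounds; h, ρ and log π take reflected random walks.  At each recorded
(thinned) iteration τ, β̃ and u are drawn from their exact conditionals
and the realized variance fractions are recorded as

    PVE = s(Xβ̃ + u) / (s(Xβ̃ + u) + τ⁻¹),    PGE = s(Xβ̃) / s(Xβ̃ + u)

with s(·) the in-sample variance.  Repeat chains with distinct seeds are
summarised by medians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genotype_io import GenotypeMatrix, PhenotypeVector
from .relatedness import KinshipMatrix, StructureCovariates

logger = logging.getLogger("pathgwa")

__all__ = [
    "BslmmConfig",
    "BslmmPosterior",
    "MajorEffectCall",
    "bslmm_fit",
    "bslmm_fit_single",
    "aggregate_chains",
    "sparse_effect",
    "hpdi",
    "classify_major",
]

HYP_COLUMNS = ("h", "pve", "rho", "pge", "pi", "n_gamma")


@dataclass
class BslmmConfig:
    """MCMC settings; defaults are the long production settings
    (500k burn-in, 5M steps, thin 100, 10 chains)."""

    burn_in: int = 500_000
    steps: int = 5_000_000
    record_pace: int = 100
    chains: int = 10
    seed: int = 1
    s_max: int = 300  # cap on the sparse set size
    pi_log10_bounds: tuple[float, float] | None = None  # default (-log10 p, 0)
    step_h: float = 0.1
    step_rho: float = 0.1
    step_logpi: float = 0.5  # natural-log units
    p_gamma_move: float = 0.9  # fraction of iterations proposing a γ change
    geometric_p: float = 0.7  # multi-SNP move length ~ Geometric(p), capped at 4
    project_covariates: bool = True  # project the PCs as well as the intercept
    prior_only: bool = False  # constant likelihood; used for prior-recovery checks

    def __post_init__(self) -> None:
        if min(self.burn_in, self.steps, self.record_pace, self.chains) < 1:
            raise ValueError("burn_in, steps, record_pace and chains must be >= 1")

    @property
    def n_records(self) -> int:
        return self.steps // self.record_pace


@dataclass
class BslmmPosterior:
    """Posterior summary of one chain (or of aggregated chains)."""

    snp_ids: list[str]
    chroms: list[str]
    positions: list[int]
    hyp: pd.DataFrame  # recorded samples, columns HYP_COLUMNS
    pip: np.ndarray  # per-SNP posterior inclusion probability
    beta_mean: np.ndarray  # per-SNP mean sparse effect, conditional on inclusion
    beta_samples: list[np.ndarray]  # per-SNP conditional effect draws
    alpha: np.ndarray  # per-SNP polygenic effect (posterior-mean approximation)
    n_chains: int = 1
    point_estimates: dict[str, float] | None = None

    def point_estimate(self, name: str) -> float:
        """Median point estimate (median of per-chain medians after
        aggregation)."""
        if self.point_estimates is not None and name in self.point_estimates:
            return self.point_estimates[name]
        return float(np.median(self.hyp[name].to_numpy()))

    def hyperparameter_interval(self, name: str, mass: float = 0.95, mode: str = "central"):
        return hpdi(self.hyp[name].to_numpy(), mass=mass, mode=mode)

    def sparse_effects(self) -> np.ndarray:
        """|β × γ| per SNP."""
        return np.abs(self.beta_mean * self.pip)

    def effect_hpdi(self, j: int, mass: float = 0.95, mode: str = "central"):
        """Effect interval for SNP j from its conditional draws; ``None``
        when the SNP entered fewer than 10 recorded samples."""
        s = self.beta_samples[j]
        if s.size < 10:
            return None
        return hpdi(s, mass=mass, mode=mode)

    def param_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos": self.positions,
                "id": self.snp_ids,
                "alpha": self.alpha,
                "beta": self.beta_mean,
                "gamma": self.pip,
            }
        )

    def write_hyp(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# hyperparameter trace, one row per recorded iteration\n")
            self.hyp.to_csv(fh, sep="\t", index=False)

    def write_param(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# per-SNP posterior summaries\n")
            self.param_frame().to_csv(fh, sep="\t", index=False)


@dataclass
class MajorEffectCall:
    snp_id: str
    pip: float
    sparse_effect: float  # |β × γ|
    hpdi_lo: float
    hpdi_hi: float
    is_major: bool


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _chol_inplace(C, q):
    """Lower Cholesky of C[:q,:q] in place; False on failure."""
    for k in range(q):
        s = C[k, k]
        for m in range(k):
            s -= C[k, m] * C[k, m]
        if s <= 0.0:
            return False
        C[k, k] = math.sqrt(s)
        for i in range(k + 1, q):
            t = C[i, k]
            for m in range(k):
                t -= C[i, m] * C[k, m]
            C[i, k] = t / C[k, k]
    return True


@njit(cache=True)
def _forward_solve(L, rhs, out, q):
    for i in range(q):
        t = rhs[i]
        for m in range(i):
            t -= L[i, m] * out[m]
        out[i] = t / L[i, i]


@njit(cache=True)
def _backward_solve(L, rhs, out, q):
    for i in range(q - 1, -1, -1):
        t = rhs[i]
        for m in range(i + 1, q):
            t -= L[m, i] * out[m]
        out[i] = t / L[i, i]


@njit(cache=True)
def _bslmm_kernel(
    yt, XT, d, ut1, n_eff, sx_mean, mK,
    burn_in, steps, pace, seed,
    s_max, logpi_lo, logpi_hi,
    step_h, step_rho, step_logpi, p_gamma_move, geom_p,
    prior_only,
):
    """Sampler core in the eigen-rotated, covariate-projected basis.

    ``XT`` is the (p, n) transposed rotated genotype matrix so each SNP's
    column is a contiguous row.  Returns the recorded hyperparameter
    trace, per-record sparse-set contents with effect draws, and
    acceptance counters.
    """
    np.random.seed(seed)
    n = yt.shape[0]
    p = XT.shape[0]
    smax = min(s_max, p)
    n_rec = steps // pace

    hyp = np.zeros((n_rec, 6))
    rec_q = np.zeros(n_rec, dtype=np.int64)
    rec_snp = np.full((n_rec, smax), -1, dtype=np.int64)
    rec_beta = np.zeros((n_rec, smax))

    # state
    h = np.random.rand()
    rho = np.random.rand()
    logpi = logpi_lo + np.random.rand() * (logpi_hi - logpi_lo)
    q = 0
    idx = np.full(smax, -1, dtype=np.int64)
    incl = np.zeros(p, dtype=np.bool_)
    A = np.zeros((smax, smax))
    b = np.zeros(smax)
    idx_p = np.full(smax, -1, dtype=np.int64)
    A_p = np.zeros((smax, smax))
    b_p = np.zeros(smax)
    touched = np.empty(16, dtype=np.int64)

    w = np.empty(n)
    wy = np.empty(n)
    wx = np.empty(n)
    Xg = np.zeros((smax, n))  # rows = rotated columns of the included SNPs
    Xg_p = np.zeros((smax, n))
    Xw = np.zeros((smax, n))
    C = np.zeros((smax, smax))
    tmp1 = np.zeros(smax)
    tmp2 = np.zeros(smax)
    xbuf = np.zeros(n)

    def _sigmas(hv, rv, lpv):
        hh = min(max(hv, 1e-8), 1.0 - 1e-8)
        gtot = hh / (1.0 - hh)
        piv = math.exp(lpv)
        sa2 = rv * gtot / (piv * p * sx_mean) if piv * p * sx_mean > 0.0 else 0.0
        sb2 = (1.0 - rv) * gtot / mK if mK > 0.0 else 0.0
        return sa2, sb2

    def _weights(sb2):
        """Fill w (and wy) with 1/(σb²d+1); return (yᵀΛ⁻¹y, Σ log λ_i)."""
        yy = 0.0
        ld = 0.0
        for i in range(n):
            v = sb2 * d[i] + 1.0
            w[i] = 1.0 / v
            wy[i] = yt[i] * w[i]
            ld += math.log(v)
            yy += yt[i] * wy[i]
        return yy, ld

    def _rebuild(Adst, bdst, Xrows, qq):
        """A = Xγᵀ Λ⁻¹ Xγ and b = Xγᵀ Λ⁻¹ y for the rows in Xrows (BLAS)."""
        if qq == 0:
            return
        for k in range(qq):
            for i in range(n):
                Xw[k, i] = Xrows[k, i] * w[i]
        bnew = np.dot(Xrows[:qq], wy)
        Anew = np.dot(Xw[:qq], Xrows[:qq].T)
        for k in range(qq):
            bdst[k] = bnew[k]
            for l in range(qq):
                Adst[k, l] = Anew[k, l]

    def _add_snp(Adst, bdst, Xrows, qq, j):
        """Fill slot qq with SNP j; Xrows[qq] must already hold its column."""
        s_b = 0.0
        for i in range(n):
            wx[i] = XT[j, i] * w[i]
            s_b += wx[i] * yt[i]
        bdst[qq] = s_b
        row = np.dot(Xrows[: qq + 1], wx)
        for k in range(qq + 1):
            Adst[qq, k] = row[k]
            Adst[k, qq] = row[k]

    def _loglik(Amat, bvec, qq, yy, ld, sa2, lpv):
        piv = math.exp(lpv)
        piv = min(piv, 1.0 - 1e-12)
        lp = qq * math.log(piv) + (p - qq) * math.log(1.0 - piv)
        if prior_only:
            return lp
        quad = 0.0
        logdetC = 0.0
        if qq > 0 and sa2 > 0.0:
            for k in range(qq):
                for l in range(qq):
                    C[k, l] = sa2 * Amat[k, l]
                C[k, k] += 1.0
            if not _chol_inplace(C, qq):
                return -np.inf
            for k in range(qq):
                logdetC += 2.0 * math.log(C[k, k])
            _forward_solve(C, bvec, tmp1, qq)
            for k in range(qq):
                quad += tmp1[k] * tmp1[k]
            quad *= sa2
        rss = yy - quad
        if rss <= 0.0:
            return -np.inf
        return -0.5 * ld - 0.5 * logdetC - 0.5 * n_eff * math.log(rss) + lp

    sa2, sb2 = _sigmas(h, rho, logpi)
    yy, ld = _weights(sb2)
    ll_cur = _loglik(A, b, q, yy, ld, sa2, logpi)

    acc_gamma = 0
    acc_hyper = 0
    rec_i = 0
    total = burn_in + steps

    for t in range(total):
        if np.random.rand() < p_gamma_move:
            # ---- γ move ----
            m = np.random.geometric(geom_p)
            if m > 4:
                m = 4
            qp = q
            for k in range(q):
                idx_p[k] = idx[k]
                b_p[k] = b[k]
                for l in range(q):
                    A_p[k, l] = A[k, l]
                for i in range(n):
                    Xg_p[k, i] = Xg[k, i]
            tcount = 0
            log_hastings = 0.0
            for _ in range(m):
                if qp == 0:
                    padd, pdel, pswap = 1.0, 0.0, 0.0
                elif qp >= p:
                    padd, pdel, pswap = 0.0, 1.0, 0.0
                elif qp >= smax:
                    padd, pdel, pswap = 0.0, 2.0 / 3.0, 1.0 / 3.0
                else:
                    padd, pdel, pswap = 0.4, 0.4, 0.2
                uu = np.random.rand()
                if uu < padd:
                    j = np.random.randint(p)
                    while incl[j]:
                        j = np.random.randint(p)
                    if qp + 1 >= p:
                        rdel = 1.0
                    elif qp + 1 >= smax:
                        rdel = 2.0 / 3.0
                    else:
                        rdel = 0.4
                    log_hastings += math.log(rdel / (qp + 1.0)) - math.log(padd / (p - qp))
                    idx_p[qp] = j
                    for i in range(n):
                        Xg_p[qp, i] = XT[j, i]
                    _add_snp(A_p, b_p, Xg_p, qp, j)
                    incl[j] = True
                    touched[tcount] = j
                    tcount += 1
                    qp += 1
                elif uu < padd + pdel:
                    kdel = np.random.randint(qp)
                    if qp - 1 == 0:
                        radd = 1.0
                    else:
                        radd = 0.4
                    log_hastings += math.log(radd / (p - qp + 1.0)) - math.log(pdel / qp)
                    jdel = idx_p[kdel]
                    incl[jdel] = False
                    touched[tcount] = jdel
                    tcount += 1
                    last = qp - 1
                    if kdel != last:  # move last slot into the hole
                        idx_p[kdel] = idx_p[last]
                        b_p[kdel] = b_p[last]
                        for i in range(n):
                            Xg_p[kdel, i] = Xg_p[last, i]
                        for l in range(qp):
                            A_p[kdel, l] = A_p[last, l]
                        for l in range(qp):
                            A_p[l, kdel] = A_p[l, last]
                    qp -= 1
                else:
                    # swap: overwrite one slot with a new SNP (symmetric)
                    kdel = np.random.randint(qp)
                    j = np.random.randint(p)
                    while incl[j]:
                        j = np.random.randint(p)
                    jdel = idx_p[kdel]
                    incl[jdel] = False
                    touched[tcount] = jdel
                    tcount += 1
                    idx_p[kdel] = j
                    for i in range(n):
                        Xg_p[kdel, i] = XT[j, i]
                    s_b = 0.0
                    for i in range(n):
                        wx[i] = XT[j, i] * w[i]
                        s_b += wx[i] * yt[i]
                    b_p[kdel] = s_b
                    row = np.dot(Xg_p[:qp], wx)
                    for k in range(qp):
                        A_p[kdel, k] = row[k]
                        A_p[k, kdel] = row[k]
                    incl[j] = True
                    touched[tcount] = j
                    tcount += 1
            ll_prop = _loglik(A_p, b_p, qp, yy, ld, sa2, logpi)
            if math.log(np.random.rand() + 1e-300) < ll_prop - ll_cur + log_hastings:
                acc_gamma += 1
                ll_cur = ll_prop
                q = qp
                idx, idx_p = idx_p, idx
                A, A_p = A_p, A
                b, b_p = b_p, b
                Xg, Xg_p = Xg_p, Xg
            else:
                for k in range(tcount - 1, -1, -1):  # revert inclusion flags
                    incl[touched[k]] = not incl[touched[k]]
        else:
            # ---- hyper move: reflected random walk on (h, ρ, log π) ----
            hp = h + (np.random.rand() - 0.5) * 2.0 * step_h
            while hp < 0.0 or hp > 1.0:
                if hp < 0.0:
                    hp = -hp
                if hp > 1.0:
                    hp = 2.0 - hp
            rp = rho + (np.random.rand() - 0.5) * 2.0 * step_rho
            while rp < 0.0 or rp > 1.0:
                if rp < 0.0:
                    rp = -rp
                if rp > 1.0:
                    rp = 2.0 - rp
            lpp = logpi + (np.random.rand() - 0.5) * 2.0 * step_logpi
            if logpi_hi > logpi_lo:
                while lpp < logpi_lo or lpp > logpi_hi:
                    if lpp < logpi_lo:
                        lpp = 2.0 * logpi_lo - lpp
                    if lpp > logpi_hi:
                        lpp = 2.0 * logpi_hi - lpp
            else:
                lpp = logpi
            sa2_p, sb2_p = _sigmas(hp, rp, lpp)
            if prior_only:
                ll_prop = _loglik(A, b, q, yy, ld, sa2_p, lpp)
                if math.log(np.random.rand() + 1e-300) < ll_prop - ll_cur:
                    acc_hyper += 1
                    ll_cur = ll_prop
                    h, rho, logpi = hp, rp, lpp
            else:
                yy_p, ld_p = _weights(sb2_p)  # w now holds proposal weights
                _rebuild(A_p, b_p, Xg, q)
                ll_prop = _loglik(A_p, b_p, q, yy_p, ld_p, sa2_p, lpp)
                if math.log(np.random.rand() + 1e-300) < ll_prop - ll_cur:
                    acc_hyper += 1
                    ll_cur = ll_prop
                    h, rho, logpi = hp, rp, lpp
                    sa2, sb2 = sa2_p, sb2_p
                    yy, ld = yy_p, ld_p
                    for k in range(q):
                        b[k] = b_p[k]
                        for l in range(q):
                            A[k, l] = A_p[k, l]
                else:
                    yy, ld = _weights(sb2)  # restore current-state weights

        # ---- record ----
        if t >= burn_in and (t - burn_in) % pace == pace - 1 and rec_i < n_rec:
            piv = math.exp(logpi)
            if prior_only:
                hyp[rec_i, 0] = h
                hyp[rec_i, 1] = 0.0
                hyp[rec_i, 2] = rho
                hyp[rec_i, 3] = 0.0
                hyp[rec_i, 4] = piv
                hyp[rec_i, 5] = q
                rec_q[rec_i] = 0
                rec_i += 1
            else:
                quad = 0.0
                have_chol = False
                if q > 0 and sa2 > 0.0:
                    for k in range(q):
                        for l in range(q):
                            C[k, l] = sa2 * A[k, l]
                        C[k, k] += 1.0
                    have_chol = _chol_inplace(C, q)
                    if have_chol:
                        _forward_solve(C, b, tmp1, q)
                        for k in range(q):
                            quad += tmp1[k] * tmp1[k]
                        quad *= sa2
                rss = yy - quad
                if rss <= 0.0:
                    rss = 1e-300
                tau = np.random.gamma(0.5 * n_eff, 2.0 / rss)
                if have_chol:
                    _backward_solve(C, tmp1, tmp2, q)  # C⁻¹ b
                    for k in range(q):
                        tmp2[k] *= sa2  # posterior mean of β̃
                    for k in range(q):
                        tmp1[k] = np.random.normal(0.0, 1.0)
                    _backward_solve(C, tmp1, tmp1, q)  # L⁻ᵀ z ~ N(0, C⁻¹)
                    sc = math.sqrt(sa2 / tau)
                    for k in range(q):
                        tmp2[k] += sc * tmp1[k]
                else:
                    for k in range(q):
                        tmp2[k] = 0.0
                for i in range(n):
                    xbuf[i] = 0.0
                for k in range(q):
                    bk = tmp2[k]
                    for i in range(n):
                        xbuf[i] += Xg[k, i] * bk
                sxb = 0.0
                sxb2 = 0.0
                sg = 0.0
                sg2 = 0.0
                for i in range(n):
                    r_i = yt[i] - xbuf[i]
                    coef = sb2 * d[i] / (sb2 * d[i] + 1.0) if sb2 > 0.0 else 0.0
                    u_i = coef * r_i
                    if coef > 0.0:
                        u_i += math.sqrt(coef / tau) * np.random.normal(0.0, 1.0)
                    g_i = xbuf[i] + u_i
                    sxb += xbuf[i] * ut1[i]
                    sxb2 += xbuf[i] * xbuf[i]
                    sg += g_i * ut1[i]
                    sg2 += g_i * g_i
                v_xb = max(sxb2 / n - sxb * sxb, 0.0)
                v_g = max(sg2 / n - sg * sg, 0.0)
                pve_t = v_g / (v_g + 1.0 / tau)
                pge_t = min(v_xb / v_g, 1.0) if v_g > 0.0 else 0.0
                hyp[rec_i, 0] = h
                hyp[rec_i, 1] = pve_t
                hyp[rec_i, 2] = rho
                hyp[rec_i, 3] = pge_t
                hyp[rec_i, 4] = piv
                hyp[rec_i, 5] = q
                rec_q[rec_i] = q
                for k in range(q):
                    rec_snp[rec_i, k] = idx[k]
                    rec_beta[rec_i, k] = tmp2[k]
                rec_i += 1

    return hyp, rec_q, rec_snp, rec_beta, acc_gamma, acc_hyper


# ---------------------------------------------------------------------------
# python wrapper
# ---------------------------------------------------------------------------


def _project_out(M: np.ndarray, W: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(W)
    return M - Q @ (Q.T @ M)


def bslmm_fit_single(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    K: KinshipMatrix,
    W: StructureCovariates | None,
    config: BslmmConfig,
    seed: int | None = None,
) -> BslmmPosterior:
    """Run one MCMC chain and summarise its posterior.

    Covariates enter as fixed effects projected out of y and X before
    sampling (the standard equivalent of including them in the model);
    with ``config.project_covariates`` False only the intercept is
    projected.
    """
    if G.n_snps < 2:
        raise ValueError("BSLMM needs at least 2 SNPs")
    if W is not None and not (G.samples == y.samples == K.samples == W.samples):
        raise ValueError("sample order differs between inputs")
    if W is None and not (G.samples == y.samples == K.samples):
        raise ValueError("sample order differs between inputs")
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("BSLMM requires imputed dosages")
    n, p = X.shape
    yv = np.asarray(y.values, float)

    if W is not None and config.project_covariates:
        Wm = W.W
    else:
        Wm = np.ones((n, 1))
    c = Wm.shape[1]
    yp = _project_out(yv[:, None], Wm)[:, 0]
    Xp = _project_out(X, Wm)

    d, U = np.linalg.eigh((K.K + K.K.T) / 2.0)
    if d.min() < -1e-8:
        raise ValueError(f"kinship not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    yt = U.T @ yp
    XT = np.ascontiguousarray((U.T @ Xp).T)
    ut1 = (U.T @ np.ones(n)) / n

    sx_mean = float(np.var(X, axis=0).mean())
    if sx_mean <= 0:
        raise ValueError("all SNPs are monomorphic")
    mK = float(np.trace(K.K)) / n
    n_eff = n - c

    if config.pi_log10_bounds is not None:
        logpi_lo = math.log(10.0) * config.pi_log10_bounds[0]
        logpi_hi = math.log(10.0) * config.pi_log10_bounds[1]
    else:
        logpi_lo, logpi_hi = math.log(1.0 / p), 0.0

    kernel_seed = int((config.seed if seed is None else seed) % (2**31))
    hyp_arr, rec_q, rec_snp, rec_beta, acc_g, acc_h = _bslmm_kernel(
        yt, XT, d, ut1, float(n_eff), sx_mean, mK,
        config.burn_in, config.steps, config.record_pace, kernel_seed,
        config.s_max, logpi_lo, logpi_hi,
        config.step_h, config.step_rho, config.step_logpi,
        config.p_gamma_move, config.geometric_p,
        config.prior_only,
    )
    n_rec = hyp_arr.shape[0]
    logger.info(
        "bslmm chain seed=%d: %d records, acceptance γ=%.2f hyper=%.2f, mean n_gamma=%.2f",
        kernel_seed, n_rec,
        acc_g / max(config.p_gamma_move * (config.burn_in + config.steps), 1),
        acc_h / max((1 - config.p_gamma_move) * (config.burn_in + config.steps), 1),
        float(hyp_arr[:, 5].mean()),
    )

    hyp = pd.DataFrame(hyp_arr, columns=list(HYP_COLUMNS))

    # gather per-SNP inclusion draws
    mask = rec_snp >= 0
    snp_flat = rec_snp[mask]
    beta_flat = rec_beta[mask]
    counts = np.bincount(snp_flat, minlength=p)
    pip = counts / n_rec
    sums = np.bincount(snp_flat, weights=beta_flat, minlength=p)
    beta_mean = np.divide(sums, counts, out=np.zeros(p), where=counts > 0)
    order = np.argsort(snp_flat, kind="stable")
    sorted_beta = beta_flat[order]
    splits = np.cumsum(counts)[:-1]
    per_snp = np.split(sorted_beta, splits)
    beta_samples = [np.asarray(s) for s in per_snp]

    # polygenic per-SNP effect, posterior-mean approximation:
    # E[ã | r] = (σb²/p) Xᵀ (σb²K + I)⁻¹ r at the posterior-median h, ρ
    h_med = float(np.median(hyp_arr[:, 0]))
    rho_med = float(np.median(hyp_arr[:, 2]))
    gtot = min(max(h_med, 1e-8), 1 - 1e-8) / (1.0 - min(max(h_med, 1e-8), 1 - 1e-8))
    sb2_med = (1.0 - rho_med) * gtot / mK if mK > 0 else 0.0
    resid = yt - XT.T @ (pip * beta_mean)
    alpha = (sb2_med / p) * (XT @ (resid / (sb2_med * d + 1.0)))

    return BslmmPosterior(
        snp_ids=G.snp_ids,
        chroms=[s.chrom for s in G.snps],
        positions=[s.pos for s in G.snps],
        hyp=hyp,
        pip=pip,
        beta_mean=beta_mean,
        beta_samples=beta_samples,
        alpha=alpha,
        n_chains=1,
    )


def bslmm_fit(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    K: KinshipMatrix,
    W: StructureCovariates | None,
    config: BslmmConfig,
) -> BslmmPosterior:
    """Fit ``config.chains`` repeat chains (chain i seeded base_seed + i)
    and aggregate them by medians."""
    chains = [
        bslmm_fit_single(G, y, K, W, config, seed=config.seed + i)
        for i in range(config.chains)
    ]
    return chains[0] if len(chains) == 1 else aggregate_chains(chains)


def aggregate_chains(posteriors: list[BslmmPosterior]) -> BslmmPosterior:
    """Median aggregation of repeat chains fitted on identical data.

    Hyperparameter point estimates are medians of the per-chain medians;
    per-SNP PIPs are per-SNP medians across chains; effect draws and the
    hyperparameter trace are pooled, so intervals come from the pooled
    samples by default.
    """
    if not posteriors:
        raise ValueError("no chains to aggregate")
    ids0 = posteriors[0].snp_ids
    for po in posteriors[1:]:
        if po.snp_ids != ids0:
            raise ValueError("chains were fitted on different SNP sets")
    p = len(ids0)
    hyp = pd.concat([po.hyp for po in posteriors], ignore_index=True)
    point = {
        name: float(np.median([po.point_estimate(name) for po in posteriors]))
        for name in HYP_COLUMNS
    }
    pip = np.median(np.vstack([po.pip for po in posteriors]), axis=0)
    beta_samples = [
        np.concatenate([po.beta_samples[j] for po in posteriors]) for j in range(p)
    ]
    beta_mean = np.array([s.mean() if s.size else 0.0 for s in beta_samples])
    alpha = np.median(np.vstack([po.alpha for po in posteriors]), axis=0)
    return BslmmPosterior(
        snp_ids=list(ids0),
        chroms=list(posteriors[0].chroms),
        positions=list(posteriors[0].positions),
        hyp=hyp,
        pip=pip,
        beta_mean=beta_mean,
        beta_samples=beta_samples,
        alpha=alpha,
        n_chains=sum(po.n_chains for po in posteriors),
        point_estimates=point,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def sparse_effect(beta_mean: float, pip: float) -> float:
    """Inclusion-weighted effect magnitude |β × γ|."""
    if not (0.0 <= pip <= 1.0):
        raise ValueError("pip must be in [0, 1]")
    return abs(beta_mean * pip)


def hpdi(samples: np.ndarray, mass: float = 0.95, mode: str = "central") -> tuple[float, float]:
    """Posterior interval: ``"central"`` takes the (1−mass)/2 and
    1−(1−mass)/2 quantiles (2.5/97.5% at the default mass); ``"hpd"``
    returns the shortest interval containing the mass."""
    s = np.sort(np.asarray(samples, float))
    if s.size < 10:
        raise ValueError(f"need >= 10 samples for an interval, got {s.size}")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    if mode == "central":
        lo = float(np.quantile(s, (1.0 - mass) / 2.0))
        hi = float(np.quantile(s, 1.0 - (1.0 - mass) / 2.0))
        return lo, hi
    if mode == "hpd":
        m = int(math.ceil(mass * s.size))  # samples the interval must hold
        if m >= s.size:
            return float(s[0]), float(s[-1])
        widths = s[m - 1:] - s[: s.size - m + 1]
        j = int(np.argmin(widths))
        return float(s[j]), float(s[j + m - 1])
    raise ValueError(f"unknown interval mode {mode!r}")


def classify_major(
    posterior: BslmmPosterior,
    pip_threshold: float = 0.10,
    mass: float = 0.95,
    mode: str = "central",
) -> list[MajorEffectCall]:
    """Apply the major-effect rule: PIP >= threshold AND the effect
    interval does not overlap zero.  A SNP whose conditional effect has
    fewer than 10 draws cannot establish a directional effect and is
    never called major.  Output sorted by |β × γ| descending."""
    calls = []
    effects = posterior.sparse_effects()
    for j, sid in enumerate(posterior.snp_ids):
        interval = posterior.effect_hpdi(j, mass=mass, mode=mode)
        if interval is None:
            lo, hi = 0.0, 0.0
            is_major = False
        else:
            lo, hi = interval
            is_major = bool(posterior.pip[j] >= pip_threshold and not (lo <= 0.0 <= hi))
        calls.append(
            MajorEffectCall(
                snp_id=sid,
                pip=float(posterior.pip[j]),
                sparse_effect=float(effects[j]),
                hpdi_lo=lo,
                hpdi_hi=hi,
                is_major=is_major,
            )
        )
    calls.sort(key=lambda cc: -cc.sparse_effect)
    return calls
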
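import math

import numpy as np
import pytest
from scipy import stats

from pathgwa.genotype_io import PhenotypeVector
from pathgwa.lmm import (
    LmmSnpResult, blocks_from_bed, blocks_from_dprime, estimate_h2, gao_meff,
    lmm_associate, reml_lambda, subset_by_rank, subset_union,
)
from pathgwa.relatedness import KinshipMatrix, StructureCovariates, centered_kinship, \
    pca_covariates
from pathgwa.simulate import SimulationConfig, simulate_genotypes, simulate_phenotype

from conftest import make_matrix


def _pheno(G, values):
    return PhenotypeVector(samples=list(G.samples), values=np.asarray(values, float))


def _covariates(G, k=0, rng=None):
    n = G.n_samples
    if k == 0:
        return StructureCovariates(samples=list(G.samples), W=np.ones((n, 1)), k=0)
    cols = rng.standard_normal((n, k))
    cols -= cols.mean(axis=0)
    return StructureCovariates(samples=list(G.samples), W=np.column_stack([np.ones(n), cols]), k=k)


class TestLmmAssociate:
    def test_zero_kinship_equals_ols_oracle(self):
        rng = np.random.default_rng(1)
        n, p = 30, 8
        G = make_matrix(rng.integers(0, 3, (n, p)).astype(float))
        y = _pheno(G, rng.standard_normal(n))
        K = KinshipMatrix(samples=list(G.samples), K=np.zeros((n, n)))
        W = _covariates(G, k=2, rng=rng)
        results = lmm_associate(G, y, K, W)
        for j, r in enumerate(results):
            F = np.column_stack([W.W, G.dosages[:, j]])
            coef, _, _, _ = np.linalg.lstsq(F, y.values, rcond=None)
            resid = y.values - F @ coef
            df = n - F.shape[1]
            s2 = resid @ resid / df
            cov = s2 * np.linalg.inv(F.T @ F)
            se = math.sqrt(cov[-1, -1])
            p_ols = stats.f.sf((coef[-1] / se) ** 2, 1, df)
            assert r.beta == pytest.approx(coef[-1], abs=1e-8)
            assert r.se == pytest.approx(se, abs=1e-8)
            assert r.p_wald == pytest.approx(p_ols, rel=1e-6)

    def test_exact_linear_fit_recovers_beta(self):
        rng = np.random.default_rng(2)
        n = 40
        x = rng.integers(0, 3, n).astype(float)
        G = make_matrix(np.column_stack([x, rng.integers(0, 3, n).astype(float)]))
        x_sorted = G.dosages[:, 0] if np.allclose(G.dosages[:, 0], x) else G.dosages[:, 1]
        y = _pheno(G, 2.0 * x + 1.0)
        K = KinshipMatrix(samples=list(G.samples), K=np.zeros((n, n)))
        W = _covariates(G)
        r = [res for res in lmm_associate(G, y, K, W) if np.allclose(G.dosages[:, 0], x)][0]
        assert r.beta == pytest.approx(2.0, abs=1e-10)
        assert r.p_wald <= 1e-100

    def test_fixed_lambda_matches_gls_oracle(self):
        rng = np.random.default_rng(3)
        n, p = 20, 6
        G = make_matrix(rng.integers(0, 3, (n, p)).astype(float))
        K = centered_kinship(G)
        W = _covariates(G, k=2, rng=rng)
        y = _pheno(G, rng.standard_normal(n))
        results = lmm_associate(G, y, K, W, fix_lambda=1.0)
        V = K.K + np.eye(n)
        Vi = np.linalg.inv(V)
        for j, r in enumerate(results):
            F = np.column_stack([W.W, G.dosages[:, j]])
            A = F.T @ Vi @ F
            coef = np.linalg.solve(A, F.T @ Vi @ y.values)
            resid = y.values - F @ coef
            df = n - F.shape[1]
            s2 = resid @ Vi @ resid / df
            se = math.sqrt(s2 * np.linalg.inv(A)[-1, -1])
            assert r.beta == pytest.approx(coef[-1], abs=1e-8)
            assert r.se == pytest.approx(se, abs=1e-8)

    def test_invariant_to_consistent_sample_reordering(self, small_panel, small_panel_model):
        _, G, y, _ = small_panel
        K, W = small_panel_model
        res1 = lmm_associate(G, y, K, W)
        perm = list(np.random.default_rng(8).permutation(G.n_samples))
        G2 = G.take_samples(perm)
        y2 = PhenotypeVector(samples=[y.samples[i] for i in perm], values=y.values[perm])
        K2 = KinshipMatrix(samples=[K.samples[i] for i in perm],
                           K=K.K[np.ix_(perm, perm)])
        W2 = StructureCovariates(samples=[W.samples[i] for i in perm],
                                 W=W.W[perm], k=W.k)
        res2 = lmm_associate(G2, y2, K2, W2)
        for a, b in zip(res1, res2):
            assert a.beta == pytest.approx(b.beta, rel=1e-6, abs=1e-9)
            assert a.p_wald == pytest.approx(b.p_wald, rel=1e-4, abs=1e-12)


class TestRemlLambda:
    def test_identity_kinship_returns_finite_in_bounds(self):
        rng = np.random.default_rng(4)
        n = 50
        y = rng.standard_normal(n)
        W = np.ones((n, 1))
        lam = reml_lambda(y, None, W, K=np.eye(n))
        assert 1e-5 <= lam <= 1e5 and np.isfinite(lam)

    def test_recovers_variance_ratio_from_polygenic_simulation(self):
        # PVE 0.8, no sparse effects: truth lambda = 4 / mean-diag(K)
        errs = []
        for s in range(20):
            cfg = SimulationConfig(n_samples=200, n_snps=400, n_causal_sparse=0,
                                   pve_target=0.8, pge_target=0.0, seed=500 + s)
            G = simulate_genotypes(cfg)
            y, _ = simulate_phenotype(G, cfg)
            K = centered_kinship(G)
            mK = np.trace(K.K) / K.K.shape[0]
            lam_true = (0.8 / 0.2) / mK
            lam_hat = reml_lambda(y.values, None, np.ones((200, 1)), K=K.K)
            errs.append(abs(math.log10(lam_hat) - math.log10(lam_true)))
        assert np.median(errs) < 0.5

    def test_zero_signal_pins_lambda_low(self):
        # null REML profiles are flat near zero, so individual seeds can
        # wander; the median sits at the lower search bound
        lams = []
        for s in range(10):
            cfg = SimulationConfig(n_samples=200, n_snps=400, n_causal_sparse=0,
                                   pve_target=0.0, seed=70 + s)
            G = simulate_genotypes(cfg)
            y, _ = simulate_phenotype(G, cfg)
            K = centered_kinship(G)
            lams.append(reml_lambda(y.values, None, np.ones((200, 1)), K=K.K))
        assert np.median(lams) < 0.05
        assert min(lams) == pytest.approx(1e-5, rel=1e-6)


class TestEstimateH2:
    def test_recovers_simulated_heritability(self):
        hits = 0
        for s in range(10):
            cfg = SimulationConfig(n_samples=500, n_snps=500, n_causal_sparse=0,
                                   pve_target=0.5, pge_target=0.0, seed=900 + s)
            G = simulate_genotypes(cfg)
            y, _ = simulate_phenotype(G, cfg)
            K = centered_kinship(G)
            W = StructureCovariates(samples=list(G.samples), W=np.ones((500, 1)), k=0)
            h2, (lo, hi) = estimate_h2(y, K, W)
            assert lo <= h2 <= hi
            hits += 0.3 <= h2 <= 0.7
        assert hits >= 8


class TestGaoMeff:
    def test_block_of_duplicates_contributes_one(self):
        rng = np.random.default_rng(5)
        base = (rng.random(100) < 0.4).astype(float) * 2
        G = make_matrix(np.column_stack([base] * 10))
        th = gao_meff(G, [list(range(10))], mode="simpleM")
        assert th.m_eff == 1

    def test_uncorrelated_block_contributes_all(self):
        # Walsh-Hadamard design: exactly orthogonal mean-centered columns
        from scipy.linalg import hadamard
        H = hadamard(32)[:, 1:11]
        G = make_matrix((H + 1.0))  # dosages in {0, 2}
        th = gao_meff(G, [list(range(10))], mode="simpleM")
        assert th.m_eff == 10

    def test_two_block_fixture_matches_eigen_oracle(self):
        rng = np.random.default_rng(6)
        n = 400
        blocks = []
        cols = []
        start = 0
        for size in (4, 6):
            f = rng.standard_normal(n)
            latent = np.sqrt(0.99) * f[:, None] + np.sqrt(0.01) * rng.standard_normal((n, size))
            cols.append((latent < 0).astype(float) * 2)
            blocks.append(list(range(start, start + size)))
            start += size
        G = make_matrix(np.hstack(cols))
        th = gao_meff(G, blocks, mode="simpleM", variance_fraction=0.995)
        expected = 0
        for idx in blocks:  # independent oracle: full spectrum per block
            corr = np.corrcoef(G.dosages[:, idx], rowvar=False)
            ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
            cum = np.cumsum(ev)
            expected += int(np.argmax(cum >= 0.995 * cum[-1]) + 1)
        assert th.m_eff == expected

    def test_block_count_mode_returns_partition_size(self, small_panel):
        _, G, _, _ = small_panel
        blocks = [list(range(i, min(i + 30, G.n_snps))) for i in range(0, G.n_snps, 30)]
        th = gao_meff(G, blocks, mode="block-count")
        assert th.m_eff == len(blocks)
        assert th.significant_logp == pytest.approx(-math.log10(0.05 / len(blocks)))
        assert th.suggestive_logp == pytest.approx(3.0)

    def test_bad_partition_rejected(self, small_panel):
        _, G, _, _ = small_panel
        with pytest.raises(ValueError):
            gao_meff(G, [[0, 1]], mode="block-count")

    def test_blocks_from_dprime_splits_chromosomes(self, small_panel):
        _, G, _, _ = small_panel
        blocks = blocks_from_dprime(G, threshold=0.8)
        flat = [j for b in blocks for j in b]
        assert flat == list(range(G.n_snps))
        for b in blocks:
            assert len({G.snps[j].chrom for j in b}) == 1


def _fake_results(p, rng):
    res = []
    for j in range(p):
        res.append(
            LmmSnpResult(f"Chr01:{100*(j+1)}", "Chr01", 100 * (j + 1), 0.3,
                         float(rng.standard_normal()), 0.1, float(rng.random()), 1.0)
        )
    return res


class TestSubsets:
    def test_one_percent_of_1000_is_10(self):
        res = _fake_results(1000, np.random.default_rng(1))
        assert len(subset_by_rank(res, 0.01, "lowest_p").snp_ids) == 10

    def test_largest_abs_beta_ranks_extreme_first(self):
        res = _fake_results(50, np.random.default_rng(2))
        res[17].beta = -99.0
        sub = subset_by_rank(res, 0.1, "largest_abs_beta")
        assert sub.snp_ids[0] == res[17].snp_id

    def test_fraction_one_returns_everything(self):
        res = _fake_results(30, np.random.default_rng(3))
        assert set(subset_by_rank(res, 1.0, "lowest_p").snp_ids) == {r.snp_id for r in res}

    def test_union_obeys_inclusion_exclusion(self):
        res = _fake_results(40, np.random.default_rng(4))
        a = subset_by_rank(res, 0.25, "lowest_p")       # 10 SNPs
        b = subset_by_rank(res, 0.25, "largest_abs_beta")
        overlap = len(set(a.snp_ids) & set(b.snp_ids))
        u = subset_union(a, b)
        assert len(u.snp_ids) == 20 - overlap
        assert u.name == "combination"
        # sorted by position
        assert u.keys == sorted(u.keys, key=lambda k: k[1])

    def test_union_idempotent(self):
        res = _fake_results(40, np.random.default_rng(5))
        a = subset_by_rank(res, 0.25, "lowest_p")
        u = subset_union(a, a)
        assert sorted(u.snp_ids) == sorted(a.snp_ids)

    def test_union_equals_constructive_identity(self):
        res = _fake_results(60, np.random.default_rng(6))
        a = subset_by_rank(res, 0.1, "lowest_p")
        b = subset_by_rank(res, 0.1, "largest_abs_beta")
        u = subset_union(a, b)
        assert set(u.snp_ids) == set(a.snp_ids) | set(b.snp_ids)
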
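import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathgwa.bslmm import (
    BslmmConfig, BslmmPosterior, aggregate_chains, bslmm_fit, bslmm_fit_single,
    classify_major, hpdi, sparse_effect,
)
from pathgwa.relatedness import centered_kinship, pca_covariates
from pathgwa.simulate import SimulationConfig, simulate_genotypes, simulate_phenotype

FAST = dict(burn_in=5_000, steps=50_000, record_pace=10, chains=1)


def _fit(n, p, n_causal, pve, pge, sim_seed, chain_seed, **kw):
    cfg = SimulationConfig(n_samples=n, n_snps=p, n_causal_sparse=n_causal,
                           pve_target=pve, pge_target=pge, seed=sim_seed)
    G = simulate_genotypes(cfg)
    y, truth = simulate_phenotype(G, cfg)
    K = centered_kinship(G)
    W = pca_covariates(G, k=4)
    settings = {**FAST, **kw, "seed": chain_seed}
    return bslmm_fit_single(G, y, K, W, BslmmConfig(**settings)), truth


@pytest.fixture(scope="module")
def oligogenic_fit():
    """One causal SNP carrying half the trait variance."""
    post, truth = _fit(300, 500, 1, 0.5, 1.0, sim_seed=7, chain_seed=3,
                       burn_in=10_000, steps=100_000)
    return post, truth


class TestSparseEffect:
    @pytest.mark.parametrize(
        "beta,pip,expected",
        [(0.5, 0.2, 0.10), (1.7, 0.0, 0.0), (-0.3, 0.5, 0.15)],
    )
    def test_absolute_product(self, beta, pip, expected):
        assert sparse_effect(beta, pip) == pytest.approx(expected)

    def test_pip_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sparse_effect(0.5, 1.2)


class TestHpdi:
    def test_constant_samples(self):
        assert hpdi(np.full(100, 3.25)) == (3.25, 3.25)
        assert hpdi(np.full(100, 3.25), mode="hpd") == (3.25, 3.25)

    def test_uniform_central_quantiles(self):
        rng = np.random.default_rng(12)
        lo, hi = hpdi(rng.random(100_000), mass=0.95, mode="central")
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)

    def test_hpd_shorter_than_central_for_skewed_sample(self):
        rng = np.random.default_rng(13)
        s = rng.exponential(size=50_000)  # strongly right-skewed
        c_lo, c_hi = hpdi(s, mode="central")
        h_lo, h_hi = hpdi(s, mode="hpd")
        assert (h_hi - h_lo) < (c_hi - c_lo)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(5))


def _toy_posterior(pip, beta_draws):
    p = len(pip)
    return BslmmPosterior(
        snp_ids=[f"Chr01:{100*(j+1)}" for j in range(p)],
        chroms=["Chr01"] * p,
        positions=[100 * (j + 1) for j in range(p)],
        hyp=pd.DataFrame({c: np.linspace(0.1, 0.9, 20) for c in
                          ("h", "pve", "rho", "pge", "pi", "n_gamma")}),
        pip=np.asarray(pip, float),
        beta_mean=np.array([d.mean() if len(d) else 0.0 for d in beta_draws]),
        beta_samples=[np.asarray(d, float) for d in beta_draws],
        alpha=np.zeros(p),
    )


class TestClassifyMajor:
    def test_conjunction_rule(self):
        draws_pos = np.linspace(0.1, 0.3, 40)     # interval away from zero
        draws_mixed = np.linspace(-0.1, 0.3, 40)  # interval crosses zero
        post = _toy_posterior(
            pip=[0.15, 0.15, 0.05],
            beta_draws=[draws_pos, draws_mixed, draws_pos],
        )
        calls = {c.snp_id: c for c in classify_major(post, pip_threshold=0.10)}
        assert calls["Chr01:100"].is_major          # PIP ok, HPDI excludes 0
        assert not calls["Chr01:200"].is_major      # HPDI crosses zero
        assert not calls["Chr01:300"].is_major      # PIP below threshold

    def test_insufficient_draws_never_major(self):
        post = _toy_posterior(pip=[0.5], beta_draws=[np.array([0.2, 0.2])])
        (call,) = classify_major(post)
        assert not call.is_major

    def test_sorted_by_sparse_effect(self):
        post = _toy_posterior(
            pip=[0.2, 0.9, 0.5],
            beta_draws=[np.full(20, 0.1), np.full(20, 0.4), np.full(20, 0.2)],
        )
        calls = classify_major(post)
        effects = [c.sparse_effect for c in calls]
        assert effects == sorted(effects, reverse=True)


class TestAggregateChains:
    def test_identical_chains_equal_single_chain(self, oligogenic_fit):
        post, _ = oligogenic_fit
        agg = aggregate_chains([post, post, post])
        for name in ("pve", "rho", "pi"):
            assert agg.point_estimate(name) == pytest.approx(post.point_estimate(name))
        np.testing.assert_allclose(agg.pip, post.pip)

    def test_pip_median(self):
        posts = [_toy_posterior([pipv], [np.linspace(0, 1, 30)]) for pipv in (0.1, 0.2, 0.9)]
        agg = aggregate_chains(posts)
        assert agg.pip[0] == pytest.approx(0.2)

    def test_pooled_sample_counts(self):
        posts = [_toy_posterior([0.5], [np.linspace(0, 1, k)]) for k in (10, 20, 30)]
        agg = aggregate_chains(posts)
        assert agg.beta_samples[0].size == 60
        assert len(agg.hyp) == 60

    def test_mismatched_snp_sets_rejected(self):
        a = _toy_posterior([0.5], [np.linspace(0, 1, 10)])
        b = _toy_posterior([0.5, 0.1], [np.linspace(0, 1, 10)] * 2)
        with pytest.raises(ValueError):
            aggregate_chains([a, b])


class TestPosteriorInvariants:
    def test_samples_normalized(self, oligogenic_fit):
        post, _ = oligogenic_fit
        hyp = post.hyp
        for c in ("h", "pve", "rho", "pge"):
            assert hyp[c].between(0, 1).all()
        assert hyp["pi"].between(0, 1).all()
        assert (hyp["n_gamma"] >= 0).all()
        assert (hyp["n_gamma"] <= 500).all()
        assert np.all((post.pip >= 0) & (post.pip <= 1))

    def test_mean_n_gamma_equals_sum_of_pips(self, oligogenic_fit):
        post, _ = oligogenic_fit
        assert post.hyp["n_gamma"].mean() == pytest.approx(post.pip.sum(), abs=1e-9)

    def test_causal_snp_dominates_posterior(self):
        """A single SNP carrying half the variance gets the top PIP (>= 0.5)
        and a small sparse set, in most seeds."""
        ok = 0
        for s in range(10):
            post, truth = _fit(300, 500, 1, 0.5, 1.0, sim_seed=100 + s, chain_seed=s)
            j = truth.causal_indices[0]
            ok += (post.pip.argmax() == j and post.pip[j] >= 0.5
                   and post.point_estimate("n_gamma") <= 3)
        assert ok >= 8

    def test_null_pve_small(self):
        """Pure-noise trait: posterior median PVE stays below 0.2."""
        ok = 0
        for s in range(10):
            post, _ = _fit(300, 500, 0, 0.0, 1.0, sim_seed=1000 + s, chain_seed=s)
            ok += post.point_estimate("pve") < 0.2
        assert ok >= 9

    def test_pips_match_brute_force_posterior_oracle(self):
        """On a two-SNP problem the sampler's PIPs must match the exact
        posterior computed by dense enumeration over γ with numerical
        integration of the (h, ρ, log π) hyperpriors."""
        rng = np.random.default_rng(77)
        n, p = 50, 2
        from conftest import make_matrix
        from pathgwa.genotype_io import PhenotypeVector
        from pathgwa.relatedness import KinshipMatrix, StructureCovariates

        X = rng.integers(0, 3, (n, p)).astype(float)
        G = make_matrix(X)
        K = np.cov(rng.standard_normal((n, 2 * n)))  # generic PSD kinship
        K = (K + K.T) / 2
        y = 0.6 * X[:, 0] + rng.standard_normal(n)

        # --- dense oracle: marginal likelihood per γ, hyperpriors on a grid
        M = np.eye(n) - np.full((n, n), 1.0 / n)  # project the intercept
        yp = M @ y
        Xp = M @ X
        sx = float(np.var(X, axis=0).mean())
        mK = float(np.trace(K)) / n
        n_eff = n - 1
        hs = np.linspace(0.005, 0.995, 25)
        rs = np.linspace(0.005, 0.995, 25)
        lps = np.linspace(np.log(1.0 / p), 0.0, 25) * (1 - 1e-9) + \
            np.log(1.0 / p) * 1e-9
        gammas = [(), (0,), (1,), (0, 1)]
        post_mass = np.zeros(len(gammas))
        lse = []
        for gi, gam in enumerate(gammas):
            vals = []
            for h in hs:
                gtot = h / (1 - h)
                for r in rs:
                    sb2 = (1 - r) * gtot / mK
                    base = sb2 * K + np.eye(n)
                    for lp in lps:
                        pi = np.exp(lp)
                        sa2 = r * gtot / (pi * p * sx)
                        S = base.copy()
                        for j in gam:
                            S += sa2 * np.outer(Xp[:, j], Xp[:, j])
                        sign, logdet = np.linalg.slogdet(S)
                        quad = yp @ np.linalg.solve(S, yp)
                        prior = len(gam) * np.log(min(pi, 1 - 1e-12)) + \
                            (p - len(gam)) * np.log(1 - min(pi, 1 - 1e-12))
                        vals.append(-0.5 * logdet - 0.5 * n_eff * np.log(quad) + prior)
            vals = np.array(vals)
            lse.append(vals.max() + np.log(np.mean(np.exp(vals - vals.max()))))
        w = np.exp(np.array(lse) - max(lse))
        w /= w.sum()
        pip_oracle = np.array([
            sum(w[gi] for gi, gam in enumerate(gammas) if j in gam) for j in range(p)
        ])

        # --- sampler
        Gm = G
        pv = PhenotypeVector(samples=list(Gm.samples), values=y)
        Km = KinshipMatrix(samples=list(Gm.samples), K=K)
        config = BslmmConfig(burn_in=20_000, steps=500_000, record_pace=10,
                             chains=1, seed=4, p_gamma_move=0.8)
        post = bslmm_fit_single(Gm, pv, Km, None, config)
        np.testing.assert_allclose(post.pip, pip_oracle, atol=0.03)

    def test_chain_seed_determinism(self):
        p1, _ = _fit(100, 100, 1, 0.5, 1.0, sim_seed=42, chain_seed=9)
        p2, _ = _fit(100, 100, 1, 0.5, 1.0, sim_seed=42, chain_seed=9)
        pd.testing.assert_frame_equal(p1.hyp, p2.hyp)
        np.testing.assert_array_equal(p1.pip, p2.pip)
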
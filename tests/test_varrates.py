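"""Variable-rates machinery: likelihood identities, rjMCMC invariants,
stepping-stone estimator, diagnostics, consensus tree, multi-rate BM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eyevol.phylo import vcv_matrix
from eyevol.simulate import SimConfig, simulate_bm, simulate_tree, simulate_traits
from eyevol.traits import add_log10, species_means
from eyevol.varrates import (VarRatesConfig, VarRatesPosterior, bayes_factor,
                             consensus_scaled_tree, marginal_likelihood,
                             mcmc_diagnostics, multirate_bm, power_ladder,
                             sample_scalar_prior, scalar_prior_scale,
                             stepping_stone_logml, varrates_loglik,
                             varrates_mcmc, _TreeMachinery)


@pytest.fixture(scope="module")
def small_problem():
    cfg = SimConfig(seed=8, n_species=20)
    tree = simulate_tree(cfg)
    rec, truth = simulate_traits(tree, cfg)
    means = species_means(add_log10(rec))
    return tree, means, truth


class TestLikelihood:
    def test_unit_scalars_equal_plain_bm_regression_loglik(self, small_problem):
        tree, means, _ = small_problem
        df = means.set_index("species").loc[tree.tips]
        y = df["mean_log10_eye"].to_numpy()
        X = np.column_stack([np.ones(len(y)),
                             df["mean_log10_wing"].to_numpy()])
        beta = np.array([0.1, 0.5])
        s2 = 0.05
        ll = varrates_loglik(tree, y, X, beta, s2, lam=1.0)
        V = s2 * vcv_matrix(tree).matrix
        oracle = stats.multivariate_normal(X @ beta, V).logpdf(y)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_scalars_scale_covariance_blockwise(self, small_problem):
        tree, means, _ = small_problem
        mach = _TreeMachinery(tree)
        df = means.set_index("species").loc[tree.tips]
        y = df["mean_log10_eye"].to_numpy()
        X = np.ones((len(y), 1))
        r = np.ones(mach.n_edges)
        r[0] = 10.0
        ll = varrates_loglik(tree, y, X, np.array([0.0]), 1.0, 1.0,
                             edge_rates=r)
        bl = tree.length.copy()
        bl[1] *= 10.0  # edge index 0 is node 1's edge
        from eyevol.phylo import Phylogeny
        stretched = Phylogeny(tree.parent.copy(), bl, list(tree.label))
        oracle = stats.multivariate_normal(
            np.zeros(len(y)), vcv_matrix(stretched).matrix).logpdf(y)
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestPrior:
    def test_scalar_prior_median_is_one(self):
        rng = np.random.default_rng(1)
        draws = sample_scalar_prior(100_000, rng)
        assert 0.95 <= np.median(draws) <= 1.05

    def test_scale_closed_form(self):
        s = scalar_prior_scale()
        assert stats.gamma.ppf(0.5, a=1.1, scale=s) == pytest.approx(1.0)


class TestSamplerContracts:
    def test_zero_iteration_config_rejected(self):
        with pytest.raises(ValueError):
            VarRatesConfig(n_iterations=0)

    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            VarRatesConfig(n_iterations=100, burnin=100)

    def test_constant_response_rejected(self, small_problem):
        tree, means, _ = small_problem
        bad = means.copy()
        bad["mean_log10_eye"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            varrates_mcmc(bad, tree, VarRatesConfig(
                n_iterations=100, burnin=10))

    def test_reproducible_given_seed(self, small_problem):
        tree, means, _ = small_problem
        cfg = VarRatesConfig(seed=5, n_chains=1, n_iterations=3000,
                             burnin=500, thinning=10)
        a = varrates_mcmc(means, tree, cfg).stacked()
        b = varrates_mcmc(means, tree, cfg).stacked()
        pd.testing.assert_frame_equal(a, b)

    def test_sample_count_matches_config(self, small_problem):
        tree, means, _ = small_problem
        cfg = VarRatesConfig(seed=5, n_chains=2, n_iterations=4000,
                             burnin=1000, thinning=10)
        post = varrates_mcmc(means, tree, cfg)
        assert all(len(c) == 300 for c in post.chains)

    def test_homogeneous_sampler_stationary_across_seeds(self, small_problem):
        # two independent homogeneous-model chains target one posterior:
        # two-sample KS on each marginal should not reject at alpha = 0.01
        tree, means, _ = small_problem
        out = []
        for seed in (11, 17):
            # heavy thinning: KS needs approximately independent draws
            cfg = VarRatesConfig(seed=seed, n_chains=1, rj_enabled=False,
                                 n_iterations=120_000, burnin=20_000,
                                 thinning=500)
            out.append(varrates_mcmc(means, tree, cfg).stacked())
        for col in ("beta1", "sigma2", "lam"):
            p = stats.ks_2samp(out[0][col], out[1][col]).pvalue
            assert p > 0.01, col


class TestSteppingStone:
    def _conjugate(self, K, n_draws=4000, seed=0):
        # y_i ~ N(mu, s2) with mu ~ N(0, tau2): analytic marginal available
        rng = np.random.default_rng(seed)
        n, s2, tau2 = 12, 1.0, 4.0
        y = rng.normal(1.0, np.sqrt(s2), size=n)

        def samples_at(beta):
            r = np.random.default_rng((seed, int(beta * 1e9) % (2**31)))
            prec = 1.0 / tau2 + beta * n / s2
            mean = (beta * y.sum() / s2) / prec
            mu = r.normal(mean, np.sqrt(1.0 / prec), size=n_draws)
            return np.array([
                np.sum(stats.norm.logpdf(y, m, np.sqrt(s2))) for m in mu])

        est = stepping_stone_logml(samples_at, K=K)
        V = s2 * np.eye(n) + tau2 * np.ones((n, n))
        exact = stats.multivariate_normal(np.zeros(n), V).logpdf(y)
        return est, exact

    def test_conjugate_toy_within_tenth_nat(self):
        est, exact = self._conjugate(K=32)
        assert est == pytest.approx(exact, abs=0.1)

    def test_ladder_doubling_shifts_estimate_little(self):
        a, _ = self._conjugate(K=16)
        b, _ = self._conjugate(K=32)
        assert abs(a - b) < 0.2

    def test_ladder_shape_and_bounds(self):
        b = power_ladder(8)
        assert b[0] == 0.0 and b[-1] == 1.0
        assert np.all(np.diff(b) > 0)
        with pytest.raises(ValueError):
            power_ladder(1)


class TestBayesFactor:
    def test_identity_and_definition(self):
        assert bayes_factor(-10.0, -10.0) == 0.0
        assert bayes_factor(-9.0, -10.0) == pytest.approx(2.0)

    def test_antisymmetric(self):
        assert bayes_factor(-3.0, -7.5) == -bayes_factor(-7.5, -3.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(float("nan"), 0.0)


class TestDiagnostics:
    def _posterior_from(self, chains_dict_list, tree):
        chains = [pd.DataFrame(d) for d in chains_dict_list]
        rates = [np.ones((len(c), tree.n_nodes - 1)) for c in chains]
        return VarRatesPosterior(chains, rates,
                                 np.arange(1, tree.n_nodes), tree,
                                 VarRatesConfig())

    def test_iid_chains_high_ess_low_rhat(self, small_problem):
        tree, _, _ = small_problem
        rng = np.random.default_rng(0)
        chains = [{"beta0": rng.normal(size=1000)} for _ in range(3)]
        post = self._posterior_from(chains, tree)
        d = mcmc_diagnostics(post, params=("beta0",)).iloc[0]
        assert d["ess"] >= 2500
        assert d["rhat"] < 1.01

    def test_disjoint_constant_chains_diverge(self, small_problem):
        tree, _, _ = small_problem
        rng = np.random.default_rng(0)
        chains = [{"beta0": rng.normal(0, 1e-3, size=500)},
                  {"beta0": rng.normal(10, 1e-3, size=500)}]
        post = self._posterior_from(chains, tree)
        d = mcmc_diagnostics(post, params=("beta0",)).iloc[0]
        # rank-normalized split-R-hat saturates below the naive ratio for
        # fully disjoint chains; far above the 1.2 convergence ceiling
        assert d["rhat"] > 1.5

    def test_ar1_ess_matches_closed_form(self, small_problem):
        tree, _, _ = small_problem
        rho, n = 0.9, 40_000
        rng = np.random.default_rng(3)
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.normal() * np.sqrt(1 - rho**2)
        post = self._posterior_from([{"beta0": x}], tree)
        d = mcmc_diagnostics(post, params=("beta0",)).iloc[0]
        expected = n * (1 - rho) / (1 + rho)
        assert abs(d["ess"] - expected) / expected < 0.25
        assert np.isnan(d["rhat"])  # unavailable with one chain


class TestConsensusTree:
    def test_all_unit_scalars_identity(self, small_problem):
        tree, means, _ = small_problem
        cfg = VarRatesConfig(seed=1, n_chains=1, n_iterations=2000,
                             burnin=500, thinning=10, rj_enabled=False)
        post = varrates_mcmc(means, tree, cfg)
        cons = consensus_scaled_tree(post)
        assert np.allclose(cons.length, tree.length)

    def test_single_stretched_branch(self, small_problem):
        tree, _, _ = small_problem
        E = tree.n_nodes - 1
        rates = np.ones((50, E))
        rates[:, 4] = 10.0
        post = VarRatesPosterior(
            [pd.DataFrame({"loglik": np.zeros(50)})], [rates],
            np.arange(1, tree.n_nodes), tree, VarRatesConfig())
        cons = consensus_scaled_tree(post)
        assert cons.length[5] == pytest.approx(10.0 * tree.length[5])
        mask = np.ones(tree.n_nodes, dtype=bool)
        mask[5] = False
        assert np.allclose(cons.length[mask], tree.length[mask])


class TestMultirateBm:
    def test_high_penalty_shrinks_toward_homogeneity(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_species=25, shifted_clade_rate=1.0)
            tree = simulate_tree(cfg)
            rng = np.random.default_rng(seed)
            trait = simulate_bm(tree, 1.0, rng)
            fit = multirate_bm(trait, tree, lambda_pen=50.0)
            ratio = fit.branch_sigma2.max() / fit.branch_sigma2.min()
            hits += ratio < 2.0
        assert hits >= 9

    def test_shifted_clade_rates_exceed_background(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_species=30)
            tree = simulate_tree(cfg)
            _, truth = simulate_traits(tree, cfg)
            dev = truth["deviation_species"]
            fit = multirate_bm(dev, tree, lambda_pen=1.0)
            mach = _TreeMachinery(tree)
            cl = mach.clade_edges[truth["shifted_clade_node"]]
            other = [j for j in range(mach.n_edges) if j not in set(cl)]
            hits += (fit.branch_sigma2[cl].mean()
                     > fit.branch_sigma2[other].mean())
        assert hits >= 9

    def test_lower_penalty_allows_no_less_rate_variance(self, small_problem):
        tree, _, truth = small_problem
        dev = truth["deviation_species"]
        loose = multirate_bm(dev, tree, lambda_pen=0.1)
        tight = multirate_bm(dev, tree, lambda_pen=50.0)
        assert (np.var(np.log(loose.branch_sigma2))
                >= np.var(np.log(tight.branch_sigma2)) - 1e-12)

    def test_nonpositive_penalty_rejected(self, small_problem):
        tree, _, truth = small_problem
        with pytest.raises(ValueError):
            multirate_bm(truth["deviation_species"], tree, lambda_pen=0.0)
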
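import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from driftshift._stats import hpd_interval, ln_harmonic_mean
from driftshift.errors import UnidentifiableError, ValidationError
from driftshift.signal import (PhyloCovariance, bayes_factor, fit_lambda,
                               gls_fit, lambda_transform, phylo_covariance)
from driftshift.synthetic import simulate_traits
from driftshift.treeio import TraitTable

from conftest import newick, yule_tree


class TestPhyloCovariance:
    def test_two_independent_tips(self, two_tip):
        V = phylo_covariance(two_tip)
        np.testing.assert_allclose(V.matrix, np.eye(2))

    def test_shared_branch_is_covariance(self):
        V = phylo_covariance(newick("((A:1,B:1):1,C:2);"))
        i = {l: k for k, l in enumerate(V.labels)}
        assert V.matrix[i["A"], i["B"]] == pytest.approx(1.0)
        assert V.matrix[i["A"], i["C"]] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(V.matrix), 2.0)

    def test_symmetric_nonnegative_psd(self):
        V = phylo_covariance(yule_tree(15, seed=2)).matrix
        np.testing.assert_allclose(V, V.T)
        assert (V >= 0).all()
        assert np.linalg.eigvalsh(V).min() > -1e-9
        # off-diagonals bounded by the smaller diagonal
        d = np.diag(V)
        assert (V <= np.minimum.outer(d, d) + 1e-12).all()


class TestLambdaTransform:
    def test_identity_zero_and_half(self):
        V = phylo_covariance(newick("((A:1,B:1):1,C:2);"))
        np.testing.assert_allclose(lambda_transform(V, 1.0).matrix, V.matrix)
        np.testing.assert_allclose(lambda_transform(V, 0.0).matrix,
                                   np.diag(np.diag(V.matrix)))
        half = lambda_transform(V, 0.5).matrix
        i = {l: k for k, l in enumerate(V.labels)}
        assert half[i["A"], i["B"]] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(half), np.diag(V.matrix))

    def test_domain_error(self):
        V = phylo_covariance(newick("(A:1,B:1);"))
        with pytest.raises(ValueError):
            lambda_transform(V, 1.5)


class TestGlsFit:
    def test_two_tip_identity_covariance(self):
        V = PhyloCovariance(np.eye(2), ["A", "B"])
        fit = gls_fit(TraitTable({"A": 0.0, "B": 2.0}), V)
        assert fit.alpha == pytest.approx(1.0)
        assert fit.sigma2 == pytest.approx(1.0)
        expected = norm.logpdf([0.0, 2.0], loc=1.0, scale=1.0).sum()
        assert fit.ln_likelihood == pytest.approx(expected)

    def test_location_equivariance(self, small_traits, balanced4):
        V = phylo_covariance(balanced4)
        f0 = gls_fit(small_traits, V)
        shifted = TraitTable({k: v + 3.7 for k, v in small_traits.values.items()})
        f1 = gls_fit(shifted, V)
        assert f1.alpha == pytest.approx(f0.alpha + 3.7)
        assert f1.sigma2 == pytest.approx(f0.sigma2)
        assert f1.ln_likelihood == pytest.approx(f0.ln_likelihood)

    def test_matches_grid_search_oracle(self):
        tree = yule_tree(6, seed=5)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        rng = np.random.default_rng(3)
        traits = TraitTable(dict(zip(labels, rng.normal(1.0, 0.6, 6))))
        V = phylo_covariance(tree)
        fit = gls_fit(traits, V)
        y = traits.vector(V.labels)

        def grid_max(alphas, s2s):
            best, arg = -np.inf, None
            for alpha in alphas:
                for s2 in s2s:
                    lnl = multivariate_normal.logpdf(
                        y, mean=np.full(6, alpha), cov=s2 * V.matrix)
                    if lnl > best:
                        best, arg = lnl, (alpha, s2)
            return best, arg

        _, (a0, s0) = grid_max(np.linspace(y.min() - 0.5, y.max() + 0.5, 80),
                               np.geomspace(1e-3, 100.0, 150))
        best, _ = grid_max(np.linspace(a0 - 0.1, a0 + 0.1, 100),
                           np.linspace(0.8 * s0, 1.25 * s0, 100))
        assert fit.ln_likelihood == pytest.approx(best, abs=1e-4)
        assert fit.ln_likelihood >= best - 1e-9  # closed form is the max

    def test_invariant_to_simultaneous_permutation(self, balanced4, small_traits):
        V = phylo_covariance(balanced4)
        perm = [2, 0, 3, 1]
        Vp = PhyloCovariance(V.matrix[np.ix_(perm, perm)],
                             [V.labels[i] for i in perm])
        assert gls_fit(small_traits, Vp).ln_likelihood == pytest.approx(
            gls_fit(small_traits, V).ln_likelihood)


class TestFitLambda:
    def test_profile_endpoints_match_direct_fits(self):
        tree = yule_tree(20, seed=7)
        traits = simulate_traits(tree, sigma2=0.1, lam=1.0, x0=0.0, seed=11)
        V = phylo_covariance(tree)
        res = fit_lambda(tree, traits, mode="ml")
        assert res.lnl_lambda1 == pytest.approx(gls_fit(traits, V).ln_likelihood)
        ind = gls_fit(traits, lambda_transform(V, 0.0))
        assert res.lnl_lambda0 == pytest.approx(ind.ln_likelihood)
        assert 0.0 <= res.interval[0] <= res.lam <= res.interval[1] <= 1.0

    def test_brownian_traits_give_high_lambda(self):
        tree = yule_tree(50, seed=9)
        hits = 0
        for r in range(10):
            traits = simulate_traits(tree, sigma2=0.1, lam=1.0, x0=0.0, seed=r)
            if fit_lambda(tree, traits, mode="ml").lam >= 0.9:
                hits += 1
        assert hits >= 8

    def test_star_tree_is_unidentifiable(self):
        star = newick("(A:1,B:1,C:1,D:1,E:1);")
        traits = TraitTable({k: v for k, v in
                             zip("ABCDE", [0.1, -0.2, 0.3, 0.0, 0.15])})
        with pytest.raises(UnidentifiableError):
            fit_lambda(star, traits, mode="ml")

    def test_too_few_tips(self, two_tip):
        with pytest.raises(ValidationError):
            fit_lambda(two_tip, TraitTable({"A": 0.0, "B": 1.0}), mode="ml")

    def test_mcmc_mode_posterior_and_marginals(self):
        tree = yule_tree(15, seed=4)
        traits = simulate_traits(tree, sigma2=0.1, lam=1.0, x0=0.0, seed=2)
        res = fit_lambda(tree, traits, mode="mcmc", seed=0, iterations=4000)
        assert res.mode == "mcmc-harmonic-mean"
        assert 0.0 <= res.interval[0] <= res.lam <= res.interval[1] <= 1.0
        assert np.isfinite([res.lnl_observed, res.lnl_lambda0,
                            res.lnl_lambda1]).all()
        assert 0.05 < res.metadata["acceptance"] < 0.7
        # Brownian-generated data: independent-trait model should lose
        assert res.lnl_observed > res.lnl_lambda0


def test_harmonic_mean_close_to_conjugate_marginal():
    """Normal-normal conjugate toy: harmonic-mean estimate of the ln
    marginal likelihood sits within 1 ln-unit of the analytic value."""
    rng = np.random.default_rng(12)
    n, s2, tau2 = 20, 1.0, 1.0
    y = rng.normal(0.7, math.sqrt(s2), n)
    post_var = 1.0 / (n / s2 + 1.0 / tau2)
    post_mean = post_var * y.sum() / s2
    mus = rng.normal(post_mean, math.sqrt(post_var), 100_000)
    lnl = np.array([norm.logpdf(y, mu, math.sqrt(s2)).sum() for mu in mus])
    analytic = multivariate_normal.logpdf(
        y, mean=np.zeros(n), cov=s2 * np.eye(n) + tau2 * np.ones((n, n)))
    assert ln_harmonic_mean(lnl) == pytest.approx(analytic, abs=1.0)


class TestBayesFactor:
    @pytest.mark.parametrize("m1,m2,expected", [
        (7.4, -4.9, 24.6),
        (7.4, 9.3, -3.8),
        (0.0, 0.0, 0.0),
        (-123.4, -123.4, 0.0),
    ])
    def test_two_delta_ln_scale(self, m1, m2, expected):
        assert bayes_factor(m1, m2) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(float("inf"), 0.0)


def test_hpd_interval_matches_generator_quantiles(rng):
    x = rng.normal(0.3, 0.05, 1000)
    lo, hi = hpd_interval(x, 0.95)
    assert lo == pytest.approx(0.3 - 1.96 * 0.05, abs=0.02)
    assert hi == pytest.approx(0.3 + 1.96 * 0.05, abs=0.02)
    assert lo < 0.3 < hi
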
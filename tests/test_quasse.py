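import math

import numpy as np
import pytest

from driftshift.errors import GridCoverageError, ValidationError
from driftshift.quasse import (CharacterGrid, QuasseLikelihood, QuasseParams,
                               SpeciationFunction, compare_models, fit_battery,
                               model_df, node_combine, propagate_branch,
                               quasse_loglik, speciation_rate,
                               tip_initial_state)
from driftshift.quasse import QuasseFit
from driftshift.treeio import TraitTable

from conftest import newick, yule_tree

GRID = CharacterGrid(-8.0, 8.0, 512)
CONST = SpeciationFunction("constant", {"c": 0.4})


def params(c=0.4, mu=0.0, sigma2=0.05, theta=0.0, fn=None):
    return QuasseParams(fn or SpeciationFunction("constant", {"c": c}),
                        mu=mu, sigma2=sigma2, theta=theta)


class TestSpeciationFunction:
    @pytest.mark.parametrize("fn,x,expected", [
        (SpeciationFunction("constant", {"c": 0.2}), 3.3, 0.2),
        (SpeciationFunction("hump", {"y0": 0.1, "y1": 0.5, "m": 5, "w": 1}), 5.0, 0.5),
        (SpeciationFunction("sigmoidal", {"y0": 0.1, "y1": 0.3, "m": 5, "r": 1}), 5.0, 0.2),
        (SpeciationFunction("linear", {"a": 0.1, "b": 0.05}), 2.0, 0.2),
        (SpeciationFunction("linear", {"a": -1.0, "b": 0.1}), 0.0, 0.0),  # clamp
    ])
    def test_rate_formulas(self, fn, x, expected):
        assert speciation_rate(fn, x) == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SpeciationFunction("hump", {"y0": 0.1, "y1": 0.5, "m": 5, "w": -1})
        with pytest.raises(ValueError):
            SpeciationFunction("constant", {"wrong": 1.0})
        with pytest.raises(ValueError):
            QuasseParams(CONST, mu=-0.1, sigma2=0.1)
        with pytest.raises(ValueError):
            QuasseParams(CONST, mu=0.1, sigma2=0.0)

    def test_grid_point_count_power_of_two(self):
        with pytest.raises(ValueError):
            CharacterGrid(0, 1, 100)


class TestTipInitialState:
    def test_density_normalized_and_extinction_zero(self):
        st = tip_initial_state(0.5, 0.2, GRID)
        assert np.trapezoid(st.D, dx=GRID.dx) == pytest.approx(1.0, abs=1e-6)
        assert not st.E.any()
        assert (st.D >= 0).all()

    def test_small_sd_concentrates_mass(self):
        st = tip_initial_state(0.5, 0.05, GRID)
        near = np.abs(GRID.x - 0.5) < 0.2
        frac = np.trapezoid(st.D[near], dx=GRID.dx)
        assert frac > 0.999

    def test_trait_outside_grid(self):
        with pytest.raises(GridCoverageError):
            tip_initial_state(9.5, 0.1, GRID)


class TestPropagateBranch:
    def test_pure_death_of_density_under_constant_speciation(self):
        # sigma2 -> 0, mu = 0: D scales by exp(-c t), E stays 0
        st = tip_initial_state(0.0, 0.3, GRID)
        p = params(c=0.4, sigma2=1e-8)
        out = propagate_branch(st, 2.0, p, GRID, dt_target=0.05)
        ratio = np.trapezoid(out.D, dx=GRID.dx)
        assert ratio == pytest.approx(math.exp(-0.4 * 2.0), rel=1e-6)
        assert np.max(out.E) < 1e-12

    def test_extinction_probability_closed_form(self):
        # lambda = 0, mu > 0: E(t) = 1 - exp(-mu t) uniformly in x
        st = tip_initial_state(0.0, 0.3, GRID)
        p = params(c=0.0, mu=0.25, sigma2=1e-8)
        out = propagate_branch(st, 3.0, p, GRID, dt_target=0.05)
        np.testing.assert_allclose(out.E, 1 - math.exp(-0.25 * 3.0), rtol=1e-6)

    def test_heat_kernel_spread_and_shift(self):
        # pure diffusion: variance grows by sigma2 t, mean moves by -theta t
        # (the backward recursion relocates the density toward the root state)
        st = tip_initial_state(0.0, 0.3, GRID)
        p = params(c=1e-12, sigma2=0.04, theta=0.5)
        out = propagate_branch(st, 2.0, p, GRID, dt_target=0.1)
        mass = np.trapezoid(out.D, dx=GRID.dx)
        mean = np.trapezoid(out.D * GRID.x, dx=GRID.dx) / mass
        var = np.trapezoid(out.D * GRID.x ** 2, dx=GRID.dx) / mass - mean ** 2
        assert mean == pytest.approx(-0.5 * 2.0, abs=1e-6)
        assert var == pytest.approx(0.3 ** 2 + 0.04 * 2.0, rel=1e-6)

    def test_extinction_monotone_and_bounded(self):
        st = tip_initial_state(0.0, 0.3, GRID)
        p = params(c=0.4, mu=0.2, sigma2=0.05, theta=0.1)
        last = st
        prev_E = last.E.copy()
        for _ in range(5):
            last = propagate_branch(last, 0.5, p, GRID, dt_target=0.05)
            assert (last.E >= prev_E - 1e-12).all()
            assert (last.E >= 0).all() and (last.E <= 1).all()
            prev_E = last.E.copy()


class TestNodeCombine:
    def test_constant_rate_scalar_scaling(self):
        left = tip_initial_state(0.2, 0.3, GRID)
        right = tip_initial_state(0.2, 0.3, GRID)
        right.D = np.ones(GRID.n)
        out = node_combine(left, right, CONST, GRID)
        np.testing.assert_allclose(out.D, 0.4 * left.D)

    def test_commutative(self):
        left = tip_initial_state(0.2, 0.3, GRID)
        right = tip_initial_state(-0.4, 0.25, GRID)
        fn = SpeciationFunction("linear", {"a": 0.5, "b": 0.05})
        ab = node_combine(left, right, fn, GRID)
        ba = node_combine(right, left, fn, GRID)
        np.testing.assert_allclose(ab.D, ba.D)

    def test_annihilation(self):
        left = tip_initial_state(0.2, 0.3, GRID)
        left.D = np.zeros(GRID.n)
        right = tip_initial_state(-0.4, 0.25, GRID)
        assert not node_combine(left, right, CONST, GRID).D.any()

    def test_extinction_mismatch_rejected(self):
        left = tip_initial_state(0.2, 0.3, GRID)
        right = tip_initial_state(-0.4, 0.25, GRID)
        right.E = right.E + 1e-4
        with pytest.raises(ValidationError):
            node_combine(left, right, CONST, GRID)


@pytest.fixture(scope="module")
def fixture10():
    # Brownian traits keep tip z-scores moderate: tail values below the
    # double-precision FFT noise floor would saturate any likelihood of
    # this model class
    from driftshift.synthetic import simulate_traits

    tree = yule_tree(10, seed=7)
    traits = simulate_traits(tree, sigma2=0.08, lam=1.0, x0=0.0, seed=5)
    return tree, traits


class TestQuasseLoglik:
    def test_drift_model_at_zero_theta_reduces_to_no_drift(self, fixture10):
        tree, traits = fixture10
        grid = CharacterGrid(-6, 6, 512)
        fn = SpeciationFunction("linear", {"a": 0.3, "b": 0.05})
        with_drift = QuasseParams(fn, mu=0.05, sigma2=0.08, theta=0.0)
        without = QuasseParams(fn, mu=0.05, sigma2=0.08)
        assert quasse_loglik(tree, traits, with_drift, grid) == pytest.approx(
            quasse_loglik(tree, traits, without, grid), abs=1e-12)

    def test_invariant_to_tip_enumeration_order(self):
        t1 = newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = newick("((D:1,C:1):1,(B:1,A:1):1);")
        traits = TraitTable({"A": 0.3, "B": -0.2, "C": 0.1, "D": 0.0})
        grid = CharacterGrid(-6, 6, 512)
        p = params(c=0.4, mu=0.05, sigma2=0.08, theta=0.2)
        assert quasse_loglik(t1, traits, p, grid, tip_sd=0.05) == pytest.approx(
            quasse_loglik(t2, traits, p, grid, tip_sd=0.05), abs=1e-9)

    def test_reflection_symmetry(self, fixture10):
        """Negating traits, the linear intercept/slope relation and theta
        while reflecting the grid leaves the likelihood unchanged."""
        tree, traits = fixture10
        grid = CharacterGrid(-6, 6, 512)
        fn = SpeciationFunction("linear", {"a": 0.4, "b": 0.06})
        p = QuasseParams(fn, mu=0.03, sigma2=0.06, theta=0.25)
        lnl = quasse_loglik(tree, traits, p, grid, tip_sd=0.05)
        neg = TraitTable({k: -v for k, v in traits.values.items()})
        fn_r = SpeciationFunction("linear", {"a": 0.4, "b": -0.06})
        p_r = QuasseParams(fn_r, mu=0.03, sigma2=0.06, theta=-0.25)
        lnl_r = quasse_loglik(tree, neg, p_r, grid, tip_sd=0.05)
        assert lnl_r == pytest.approx(lnl, abs=1e-6)

    def test_convergence_plateau(self, fixture10):
        tree, traits = fixture10
        p = params(c=0.4, mu=0.05, sigma2=0.08, theta=0.15)
        coarse = quasse_loglik(tree, traits, p, CharacterGrid(-7, 7, 1024),
                               tip_sd=0.05, dt_frac=0.01)
        fine = quasse_loglik(tree, traits, p, CharacterGrid(-7, 7, 2048),
                             tip_sd=0.05, dt_frac=0.005)
        assert abs(fine - coarse) < 1e-3

    def test_grid_too_narrow_raises(self, fixture10):
        tree, traits = fixture10
        with pytest.raises(GridCoverageError):
            quasse_loglik(tree, traits, params(sigma2=0.5),
                          CharacterGrid(-2, 2, 128))

    def test_trait_independent_factorization(self, fixture10):
        """Constant speciation, no extinction, flat root, no conditioning:
        the likelihood factorizes into pure-birth (tree) x Brownian
        (traits, root integrated) parts, each closed-form."""
        tree, traits = fixture10
        from driftshift.signal import phylo_covariance

        c, sd_tip, sigma2 = 0.4, 0.05, 0.08
        grid = CharacterGrid(-7, 7, 2048)
        lnl = quasse_loglik(tree, traits, params(c=c, sigma2=sigma2), grid,
                            root_mode="flat", condition_surv=False,
                            tip_sd=sd_tip, dt_frac=0.005)
        n = 10
        T = sum(e.length for e in tree.preorder_edge_iter()
                if e.length and e.head_node.parent_node)
        yule = (n - 1) * math.log(c) - c * T
        V = phylo_covariance(tree)
        y = traits.vector(V.labels)
        S = sigma2 * V.matrix + sd_tip ** 2 * np.eye(n)
        Si = np.linalg.inv(S)
        one = np.ones(n)
        a, b, q = one @ Si @ one, one @ Si @ y, y @ Si @ y
        ln_int = (-0.5 * (n * math.log(2 * math.pi)
                          + np.linalg.slogdet(S)[1])
                  + 0.5 * math.log(2 * math.pi / a) - 0.5 * (q - b * b / a))
        oracle = yule + ln_int - math.log(grid.hi - grid.lo)
        assert lnl == pytest.approx(oracle, abs=1e-3)


class TestModelAccounting:
    @pytest.mark.parametrize("kind,df", [
        ("full", 3), ("linear", 4), ("sigmoidal", 6), ("hump", 6),
        ("drift-linear", 5), ("drift-sigmoidal", 7), ("drift-hump", 7),
    ])
    def test_free_parameter_counts(self, kind, df):
        assert model_df(kind) == df

    def test_aic_identity(self):
        fit = QuasseFit(kind="drift-linear", drift=True,
                        params=params(theta=0.1), ln_likelihood=-62.56, df=5)
        assert fit.aic == pytest.approx(2 * 5 - 2 * (-62.56))


def _fake_fit(kind, lnl):
    drift = kind.startswith("drift-")
    return QuasseFit(kind=kind, drift=drift,
                     params=params(theta=0.48 if drift else 0.0),
                     ln_likelihood=lnl, df=model_df(kind))


class TestCompareModels:
    def test_chi_square_and_best_model(self):
        fits = [_fake_fit("full", -70.34), _fake_fit("drift-linear", -62.56)]
        table = compare_models(fits)
        row = table.frame.set_index("model").loc["drift-linear"]
        assert row["ChiSq"] == pytest.approx(15.56)
        assert row["AIC"] == pytest.approx(135.12)
        assert row["Pr(>Chi)"] < 0.001
        assert table.best_model == "drift-linear"

    def test_equal_fits_degenerate(self):
        base = _fake_fit("full", -50.0)
        twin = QuasseFit(kind="linear", drift=False, params=params(),
                         ln_likelihood=-50.0, df=3)
        table = compare_models([base, twin])
        row = table.frame.set_index("model").loc["linear"]
        assert row["ChiSq"] == pytest.approx(0.0)
        assert row["Pr(>Chi)"] == pytest.approx(1.0)

    def test_missing_full_rejected(self):
        with pytest.raises(ValidationError):
            compare_models([_fake_fit("linear", -50.0)])


def test_battery_respects_nesting(fixture10):
    """Warm-started battery: richer models never fit worse than the models
    they nest (up to optimizer tolerance)."""
    tree, traits = fixture10
    fits = fit_battery(tree, traits, models=["full", "linear", "drift-linear"],
                       grid_n=128, dt_frac=0.05, maxfun=80, seed=0)
    assert fits["linear"].ln_likelihood >= fits["full"].ln_likelihood - 1e-3
    assert fits["drift-linear"].ln_likelihood >= \
        fits["linear"].ln_likelihood - 1e-3
    assert [fits[m].df for m in ("full", "linear", "drift-linear")] == [3, 4, 5]


def test_constant_rate_ml_matches_ape_birthdeath(tmp_path):
    """Independent oracle: with a trait-independent constant model, the
    profile of our likelihood over (lambda, mu) must agree with the
    birth-death ML fit of R's ape package on the same tree."""
    import subprocess

    from driftshift.quasse import fit_quasse
    from driftshift.synthetic import (SimulationConfig,
                                      simulate_quasse_forward,
                                      study_constant_params)
    from driftshift.treeio import write_tree

    tree, traits = simulate_quasse_forward(
        study_constant_params(),
        SimulationConfig(seed=11, x0=4.5, max_tips=60))
    ours = fit_quasse(tree, traits, "full", n_starts=3, seed=0,
                      grid_n=128, dt_frac=0.03)
    path = tmp_path / "bd.nwk"
    write_tree(tree, str(path))
    rscript = (
        "suppressMessages(library(ape));"
        f"tr <- read.tree('{path}');"
        "f <- birthdeath(tr);"
        "bd <- f$para['b-d']; dd <- f$para['d/b'];"
        "b <- bd/(1-dd); d <- b*dd;"
        "cat(sprintf('%.6f %.6f', b, d))"
    )
    res = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=120)
    assert res.returncode == 0, res.stderr
    ape_lambda, ape_mu = map(float, res.stdout.split())
    assert ours.params.speciation.params["c"] == pytest.approx(ape_lambda,
                                                               abs=0.02)
    assert ours.params.mu == pytest.approx(ape_mu, abs=0.02)
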
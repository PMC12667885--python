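"""Closed forms against their independent numeric oracles and limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stabsel import analytic
from stabsel.params import ModelParams


def mk(ne=1000.0, u=0.01, vm=1e-3, vs=1.0, ve=0.0, **kw):
    return ModelParams(ne=ne, u=u, vm=vm, vs=vs, ve=ve, **kw)


class TestGaussianFitness:
    def test_optimum_has_fitness_one(self):
        assert analytic.gaussian_fitness(0.0, mk(vs=1.0)) == 1.0
        p = mk(vs=3.7).with_(optimum=2.5)
        assert analytic.gaussian_fitness(2.5, p) == 1.0

    def test_two_vs_displacement_gives_exp_minus_one(self):
        p = mk(vs=0.8).with_(optimum=1.0)
        w = analytic.gaussian_fitness(1.0 + math.sqrt(2 * 0.8), p)
        assert w == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_environmental_absorption_widens_the_function(self):
        p = mk(vs=1.0, ve=0.5)
        assert analytic.gaussian_fitness(1.0, p, absorb_ve=True) == pytest.approx(
            math.exp(-1.0 / 3.0)
        )

    def test_nonfinite_trait_value_rejected(self):
        with pytest.raises(ValueError):
            analytic.gaussian_fitness(math.nan, mk())

    def test_vectorized_and_in_unit_interval(self, rng):
        w = analytic.gaussian_fitness(rng.normal(size=50), mk())
        assert w.shape == (50,) and np.all((w > 0) & (w <= 1))


class TestMeanFitnessAt:
    def test_point_mass_at_optimum(self):
        assert analytic.mean_fitness_at(0.0, 0.0, 1.0) == 1.0

    def test_vp_equal_vs_ratio(self):
        assert analytic.mean_fitness_at(0.0, 2.0, 2.0) == pytest.approx(
            math.sqrt(0.5), rel=1e-12
        )

    @pytest.mark.parametrize("pbar,vp,vs", [
        (0.1, 0.04, 1.0), (0.0, 0.5, 1.0), (-0.3, 0.2, 2.0), (1.0, 1e-4, 0.5),
    ])
    def test_matches_quadrature_oracle(self, pbar, vp, vs):
        closed = analytic.mean_fitness_at(pbar, vp, vs)
        numeric = analytic.mean_fitness_numeric(pbar, vp, vs)
        assert closed == pytest.approx(numeric, rel=1e-10)

    def test_invalid_vs_rejected(self):
        with pytest.raises(ValueError):
            analytic.mean_fitness_at(0.0, 0.1, 0.0)


class TestExpectedMeanFitnessGivenVp:
    def test_infinite_ne_limit(self):
        for vp in (0.01, 0.1, 1.0):
            assert analytic.expected_mean_fitness_given_vp(1e12, vp, 1.0) == pytest.approx(
                math.sqrt(1.0 / (vp + 1.0)), abs=1e-5
            )

    def test_no_variance_no_load(self):
        assert analytic.expected_mean_fitness_given_vp(1e12, 0.0, 1.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_degenerate_inner_integral(self):
        assert analytic.expected_mean_fitness_numeric(1000, 0.0, 1.0) == pytest.approx(
            math.sqrt(2000.0 / 2001.0), rel=1e-9
        )

    def test_direct_substitution(self):
        assert analytic.expected_mean_fitness_given_vp(10, 1.0, 1.0) == pytest.approx(
            math.sqrt(20.0 / 41.0), rel=1e-12
        )

    def test_nested_quadrature_oracle_grid(self):
        # the closed form must match brute-force double integration
        for ne in (10.0, 1000.0):
            for vp in (0.0, 0.1, 1.0):
                closed = analytic.expected_mean_fitness_given_vp(ne, vp, 1.0)
                numeric = analytic.expected_mean_fitness_numeric(ne, vp, 1.0)
                assert closed == pytest.approx(numeric, rel=1e-8)

    def test_monotone_nonincreasing_in_vp(self):
        vals = [analytic.expected_mean_fitness_given_vp(500, vp, 1.0)
                for vp in np.linspace(0, 2, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestVgShoc:
    def test_house_of_cards_limit(self):
        p = mk(ne=1e9, u=0.01, vm=1.0, vs=1.0)
        assert analytic.vg_shoc(p) == pytest.approx(4 * 0.01 * 1.0, rel=1e-6)

    def test_drift_limit(self):
        p = mk(ne=10, u=0.01, vm=1e-8, vs=1.0)
        assert analytic.vg_shoc(p) == pytest.approx(4 * 10 * 0.01 * 1e-8, rel=1e-6)

    def test_crossover_point(self):
        p = mk(ne=100, u=0.01, vm=0.01, vs=1.0)  # ne*vm == vs
        assert analytic.vg_shoc(p) == pytest.approx(2 * 0.01 * 1.0, rel=1e-12)

    def test_limit_convergence_bands(self):
        # within 1% of each regime once the ratio passes 100 (0.01)
        strong = mk(ne=1e4, u=0.01, vm=0.02, vs=1.0)  # ratio 200
        weak = mk(ne=10, u=0.01, vm=5e-4, vs=1.0)  # ratio 0.005
        assert analytic.vg_shoc(strong) == pytest.approx(4 * 0.01, rel=0.01)
        assert analytic.vg_shoc(weak) == pytest.approx(4 * 10 * 0.01 * 5e-4, rel=0.01)

    @given(
        ne=st.floats(1, 1e8), u=st.floats(1e-6, 1), vm=st.floats(1e-8, 1),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_each_argument(self, ne, u, vm):
        p = mk(ne=ne, u=u, vm=vm)
        base = analytic.vg_shoc(p)
        assert analytic.vg_shoc(p.with_(ne=ne * 2)) >= base
        assert analytic.vg_shoc(p.with_(u=u * 2)) >= base
        assert analytic.vg_shoc(p.with_(vm=vm * 2)) >= base


class TestExpectedMeanFitness:
    def test_mutation_free_population(self):
        p = mk(u=0.0, ne=250.0)
        assert analytic.expected_mean_fitness(p) == pytest.approx(
            math.sqrt(500.0 / 501.0), rel=1e-12
        )

    def test_composition_identity(self, base_params):
        # the closed form is exactly the drift-averaged fitness evaluated
        # at the SHOC variance
        direct = analytic.expected_mean_fitness(base_params)
        composed = analytic.expected_mean_fitness_given_vp(
            base_params.ne, analytic.vg_shoc(base_params), base_params.vs
        )
        assert direct == pytest.approx(composed, rel=1e-12)

    def test_large_ne_load_near_2u(self):
        p = mk(ne=1e7, u=0.01, vm=1e-2, vs=1.0)
        load = 1.0 - analytic.expected_mean_fitness(p)
        assert load < 2 * p.u
        assert load == pytest.approx(2 * p.u, rel=0.25)

    def test_environmental_absorption_exact(self):
        with_ve = analytic.expected_mean_fitness(mk(vs=1.0, ve=0.5))
        absorbed = analytic.expected_mean_fitness(mk(vs=1.5, ve=0.0))
        assert with_ve == absorbed

    @given(st.floats(1e-5, 0.5), st.floats(1e-5, 0.4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_u(self, u, du):
        p = mk(u=u)
        assert analytic.expected_mean_fitness(p.with_(u=u + du)) < (
            analytic.expected_mean_fitness(p)
        )


class TestLoadApprox:
    def test_drift_load_when_mutation_free(self):
        assert analytic.load_approx(mk(u=0.0, ne=100.0)) == pytest.approx(0.0025)

    def test_mutation_load_in_large_populations(self):
        p = mk(ne=1e9, u=0.01, vm=1.0, vs=1.0)
        assert analytic.load_approx(p) == pytest.approx(2 * 0.01, rel=1e-6)

    def test_tracks_exact_load_midrange(self, base_params):
        exact = 1.0 - analytic.expected_mean_fitness(base_params)
        assert analytic.load_approx(base_params) == pytest.approx(exact, rel=0.10)


class TestOptimalNe:
    def test_closed_form_example(self):
        res = analytic.optimal_ne(mk(u=0.01, vm=0.01, vs=1.0))
        assert res.finite
        assert res.ne_star == pytest.approx((1 + math.sqrt(8)) / 0.07, rel=1e-12)

    def test_condition_violated_no_finite_optimum(self):
        res = analytic.optimal_ne(mk(u=0.001, vm=0.01, vs=1.0))
        assert not res.finite and res.ne_star is None

    def test_environmental_variance_rescues_condition(self):
        # 8 * 0.001 * 1.5 = 0.012 > vm = 0.01
        res = analytic.optimal_ne(mk(u=0.001, vm=0.01, vs=1.0, ve=0.5))
        assert res.finite and res.ne_star > 0

    def test_boundary_is_not_finite(self):
        vm = 8 * 0.01 * 1.0  # 8 u vs == vm exactly
        res = analytic.optimal_ne(mk(u=0.01, vm=vm, vs=1.0))
        assert not res.finite

    @pytest.mark.parametrize("u,vm,vs,ve", [
        (0.01, 0.01, 1.0, 0.0),
        (0.1, 0.1, 1.0, 0.0),
        (0.05, 0.01, 1.0, 0.0),
        (0.02, 1e-3, 0.5, 0.0),
        (0.001, 1e-3, 1.0, 0.5),
        (1.0, 0.5, 1.0, 0.0),
        (0.005, 1e-4, 1.0, 0.0),
        (0.3, 0.2, 2.0, 0.0),
        (0.02, 0.03, 3.0, 1.0),
        (0.008, 1e-3, 1.0, 0.0),
        (0.6, 0.05, 0.2, 0.1),
    ])
    def test_matches_numeric_maximization(self, u, vm, vs, ve):
        p = mk(u=u, vm=vm, vs=vs, ve=ve)
        res = analytic.optimal_ne(p)
        assert res.finite
        ne_num, _ = analytic.optimal_ne_numeric(p)
        assert res.ne_star == pytest.approx(ne_num, rel=1e-6)

    @pytest.mark.parametrize("u,vm", [(0.001, 0.01), (1e-4, 0.05)])
    def test_no_optimum_means_nondecreasing_fitness(self, u, vm):
        p = mk(u=u, vm=vm)
        grid = np.logspace(0, 8, 60)
        vals = [analytic.expected_mean_fitness(p, ne=n) for n in grid]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_finite_optimum_dominates_log_grid(self):
        p = mk(u=0.01, vm=0.01)
        res = analytic.optimal_ne(p)
        best = analytic.expected_mean_fitness(p, ne=res.ne_star)
        for n in np.logspace(0, 8, 60):
            assert best >= analytic.expected_mean_fitness(p, ne=n)


class TestFiniteOptimumCondition:
    def test_strict_inequality_at_threshold(self):
        vm, vs = 0.01, 1.0
        res = analytic.finite_optimum_condition(mk(u=vm / (8 * vs), vm=vm, vs=vs))
        assert not res.finite

    def test_threshold_u_value(self):
        res = analytic.finite_optimum_condition(mk(vm=0.01, vs=1.0))
        assert res.threshold_u == pytest.approx(1.25e-3)

    def test_threshold_l_with_per_base_rate(self):
        p = ModelParams(ne=100, u=1e-8 * 1e6, vm=0.01, vs=1.0, mu=1e-8, L=1e6)
        res = analytic.finite_optimum_condition(p)
        assert res.threshold_L == pytest.approx(1.25e5)


def test_phenotype_distribution_moments(base_params):
    dist = analytic.phenotype_distribution(base_params)
    assert dist.vg == analytic.vg_shoc(base_params)
    assert dist.vp == dist.vg  # no environmental noise: VP = VG
    assert dist.delta_var == pytest.approx(1.0 / 2000.0)
    noisy = analytic.phenotype_distribution(base_params.with_(ve=0.3))
    assert noisy.vp == pytest.approx(noisy.vg + 0.3)
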
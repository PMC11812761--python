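import dataclasses
import math

import numpy as np
import pytest

from ambusim.delay import DelayParams, SpeedParams
from ambusim.epidemiology import IncidenceParams
from ambusim.estimator import (
    ModelParams,
    lives_saved_one_rep,
    monte_carlo,
    quadrature_oracle,
    results_grid,
    results_grid_table,
)
from ambusim.scenarios import ScenarioSpec
from ambusim.survival import SurvivalParams, survival_prob
from ambusim.travel import least_cost_travel_time

from conftest import make_grid


def fixed_params(beta=120.0, s=0.6, tau_mode="sample"):
    """All parameter distributions degenerate at their means."""
    return ModelParams(
        delay=DelayParams(beta=beta), speed=SpeedParams(s=s),
        survival=SurvivalParams(lambda_mean=0.056, lambda_sd=0.0),
        incidence=IncidenceParams(), tau_mode=tau_mode,
    )


def single_cell(t=20.0, rho=137.0):
    tt = make_grid([[t]], units="minutes")
    density = make_grid([[rho]], units="persons/km2")
    return tt, density


@pytest.fixture(scope="module")
def region(synthetic_region):
    _, density, friction, facilities = synthetic_region
    tt = least_cost_travel_time(friction, facilities)
    return tt, density


class TestOneReplication:
    def test_delta_is_sum_of_per_cell_map(self, region):
        tt, density = region
        draw = lives_saved_one_rep(tt, density, fixed_params(), ScenarioSpec("fastest"),
                                   np.random.default_rng(0))
        assert draw.delta == pytest.approx(draw.per_cell_delta.values.sum(), rel=1e-9)

    def test_fastest_rule_delta_nonnegative_every_rep(self, region):
        tt, density = region
        params = ModelParams(delay=DelayParams(120), speed=SpeedParams(0.6))
        for seed in range(50):
            draw = lives_saved_one_rep(tt, density, params, ScenarioSpec("fastest"),
                                       np.random.default_rng(seed))
            assert draw.delta >= 0

    def test_ambulance_rule_can_lose_lives(self, region):
        # short waiting delays + slow ambulance: forced round trips cost lives
        tt, density = region
        params = fixed_params(beta=1.0, s=0.9)
        draw = lives_saved_one_rep(tt, density, params, ScenarioSpec("ambulance"),
                                   np.random.default_rng(0))
        assert draw.delta < 0

    def test_degenerate_beta_gives_closed_form_single_cell(self):
        # beta -> 0 makes tau -> 0; fastest picks min(t, 2st) = t for s > 0.5
        tt, density = single_cell()
        params = fixed_params(beta=1e-9, s=0.9)
        draw = lives_saved_one_rep(tt, density, params, ScenarioSpec("fastest"),
                                   np.random.default_rng(1))
        assert draw.delta == pytest.approx(0.0, abs=1e-12)

    def test_unreachable_cells_contribute_zero(self):
        tt = make_grid([[20.0, np.inf]], units="minutes")
        density = make_grid([[100.0, 100.0]], units="persons/km2")
        draw = lives_saved_one_rep(tt, density, fixed_params(), ScenarioSpec("fastest"),
                                   np.random.default_rng(0))
        assert draw.per_cell_delta.values[0, 1] == 0.0


class TestMonteCarlo:
    def test_single_rep_collapses_summary(self, region):
        tt, density = region
        res = monte_carlo(tt, density, fixed_params(), ScenarioSpec("fastest"), 1, 3)
        assert res.mean_delta == res.draws[0]
        assert res.cri_low == res.cri_high == res.draws[0]

    def test_same_seed_is_bit_identical(self, region):
        tt, density = region
        params = ModelParams(delay=DelayParams(180), speed=SpeedParams(0.7))
        a = monte_carlo(tt, density, params, ScenarioSpec("fastest"), 50, 9)
        b = monte_carlo(tt, density, params, ScenarioSpec("fastest"), 50, 9)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.mean_map.values, b.mean_map.values)

    def test_mean_is_mean_of_draws_and_cri_ordered(self, region):
        tt, density = region
        res = monte_carlo(tt, density, ModelParams(), ScenarioSpec("fastest"), 100, 4)
        assert res.mean_delta == pytest.approx(res.draws.mean())
        assert res.cri_low <= np.median(res.draws) <= res.cri_high

    def test_degenerate_distributions_leave_only_incidence_noise(self):
        # lambda sd 0 and tau at its expectation: delta is exactly linear in
        # the incidence draw, so delta/incidence is the same in every rep
        tt, density = single_cell()
        params = fixed_params(tau_mode="expectation")
        ratios = []
        for seed in range(10):
            draw = lives_saved_one_rep(tt, density, params, ScenarioSpec("ambulance"),
                                       np.random.default_rng(seed))
            ratios.append(draw.delta / draw.incidence_fraction)
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_density_scaling_scales_delta(self):
        tt, density = single_cell()
        density2 = density.copy_with(3.0 * density.values)
        # adjust beta so sigma(beta, rho) is unchanged under the rescale
        p1 = fixed_params(beta=120.0, tau_mode="expectation")
        p2 = fixed_params(beta=120.0 * math.sqrt(3.0), tau_mode="expectation")
        r1 = monte_carlo(tt, density, p1, ScenarioSpec("fastest"), 30, 6)
        r2 = monte_carlo(tt, density2, p2, ScenarioSpec("fastest"), 30, 6)
        assert r2.mean_delta == pytest.approx(3.0 * r1.mean_delta, rel=1e-9)


class TestQuadratureOracle:
    @pytest.mark.parametrize("rule", ["fastest", "ambulance", "random"])
    def test_monte_carlo_agrees_with_quadrature(self, rule):
        tt, density = single_cell(t=25.0, rho=137.0)
        params = fixed_params(beta=120.0, s=0.7)
        res = monte_carlo(tt, density, params, ScenarioSpec(rule), 20_000, 11)
        oracle = quadrature_oracle(25.0, 137.0, params, ScenarioSpec(rule))
        se = res.draws.std(ddof=1) / math.sqrt(res.n_reps)
        assert abs(res.mean_delta - oracle) < 3 * se

    def test_ambulance_rule_factorises(self):
        # E[S(t + tau)] = S(t) * E[exp(-lam tau)]
        from scipy import integrate

        params = fixed_params(beta=120.0, s=0.7)
        t, rho = 25.0, 137.0
        from ambusim.delay import rayleigh_scale

        sigma = rayleigh_scale(120.0, rho)
        lam = params.survival.lambda_mean
        mgf, _ = integrate.quad(lambda z: math.exp(-lam * sigma * z) * z * math.exp(-z * z / 2), 0, 40)
        cases = rho * 1.0 * 0.0275 * params.incidence.mean_incidence_fraction
        expected = cases * (survival_prob(lam, 2 * 0.7 * t) - survival_prob(lam, t) * mgf)
        assert quadrature_oracle(t, rho, params, ScenarioSpec("ambulance")) == pytest.approx(expected, rel=1e-8)

    def test_vanishing_delay_limit(self):
        params = fixed_params(beta=1e-9, s=0.7)
        t, rho = 25.0, 137.0
        lam = params.survival.lambda_mean
        cases = rho * 0.0275 * params.incidence.mean_incidence_fraction
        expected = cases * (survival_prob(lam, 1.4 * t) - survival_prob(lam, t))
        assert quadrature_oracle(t, rho, params, ScenarioSpec("ambulance")) == pytest.approx(expected, rel=1e-6)

    def test_refuses_non_scalar_input(self):
        with pytest.raises(ValueError):
            quadrature_oracle(np.array([1.0, 2.0]), 137.0, fixed_params(), ScenarioSpec("fastest"))


class TestResultsGrid:
    def test_qualitative_pattern_under_common_random_numbers(self, region):
        """Benefit grows with the waiting delay and shrinks as the ambulance
        advantage fades (the characteristic results-grid pattern)."""
        tt, density = region
        grid = results_grid(tt, density, ModelParams(), ScenarioSpec("fastest"),
                            betas=[60, 120, 180], speeds=[0.6, 0.9], n_reps=40, seed=2)
        for s in (0.6, 0.9):
            means = grid[grid.s == s].sort_values("beta")["mean"].to_numpy()
            assert np.all(np.diff(means) >= 0)
        for beta in (60, 120, 180):
            means = grid[grid.beta == beta].sort_values("s")["mean"].to_numpy()
            assert np.all(np.diff(means) <= 0)

    def test_single_combination_equals_direct_call(self, region):
        tt, density = region
        params = ModelParams()
        grid = results_grid(tt, density, params, ScenarioSpec("fastest"),
                            betas=[120], speeds=[0.8], n_reps=25, seed=7)
        direct = monte_carlo(tt, density,
                             dataclasses.replace(params, delay=DelayParams(120),
                                                 speed=SpeedParams(0.8)),
                             ScenarioSpec("fastest"), 25, 7)
        assert grid["mean"].iloc[0] == direct.mean_delta

    def test_column_ordering_matches_input(self, region):
        tt, density = region
        grid = results_grid(tt, density, ModelParams(), ScenarioSpec("fastest"),
                            betas=[300, 60], speeds=[0.9], n_reps=5, seed=1)
        assert grid["beta"].tolist() == [300, 60]
        table = results_grid_table(grid)
        assert list(table.columns) == [60, 300]
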
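"""Tests for the patch-colonization simulator core."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dictypatch import (
    SimulationConfig,
    SporePool,
    arithmetic_mean,
    beta_params_from_moments,
    disperse,
    draw_environment,
    geometric_mean,
    patch_spore_production,
    run_replicate,
    run_replicates,
    simulate_phenotype,
)
from dictypatch.simulate import n_sori_from_spores

from conftest import point_mass_pool


class TestMeans:
    @pytest.mark.parametrize(
        "series, gm, am",
        [
            ([5, 5, 5], 5.0, 5.0),
            ([1, 100], 10.0, 50.5),
            ([0, 10, 10], 0.0, 20 / 3),
        ],
    )
    def test_known_values(self, series, gm, am):
        assert geometric_mean(series) == pytest.approx(gm)
        assert arithmetic_mean(series) == pytest.approx(am)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean([1.0, -2.0])
        with pytest.raises(ValueError):
            arithmetic_mean([-1.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e12, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_am_gm_inequality(self, series):
        assert geometric_mean(series) <= arithmetic_mean(series) * (1 + 1e-12)


class TestBetaSpec:
    def test_symmetric_hand_case(self):
        spec = beta_params_from_moments(0.5, 0.05)
        assert spec.alpha == pytest.approx(2.0)
        assert spec.beta == pytest.approx(2.0)

    def test_asymmetric_hand_case(self):
        # k = 0.3*0.7/0.01 - 1 = 20 -> alpha 6, beta 14
        spec = beta_params_from_moments(0.3, 0.01)
        assert spec.alpha == pytest.approx(6.0)
        assert spec.beta == pytest.approx(14.0)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_params_from_moments(0.5, 0.25)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(0.02, 0.98), st.floats(1e-5, 0.2))
    def test_moment_matching_is_exact(self, p, v_frac):
        v_temp = v_frac * p * (1 - p)
        spec = beta_params_from_moments(p, v_temp)
        assert math.isclose(spec.mean, p, rel_tol=1e-12)
        assert math.isclose(spec.variance, v_temp, rel_tol=1e-9)


class TestEnvironment:
    def test_zero_variance_is_degenerate(self):
        cfg = SimulationConfig(n_rounds=100, p=0.37, v_temp=0.0)
        env = draw_environment(cfg)
        assert np.all(env.p_t == 0.37)

    def test_beta_moment_recovery(self):
        cfg = SimulationConfig(n_rounds=10_000, n_patches=2, p=0.5, v_temp=0.01)
        env = draw_environment(cfg)
        se = math.sqrt(0.01 / 10_000)
        assert abs(env.p_t.mean() - 0.5) < 3 * se
        assert abs(env.p_t.var() / 0.01 - 1) < 0.10

    def test_poor_patch_count_expectation(self):
        cfg = SimulationConfig(
            n_rounds=500, n_patches=100, p=0.9, v_temp=0.0, environment_seed=4
        )
        env = draw_environment(cfg)
        per_round = env.poor.sum(axis=1)
        se = math.sqrt(100 * 0.9 * 0.1 / 500)
        assert abs(per_round.mean() - 90.0) < 4 * se

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_rounds=50, p=0.4, v_temp=0.02, environment_seed=9)
        a, b = draw_environment(cfg), draw_environment(cfg)
        assert np.array_equal(a.p_t, b.p_t)
        assert np.array_equal(a.poor, b.poor)


class TestProduction:
    def test_uninfected_poor_is_zero(self, pool):
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert patch_spore_production("uninfected", "poor", pool, 0.0, rng) == 0.0

    def test_full_cost_zeroes_rich_production(self, pool):
        rng = np.random.default_rng(0)
        assert patch_spore_production("agricolaris", "rich", pool, 1.0, rng) == 0.0

    def test_cost_arithmetic_on_point_mass(self):
        pm = point_mass_pool({("agricolaris", "rich"): 1e7})
        rng = np.random.default_rng(0)
        value = patch_spore_production("agricolaris", "rich", pm, 0.25, rng)
        assert value == pytest.approx(7.5e6)

    def test_cost_not_applied_to_uninfected_or_poor(self):
        pm = point_mass_pool(
            {("uninfected", "rich"): 1e7, ("agricolaris", "poor"): 1e6}
        )
        rng = np.random.default_rng(0)
        assert patch_spore_production("uninfected", "rich", pm, 0.5, rng) == 1e7
        assert patch_spore_production("agricolaris", "poor", pm, 0.5, rng) == 1e6

    def test_empty_cell_error_names_cell(self):
        pm = point_mass_pool({("agricolaris", "rich"): 1e7})
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="hayleyella.*poor"):
            patch_spore_production("hayleyella", "poor", pm, 0.0, rng)


class TestDispersal:
    def test_zero_spores_colonizes_nothing(self):
        rng = np.random.default_rng(0)
        assert not disperse(0.0, 2e5, 100, 0.5, rng).any()

    def test_single_sorus_certain_establishment(self):
        rng = np.random.default_rng(1)
        occ = disperse(2e5, 2e5, 100, 1.0, rng)
        assert occ.sum() == 1

    def test_occupancy_bounded_by_patch_count(self):
        rng = np.random.default_rng(2)
        occ = disperse(1e9, 2e5, 10, 1.0, rng)
        assert occ.sum() <= 10

    def test_stochastic_rounding_is_unbiased(self):
        rng = np.random.default_rng(3)
        draws = [n_sori_from_spores(5e5, 2e5, rng) for _ in range(4000)]
        assert set(draws) <= {2, 3}
        assert np.mean(draws) == pytest.approx(2.5, abs=0.05)

    def test_fast_path_matches_per_sorus_distribution(self):
        """Binomial-thinning dispersal is distributionally identical to the loop."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(11)
        total, sorus, n_patches, g = 50 * 2e5, 2e5, 5, 0.5
        fast = [
            disperse(total, sorus, n_patches, g, rng).sum() for _ in range(4000)
        ]
        loop = [
            disperse(total, sorus, n_patches, g, rng, method="per_sorus").sum()
            for _ in range(4000)
        ]
        assert ks_2samp(fast, loop).pvalue > 0.01


class TestReplicates:
    def test_full_determinism(self, pool):
        cfg = SimulationConfig(
            n_rounds=30, p=0.5, v_temp=0.01, environment_seed=5, demographic_seed=6
        )
        a, b = run_replicate(cfg, pool), run_replicate(cfg, pool)
        for phenotype in a:
            assert np.array_equal(a[phenotype].totals, b[phenotype].totals)

    def test_identical_pools_and_seeds_give_identical_trajectories(self, pool):
        """Phenotype symmetry: the dynamics depend only on the pool cells and seeds."""
        table = pd.concat(
            [
                pd.DataFrame(
                    {
                        "phenotype": phenotype,
                        "food_context": ["rich"] * 3 + ["poor"] * 3,
                        "clone_id": "x",
                        "date_id": "d",
                        "spores_per_plate": [1e8, 2e8, 3e8, 1e6, 2e6, 3e6],
                        "symbiont_od": 0.0,
                    }
                )
                for phenotype in ("agricolaris", "hayleyella")
            ]
        )
        shared = SporePool(table)
        cfg = SimulationConfig(n_rounds=25, p=0.5, v_temp=0.01, c=0.1)
        env = draw_environment(cfg)
        res_a = simulate_phenotype(
            "agricolaris", env, shared, cfg, np.random.default_rng(123)
        )
        res_h = simulate_phenotype(
            "hayleyella", env, shared, cfg, np.random.default_rng(123)
        )
        assert np.array_equal(res_a.totals, res_h.totals)

    def test_uninfected_extinct_in_nearly_all_poor_world(self, pool):
        """With ~99% food-poor patches the uninfected host collapses immediately."""
        cfg = SimulationConfig(
            n_rounds=20, n_replicates=10, p=0.99, v_temp=0.0, g=0.05
        )
        results = run_replicates(cfg, pool, master_seed=3)
        extinct = [results[r]["uninfected"].extinct for r in results]
        assert np.mean(extinct) > 0.8
        for r in results:
            res = results[r]["uninfected"]
            if res.extinct:
                assert res.geometric_mean == 0.0
                assert np.all(res.totals[res.extinction_round :] == 0.0)

    def test_infected_advantage_holds_across_p(self, pool, scaled_config):
        """Without infection costs the symbiont-carrying hosts win the long run."""
        for p in (0.2, 0.5, 0.8):
            cfg = SimulationConfig(
                n_patches=100, n_rounds=50, n_replicates=20, p=p, v_temp=0.01, c=0.0
            )
            results = run_replicates(cfg, pool, master_seed=17)
            wins = [
                results[r]["agricolaris"].geometric_mean
                > results[r]["uninfected"].geometric_mean
                for r in results
            ]
            assert np.mean(wins) >= 0.75

    def test_am_gm_and_absorbing_extinction_on_trajectories(self, pool):
        cfg = SimulationConfig(n_rounds=40, n_replicates=10, p=0.7, v_temp=0.05)
        results = run_replicates(cfg, pool, master_seed=21)
        for r in results:
            for res in results[r].values():
                assert res.geometric_mean <= res.arithmetic_mean * (1 + 1e-12)
                if (res.totals == 0).any():
                    assert res.geometric_mean == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationConfig(p=0.5, v_temp=0.3).validate()
        with pytest.raises(ValueError, match="p must"):
            SimulationConfig(p=1.5).validate()
        with pytest.raises(ValueError, match="g must"):
            SimulationConfig(g=0.0).validate()
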
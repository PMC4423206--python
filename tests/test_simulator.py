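import dataclasses

import numpy as np
import pytest

from ecorange.simulator import (
    ConfigError,
    Landscape,
    SimConfig,
    disperse,
    forage,
    front_position,
    generation_step,
    mutate,
    phenotype_from_traits,
    reproduce,
    resource_growth,
    run_simulation,
    sweep,
)


def tiny_cfg(**kw):
    base = dict(n_patches=12, n_core=3, burn_in=30, max_gen=200, n_init_per_patch=5, seed=1)
    base.update(kw)
    return SimConfig(**base)


def random_simplex(rng, n, k=4):
    t = rng.random((n, k))
    return t / t.sum(axis=1, keepdims=True)


class TestPhenotype:
    def test_zero_investment_means_zero_trait(self):
        cfg = SimConfig()
        ph = phenotype_from_traits(np.array([[0.0, 1.0, 0.0, 0.0]]), cfg)
        assert ph.d[0] == 0.0
        assert ph.a[0] == pytest.approx(cfg.a_max)
        assert ph.invb[0] == 0.0

    @pytest.mark.parametrize("d_max", [2.0, 3.0, 4.0])
    def test_dispersal_cap_triggers(self, d_max):
        # f_d = 0.5 gives raw rates {1.0, 1.5, 2.0}, all capped at probability 1
        cfg = SimConfig(d_max=d_max)
        ph = phenotype_from_traits(np.array([[0.5, 0.2, 0.2, 0.1]]), cfg)
        assert ph.d[0] == 1.0
        below = phenotype_from_traits(np.array([[0.1, 0.5, 0.3, 0.1]]), cfg)
        assert below.d[0] == pytest.approx(0.1 * d_max)

    def test_nonlinear_tradeoff_exponent(self):
        cfg = SimConfig(tradeoff_exponent=2.0, d_max=1.0)
        ph = phenotype_from_traits(np.array([[0.5, 0.5, 0.0, 0.0]]), cfg)
        assert ph.d[0] == pytest.approx(0.25)
        assert ph.a[0] == pytest.approx(0.25 * cfg.a_max)


class TestFourWayVariant:
    def test_assimilation_coefficient_evolves_on_extended_simplex(self):
        cfg = tiny_cfg(four_way=True, burn_in=15, max_gen=30, seed=8)
        assert cfg.n_trait_values == 5
        res = run_simulation(cfg)
        if not res.extinct:
            land = res.landscape
            assert land.traits.shape[1] == 5
            np.testing.assert_allclose(land.traits.sum(axis=1), 1.0, atol=1e-12)
            ph = phenotype_from_traits(land.traits, cfg)
            assert np.all(ph.e <= cfg.e_cap + 1e-12)
            assert ph.e.std() > 0  # e is individual, not fixed

    def test_fixed_e_without_four_way(self):
        cfg = tiny_cfg()
        ph = phenotype_from_traits(np.array([[0.25, 0.25, 0.25, 0.25]]), cfg)
        assert ph.e[0] == cfg.e


class TestResourceGrowth:
    def test_inflow_lifts_fixed_point_above_capacity(self):
        cfg = SimConfig(K=50.0, lambda0=4.0, inflow=0.1)
        assert resource_growth(50.0, cfg) == pytest.approx(55.0)

    def test_carrying_capacity_is_fixed_point(self):
        cfg = SimConfig(K=50.0, lambda0=4.0)
        assert resource_growth(50.0, cfg) == pytest.approx(50.0)
        assert resource_growth(0.0, cfg) == 0.0

    def test_hand_computed_value(self):
        # lambda0=4, K=50, N=10: 4*10 / (1 + (3/50)*10) = 25
        cfg = SimConfig(K=50.0, lambda0=4.0)
        assert resource_growth(10.0, cfg) == pytest.approx(25.0)

    def test_growth_rate_below_one_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(lambda0=0.5)


class TestForage:
    def test_no_resources_no_intake(self, rng):
        intakes, N_after = forage(0.0, [0.01, 0.02], [0.02, 0.02], rng)
        assert np.all(intakes == 0) and N_after == 0.0

    def test_refuge_floor_protected(self, rng):
        intakes, N_after = forage(5.0, [10.0], [10.0], rng, refuge_floor=5.0)
        assert np.all(intakes == 0) and N_after == 5.0

    def test_single_individual_saturates(self, rng):
        a_i, invb_i = 0.03, 0.02  # half-saturation 1/invb = 50 << N
        intakes, _ = forage(1e6, [a_i], [invb_i], rng)
        assert intakes[0] == pytest.approx(a_i, rel=1e-3)

    def test_zero_efficiency_is_not_a_division_error(self, rng):
        intakes, N_after = forage(50.0, [0.03], [0.0], rng)
        assert intakes[0] == 0.0 and N_after == 50.0

    def test_mass_balance_random_patches(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 40))
            N0 = float(rng.uniform(0, 60))
            a = rng.uniform(0, 0.05, n)
            invb = rng.uniform(0, 0.03, n)
            intakes, N_after = forage(N0, a, invb, rng)
            assert abs(intakes.sum() - (N0 - N_after)) < 1e-9
            assert N_after >= -1e-12


class TestReproduce:
    def test_no_intake_no_offspring(self, rng):
        counts = reproduce(np.zeros(1000), np.full(1000, 700.0), rng)
        assert np.all(counts == 0)

    def test_poisson_mean_and_variance(self, rng):
        # e=700, intake=0.015 -> mean 10.5 offspring
        counts = reproduce(np.full(100_000, 0.015), np.full(100_000, 700.0), rng)
        assert counts.mean() == pytest.approx(10.5, rel=0.01)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.03)


class TestMutate:
    def test_no_mutation_is_identity(self, rng):
        cfg = SimConfig(p_mut=0.0)
        t = random_simplex(rng, 50)
        np.testing.assert_array_equal(mutate(t, cfg, rng), t)

    def test_simplex_preserved_under_heavy_mutation(self, rng):
        cfg = SimConfig(p_mut=1.0)
        t = random_simplex(rng, 100_000)
        out = mutate(t, cfg, rng)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(out >= 0)

    def test_mutation_step_scale_matches_oracle(self, rng):
        # The post-mutation ratio of two trait values is (pre-normalization)
        # clip(x+eps1)/clip(x+eps2) with eps ~ N(0, mut_sd): compare a robust
        # spread statistic of log-ratios against a direct Monte-Carlo oracle.
        cfg = SimConfig(p_mut=1.0, mut_sd=0.2)
        t = np.full((100_000, 4), 0.25)
        out = mutate(t, cfg, rng)
        ok = (out[:, 0] > 0) & (out[:, 1] > 0)
        stat = np.median(np.abs(np.log(out[ok, 0] / out[ok, 1])))

        oracle_rng = np.random.default_rng(777)
        c = np.clip(0.25 + oracle_rng.normal(0, 0.2, (100_000, 2)), 0, None)
        ok_o = (c[:, 0] > 0) & (c[:, 1] > 0)
        oracle = np.median(np.abs(np.log(c[ok_o, 0] / c[ok_o, 1])))
        assert stat == pytest.approx(oracle, rel=0.05)

    def test_single_row_input(self, rng):
        cfg = SimConfig(p_mut=1.0)
        out = mutate(np.array([0.4, 0.3, 0.2, 0.1]), cfg, rng)
        assert out.shape == (4,)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestDisperse:
    def test_zero_rate_stays(self, rng):
        cfg = tiny_cfg()
        patch = np.array([0, 1, 2])
        new, alive = disperse(patch, np.zeros(3), cfg, rng)
        np.testing.assert_array_equal(new, patch)
        assert alive.all()

    def test_certain_death(self, rng):
        cfg = tiny_cfg(mu=1.0)
        _, alive = disperse(np.zeros(1000, dtype=int), np.ones(1000), cfg, rng)
        assert not alive.any()

    def test_burn_in_ring_wraps(self, rng):
        cfg = tiny_cfg(n_core=5, n_patches=100)
        new, alive = disperse(
            np.zeros(20_000, dtype=int), np.ones(20_000), cfg, rng, phase="burn_in"
        )
        dests, counts = np.unique(new, return_counts=True)
        assert set(dests) == {1, cfg.n_core - 1}
        assert counts[0] / counts.sum() == pytest.approx(0.5, abs=0.02)

    def test_reflecting_boundaries_in_expansion(self, rng):
        cfg = tiny_cfg()
        left = disperse(np.zeros(500, dtype=int), np.ones(500), cfg, rng)[0]
        assert set(np.unique(left)) == {1}
        right = disperse(
            np.full(500, cfg.n_patches - 1), np.ones(500), cfg, rng
        )[0]
        assert set(np.unique(right)) == {cfg.n_patches - 2}


class TestGenerationStep:
    def test_empty_landscape_resources_approach_capacity(self, rng):
        cfg = tiny_cfg()
        land = Landscape(
            N=np.full(cfg.n_patches, 1.0),
            traits=np.empty((0, 4)), patch=np.empty(0, dtype=int), intake=np.empty(0),
        )
        prev = land.N.copy()
        for _ in range(30):
            land = generation_step(land, cfg, rng)
            assert np.all(land.N >= prev - 1e-12)
            prev = land.N.copy()
        np.testing.assert_allclose(land.N, cfg.K, rtol=1e-6)

    def test_burn_in_containment(self, rng):
        cfg = tiny_cfg()
        traits = random_simplex(rng, cfg.n_core * 10)
        land = Landscape(
            N=np.full(cfg.n_patches, cfg.K),
            traits=traits,
            patch=np.repeat(np.arange(cfg.n_core), 10),
            intake=np.zeros(traits.shape[0]),
        )
        for _ in range(40):
            land = generation_step(land, cfg, rng, phase="burn_in")
            assert land.n_individuals == 0 or land.patch.max() < cfg.n_core

    def test_neutral_control_traits_constant(self, rng):
        # without mutation and with identical founders, selection has no
        # variation to act on: per-patch mean traits cannot change
        cfg = tiny_cfg(p_mut=0.0)
        founder = np.array([0.2, 0.4, 0.3, 0.1])
        traits = np.tile(founder, (30, 1))
        land = Landscape(
            N=np.full(cfg.n_patches, cfg.K),
            traits=traits,
            patch=np.repeat(np.arange(cfg.n_core), 10),
            intake=np.zeros(30),
        )
        for _ in range(25):
            land = generation_step(land, cfg, rng, phase="burn_in")
            if land.n_individuals:
                assert np.max(np.abs(land.traits - founder[None, :])) < 1e-12


class TestRunSimulation:
    def test_seed_determinism(self):
        cfg = tiny_cfg(seed=99, burn_in=40, max_gen=120)
        r1 = run_simulation(cfg)
        r2 = run_simulation(cfg)
        np.testing.assert_array_equal(r1.front_history, r2.front_history)
        assert r1.profile.equals(r2.profile)
        assert r1.generations == r2.generations

    def test_no_assimilation_means_extinction(self):
        res = run_simulation(tiny_cfg(e=0.0, burn_in=10))
        assert res.extinct and not res.completed

    def test_records_have_expected_shape(self):
        res = run_simulation(tiny_cfg(seed=3, burn_in=20, max_gen=60), record_every=1)
        if res.records is not None:
            assert set(res.records.columns) == {
                "generation", "patch", "density", "mean_d", "mean_invb", "resource_N"
            }
            assert res.records.patch.max() == res.config.n_patches - 1


class TestFrontPosition:
    def test_reference_cases(self):
        N = np.full(5, 10.0)
        empty = Landscape(N=N, traits=np.empty((0, 4)),
                          patch=np.empty(0, dtype=int), intake=np.empty(0))
        assert front_position(empty) == -1
        one = Landscape(N=N, traits=np.full((1, 4), 0.25),
                        patch=np.array([0]), intake=np.zeros(1))
        assert front_position(one) == 0


class TestSweep:
    def test_bookkeeping_and_reproducibility(self):
        base = tiny_cfg(burn_in=15, max_gen=40)
        grid = {"lambda0": [2.0], "mu": [0.0]}
        profiles, agg = sweep(grid, n_replicates=2, seed=5, base=base)
        assert profiles.replicate.nunique() == 2
        assert len(profiles) == 2 * base.n_patches
        assert len(agg) == base.n_patches
        profiles2, _ = sweep(grid, n_replicates=2, seed=5, base=base)
        assert profiles.equals(profiles2)
        profiles3, _ = sweep(grid, n_replicates=2, seed=6, base=base)
        assert not profiles.density.equals(profiles3.density)
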
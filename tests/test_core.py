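"""Cohort-and-stock simulator: process-level oracles and invariants."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import ecoperturb.core as core
from ecoperturb.climate import generate_environment, make_archetype
from ecoperturb.core import (
    MAX_BODY_MASS,
    MIN_BODY_MASS,
    Cohort,
    ModelParams,
    Stock,
    advance_month,
    compute_npp,
    dispersal_step,
    eat_step,
    grid_from_state,
    grid_state,
    grow_stocks,
    heterotroph_biomass,
    merge_cohorts,
    metabolism_step,
    mortality_step,
    reproduction_step,
    seed_grid,
    spin_up,
)

from conftest import AUTOTROPH, flat_env, make_cell, make_cohort, rng


class TestComputeNpp:
    def test_month_out_of_range_rejected(self):
        env = flat_env()
        for bad in (-1, 12, 3.5):
            with pytest.raises(ValueError):
                compute_npp(env, bad)

    def test_no_water_no_production(self):
        env = flat_env(precipitation=0.0, soil_water=0.0)
        assert all(compute_npp(env, m) == 0.0 for m in range(12))

    def test_nonnegative_and_seasonally_modulated(self):
        env = generate_environment(make_archetype("france_like"))
        values = [compute_npp(env, m) for m in range(12)]
        assert all(v >= 0 for v in values)
        ratio = [v / s for v, s in zip(values, env.npp_seasonality)]
        assert np.allclose(ratio, ratio[0])


class TestGrowStocks:
    def _gain(self, appropriation, turnover=0.0):
        params = replace(ModelParams(), stock_turnover=turnover)
        cell = make_cell(stock_biomass=1000.0, appropriation=appropriation)
        before = cell.stocks[0].biomass
        grow_stocks(cell, params, 0)
        return cell.stocks[0].biomass - before

    def test_full_appropriation_gains_nothing(self):
        assert self._gain(1.0) == 0.0

    def test_no_appropriation_no_turnover_adds_exact_npp_share(self):
        cell = make_cell(stock_biomass=0.0)
        expected = compute_npp(cell.environment, 0)
        assert self._gain(0.0) == pytest.approx(expected, rel=1e-12)

    def test_appropriation_term_is_linear(self):
        assert self._gain(0.5) == pytest.approx(0.5 * self._gain(0.0), rel=1e-12)

    def test_biomass_never_negative(self):
        params = replace(ModelParams(), stock_turnover=1.0)
        cell = make_cell(stock_biomass=10.0, appropriation=1.0)
        grow_stocks(cell, params, 0)
        assert cell.stocks[0].biomass >= 0.0


class TestEatStep:
    def test_nothing_to_eat(self, params):
        herb = make_cohort("herbivore", abundance=5.0, body_mass=10.0)
        cell = make_cell(stock_biomass=0.0, cohorts=[herb])
        before = herb.total_mass
        ledger = eat_step(cell, params, rng(), 0)
        assert ledger.records(herb) == []
        assert herb.total_mass == before

    def test_herbivory_mass_balance(self, params):
        herb = make_cohort("herbivore", abundance=10.0, body_mass=100.0)
        cell = make_cell(stock_biomass=1e6, cohorts=[herb])
        stock_before = cell.stocks[0].biomass
        mass_before = herb.total_mass
        ledger = eat_step(cell, params, rng(), 0)
        eaten = stock_before - cell.stocks[0].biomass
        assert eaten > 0
        assert ledger.total_eaten(herb) == pytest.approx(eaten, rel=1e-9)
        gained = herb.total_mass - mass_before
        assert gained == pytest.approx(
            params.assimilation_efficiency_herbivory * eaten, rel=1e-9
        )
        fractions = [f for _, f in ledger.dietary_fractions(herb)]
        assert sum(fractions) == pytest.approx(1.0, rel=1e-12)

    def test_prey_size_kernel_preference(self, params):
        carn = make_cohort("carnivore", abundance=2.0, body_mass=20.0,
                           optimal_prey_mass=1.0)
        small = make_cohort("herbivore", abundance=50.0, body_mass=1.0)
        large = make_cohort("herbivore", abundance=50.0, body_mass=1000.0)
        cell = make_cell(cohorts=[carn, small, large])
        ledger = eat_step(cell, params, rng(), 0)
        eaten = {id(prey): r.mass_eaten for r in ledger.records(carn)
                 for prey in [r.prey]}
        assert eaten.get(id(small), 0.0) > eaten.get(id(large), 0.0)

    def test_prey_losses_capped_by_availability(self, params):
        carn = make_cohort("carnivore", abundance=1e5, body_mass=10.0,
                           optimal_prey_mass=1.0)
        prey = make_cohort("herbivore", abundance=10.0, body_mass=1.0)
        cell = make_cell(cohorts=[carn, prey])
        before = prey.abundance
        eat_step(cell, params, rng(), 0)
        assert prey.abundance >= before * (1.0 - params.max_consumption_fraction) - 1e-12

    def test_general_per_eater_mass_balance(self, params):
        env = generate_environment(make_archetype("uganda_like"))
        grid = seed_grid(env, (1, 1), params)
        cell = grid.cell(0, 0)
        generator = rng(3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for month in range(12):
                advance_month(grid, params, month, generator)
        before = {id(c): c.total_mass for c in cell.cohorts}
        cohort_set = list(cell.cohorts)
        ledger = eat_step(cell, params, generator, 0)
        eaten_from = {}
        for eater, records in ledger.items():
            for r in records:
                if isinstance(r.prey, Cohort):
                    eaten_from[id(r.prey)] = eaten_from.get(id(r.prey), 0.0) + r.mass_eaten
        for c in cohort_set:
            plant = sum(r.mass_eaten for r in ledger.records(c)
                        if isinstance(r.prey, Stock))
            animal = sum(r.mass_eaten for r in ledger.records(c)
                         if isinstance(r.prey, Cohort))
            expected_gain = (params.assimilation_efficiency_herbivory * plant
                             + params.assimilation_efficiency_predation * animal)
            delta = c.total_mass - before[id(c)] + eaten_from.get(id(c), 0.0)
            assert delta == pytest.approx(expected_gain, rel=1e-9, abs=1e-9)


class TestMetabolism:
    def test_ectotherm_cost_increases_with_temperature(self, params):
        cold = make_cohort("herbivore", body_mass=100.0, thermoregulation="ectotherm")
        hot = make_cohort("herbivore", body_mass=100.0, thermoregulation="ectotherm")
        metabolism_step(make_cell(cohorts=[cold], env=flat_env(10.0)), params, 0)
        metabolism_step(make_cell(cohorts=[hot], env=flat_env(30.0)), params, 0)
        assert hot.body_mass < cold.body_mass

    def test_endotherm_cost_independent_of_temperature(self, params):
        a = make_cohort("herbivore", body_mass=100.0, thermoregulation="endotherm")
        b = make_cohort("herbivore", body_mass=100.0, thermoregulation="endotherm")
        metabolism_step(make_cell(cohorts=[a], env=flat_env(10.0)), params, 0)
        metabolism_step(make_cell(cohorts=[b], env=flat_env(30.0)), params, 0)
        assert a.body_mass == b.body_mass

    def test_cost_strictly_increasing_in_body_mass(self, params):
        masses = [1.0, 10.0, 100.0, 1000.0]
        costs = []
        for m in masses:
            c = make_cohort("herbivore", body_mass=m, adult_mass=m)
            metabolism_step(make_cell(cohorts=[c]), params, 0)
            costs.append(m - c.body_mass)
        assert all(a < b for a, b in zip(costs, costs[1:]))


class TestReproduction:
    def test_no_reproductive_mass_no_offspring(self, params):
        c = make_cohort("herbivore", body_mass=10.0, reproductive_mass=0.0)
        cell = make_cell(cohorts=[c])
        reproduction_step(cell, params, rng())
        assert cell.cohorts == [c]

    def test_semelparous_parent_dies_after_spawning(self, params):
        c = make_cohort("herbivore", abundance=4.0, body_mass=10.0,
                        reproductive_mass=5.0, reproductive_strategy="semelparous")
        cell = make_cell(cohorts=[c])
        reproduction_step(cell, params, rng())
        assert c.abundance == 0.0
        offspring = [x for x in cell.cohorts if x is not c]
        assert len(offspring) == 1
        assert offspring[0].body_mass == c.juvenile_mass

    def test_offspring_mass_exactly_conserves_reproductive_store(self, params):
        c = make_cohort("herbivore", abundance=7.0, body_mass=10.0,
                        reproductive_mass=6.0)
        cell = make_cell(cohorts=[c])
        expected = c.abundance * c.reproductive_mass
        reproduction_step(cell, params, rng())
        offspring = [x for x in cell.cohorts if x is not c]
        assert offspring[0].abundance * offspring[0].body_mass == pytest.approx(
            expected, rel=1e-9
        )
        assert c.reproductive_mass == 0.0
        assert c.abundance == 7.0  # iteroparous parent persists

    def test_below_store_gate_keeps_accumulating(self, params):
        juvenile = 3.0
        c = make_cohort("herbivore", body_mass=10.0, juvenile_mass=juvenile,
                        reproductive_mass=0.5 * juvenile * params.min_reproductive_ratio)
        cell = make_cell(cohorts=[c])
        reproduction_step(cell, params, rng())
        assert cell.cohorts == [c]
        assert c.reproductive_mass > 0.0


class TestMortality:
    def test_all_hazards_zero_is_identity(self):
        params = replace(ModelParams(), background_mortality=0.0,
                         starvation_mortality_rate=0.0, senescence_mortality_rate=0.0)
        c = make_cohort("herbivore", abundance=5.0)
        cell = make_cell(cohorts=[c])
        mortality_step(cell, params, rng())
        assert c.abundance == 5.0

    def test_starvation_raises_mortality(self, params):
        starving = make_cohort("herbivore", abundance=100.0, body_mass=0.2,
                               adult_mass=100.0, juvenile_mass=0.1)
        healthy = make_cohort("herbivore", abundance=100.0, body_mass=100.0,
                              adult_mass=100.0)
        cell = make_cell(cohorts=[starving, healthy])
        mortality_step(cell, params, rng())
        assert starving.abundance < healthy.abundance

    def test_extinction_threshold_removes_cohort(self, params):
        doomed = make_cohort("herbivore", abundance=0.5 * params.extinction_threshold)
        cell = make_cell(cohorts=[doomed])
        mortality_step(cell, params, rng())
        assert cell.cohorts == []


class TestDispersal:
    def test_zero_fraction_is_identity(self, params):
        env = generate_environment(make_archetype("libya_like"))
        grid = seed_grid(env, (2, 2), params)
        before = grid_state(grid)
        dispersal_step(grid, replace(params, dispersal_fraction=0.0), rng())
        assert grid_state(grid) == before

    def test_single_cell_grid_unchanged(self, params):
        env = generate_environment(make_archetype("libya_like"))
        grid = seed_grid(env, (1, 1), params)
        before = grid_state(grid)
        dispersal_step(grid, params, rng())
        assert grid_state(grid) == before

    def test_lineage_abundance_conserved(self, params):
        env = generate_environment(make_archetype("libya_like"))
        grid = seed_grid(env, (3, 3), params)

        def lineage_totals():
            totals = {}
            for cell in grid.cells():
                for c in cell.cohorts:
                    totals[c.lineage] = totals.get(c.lineage, 0.0) + c.abundance
            return totals

        before = lineage_totals()
        dispersal_step(grid, params, rng())
        after = lineage_totals()
        assert set(before) == set(after)
        for lineage, total in before.items():
            assert after[lineage] == pytest.approx(total, rel=1e-9)


class TestMerge:
    def test_under_cap_is_identity(self, params):
        cohorts = [make_cohort("herbivore", body_mass=m) for m in (1.0, 2.0)]
        cell = make_cell(cohorts=list(cohorts))
        merge_cohorts(cell, params)
        assert cell.cohorts == list(cohorts)

    def test_identical_pair_merges_to_summed_abundance(self):
        params = replace(ModelParams(), max_cohorts_per_cell=8)
        twins = [make_cohort("herbivore", abundance=5.0, body_mass=2.0)
                 for _ in range(2)]
        others = [make_cohort("herbivore", body_mass=m)
                  for m in (10.0, 30.0, 90.0, 300.0, 900.0, 3000.0, 9000.0)]
        cell = make_cell(cohorts=twins + others)
        merge_cohorts(cell, params)
        assert len(cell.cohorts) == 8
        merged = min(cell.cohorts, key=lambda c: c.body_mass)
        assert merged.abundance == 10.0
        assert merged.body_mass == 2.0

    def test_conserves_mass_and_abundance(self):
        params = replace(ModelParams(), max_cohorts_per_cell=10)
        generator = rng(5)
        cohorts = [
            make_cohort(
                "herbivore",
                abundance=float(generator.uniform(1, 100)),
                body_mass=float(m),
                adult_mass=float(m * 2),
                reproductive_mass=float(generator.uniform(0, 1)),
            )
            for m in generator.uniform(1, 1000, size=30)
        ]
        cell = make_cell(cohorts=cohorts)
        mass = sum(c.total_mass for c in cohorts)
        abundance = sum(c.abundance for c in cohorts)
        merge_cohorts(cell, params)
        assert len(cell.cohorts) <= 10
        assert sum(c.total_mass for c in cell.cohorts) == pytest.approx(mass, rel=1e-9)
        assert sum(c.abundance for c in cell.cohorts) == pytest.approx(abundance, rel=1e-9)

    def test_cap_advisory_when_no_mergeable_pair(self):
        params = replace(ModelParams(), max_cohorts_per_cell=8)
        cohorts = [
            make_cohort(tg, thermoregulation=thermo, reproductive_strategy=strategy)
            for tg in ("herbivore", "omnivore", "carnivore")
            for thermo in ("endotherm", "ectotherm")
            for strategy in ("semelparous", "iteroparous")
        ]
        cell = make_cell(cohorts=cohorts)
        with pytest.warns(RuntimeWarning, match="no mergeable"):
            merge_cohorts(cell, params)
        assert len(cell.cohorts) == 12


class TestAdvanceAndSpinUp:
    def test_empty_grid_stays_empty(self, params):
        grid = seed_grid(flat_env(), (2, 2), params)
        for cell in grid.cells():
            cell.stocks.clear()
            cell.cohorts.clear()
        advance_month(grid, params, 0, rng())
        assert all(not cell.cohorts and not cell.stocks for cell in grid.cells())

    def test_equal_seeds_bit_identical(self, params):
        env = generate_environment(make_archetype("libya_like"))
        states = []
        for _ in range(2):
            grid = seed_grid(env, (2, 2), params)
            generator = rng(11)
            for month in range(6):
                advance_month(grid, params, month, generator)
            states.append(grid_state(grid))
        assert states[0] == states[1]

    def test_different_seeds_diverge(self, params):
        env = generate_environment(make_archetype("uganda_like"))
        totals = []
        for seed in (1, 2):
            grid = seed_grid(env, (2, 2), params)
            generator = rng(seed)
            for month in range(12):
                advance_month(grid, params, month, generator)
            totals.append(heterotroph_biomass(grid))
        assert totals[0] != totals[1]

    def test_spin_up_rejects_zero_years_and_nonzero_impact(self, params):
        env = generate_environment(make_archetype("libya_like"))
        grid = seed_grid(env, (1, 1), params)
        with pytest.raises(ValueError):
            spin_up(grid, params, 0, rng())
        grid.cell(0, 0).appropriation_fraction = 0.5
        with pytest.raises(ValueError):
            spin_up(grid, params, 1, rng())

    def test_save_restore_round_trip_preserves_trajectory(self, params):
        env = generate_environment(make_archetype("libya_like"))
        grid = seed_grid(env, (2, 2), params)
        generator = rng(4)
        for month in range(12):
            advance_month(grid, params, month, generator)
        snapshot = grid_state(grid)
        rng_state = generator.bit_generator.state
        # path A: continue the original
        for month in range(12):
            advance_month(grid, params, month, generator)
        state_a = grid_state(grid)
        # path B: restore and advance the same months
        restored = grid_from_state(snapshot)
        g2 = np.random.default_rng()
        g2.bit_generator.state = rng_state
        for month in range(12):
            advance_month(restored, params, month, g2)
        assert grid_state(restored) == state_a

    def test_no_production_drives_heterotrophs_to_collapse(self, params):
        grid = seed_grid(flat_env(precipitation=0.0, soil_water=0.0), (1, 1), params)
        initial = heterotroph_biomass(grid)
        generator = rng(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for step in range(240):
                advance_month(grid, params, step % 12, generator)
                if heterotroph_biomass(grid) < 0.01 * initial:
                    break
        assert heterotroph_biomass(grid) < 0.01 * initial

    def test_state_stays_within_bounds(self, params):
        env = generate_environment(make_archetype("gobi_like"))
        grid = seed_grid(env, (2, 2), params)
        generator = rng(9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for step in range(36):
                advance_month(grid, params, step % 12, generator)
                for cell in grid.cells():
                    assert all(s.biomass >= 0 for s in cell.stocks)
                    for c in cell.cohorts:
                        assert MIN_BODY_MASS <= c.body_mass <= MAX_BODY_MASS
                        assert c.abundance >= 0
                        assert c.reproductive_mass >= 0
                        assert c.trophic_index >= 1.0
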
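import dataclasses

import numpy as np
import pytest

from cohortcomp import (ImmigrationFlows, ProjectionAssumptions,
                        RateMagnitudeError, ValidationError, advance_cohort,
                        constrain_immigration, project_births, run_projection,
                        step_year)
from cohortcomp.projection import accounting_residual
from cohortcomp.synthetic import ScenarioBundle

from conftest import toy_grid, uniform_flows, uniform_rates


class TestAdvanceCohort:
    def test_closed_system_no_mortality(self):
        assert advance_cohort(1000, 0, 0, 0) == (1000.0, 0.0, 0.0)

    def test_mortality_only_algebraic_solution(self):
        p_end, deaths, _ = advance_cohort(1000, 0.1, 0, 0)
        assert p_end == pytest.approx(1000 * 0.95 / 1.05, abs=1e-4)
        assert p_end == pytest.approx(904.7619, abs=1e-4)

    def test_inflow_with_losses_balances(self):
        p_end, deaths, emig = advance_cohort(0, 0.5, 0.1, 100)
        assert p_end == pytest.approx(76.9231, abs=1e-4)
        assert deaths == pytest.approx(19.2308, abs=1e-4)
        assert emig == pytest.approx(3.8462, abs=1e-4)
        # the accounting identity closes on the same person-years
        assert 0 - deaths + 100 - emig == pytest.approx(p_end, abs=1e-9)

    def test_excessive_rates_raise(self):
        with pytest.raises(RateMagnitudeError):
            advance_cohort(100, 1.5, 0.6, 0)


class TestProjectBirths:
    def test_zero_fertility(self):
        z = np.zeros((2, 3))
        assert project_births(z, z + 100, z + 100) == 0.0

    def test_direct_product(self):
        fert = np.array([[0.08]])
        assert project_births(fert, np.array([[500.0]]),
                              np.array([[500.0]])) == pytest.approx(40.0)

    def test_sum_over_birthplaces(self):
        fert = np.array([[0.1], [0.05]])
        start = np.array([[1000.0], [2000.0]])
        assert project_births(fert, start, start) == pytest.approx(200.0)

    def test_misaligned_domains_rejected(self):
        with pytest.raises(ValidationError):
            project_births(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 4)))


class TestConstrainImmigration:
    def test_identity_when_total_matches(self):
        imm = uniform_flows(2, 3, per_cell=10.0)
        out = constrain_immigration(imm, imm.total())
        np.testing.assert_allclose(out.flows, imm.flows, rtol=1e-12)

    def test_uniform_scaling_preserves_shares(self):
        imm = uniform_flows(2, 3, per_cell=10.0, newborn=2.0)
        base = imm.total()
        out = constrain_immigration(imm, 1.25 * base)
        np.testing.assert_allclose(out.flows, 12.5)
        np.testing.assert_allclose(out.flows_birth, 2.5)
        assert out.total() == pytest.approx(1.25 * base, rel=1e-10)

    def test_zero_total_gives_zero_flows(self):
        out = constrain_immigration(uniform_flows(2, 3, per_cell=10.0), 0.0)
        assert out.total() == 0.0

    def test_zero_base_with_positive_target_rejected(self):
        with pytest.raises(ValidationError):
            constrain_immigration(uniform_flows(2, 3), 100.0)


class TestStepYear:
    def test_pure_cohort_shift(self):
        pop = toy_grid([50.0, 60.0, 70.0, 80.0])
        rates = uniform_rates(2, 4)
        out, _ = step_year(pop, rates, uniform_flows(2, 4))
        np.testing.assert_array_equal(out.counts[:, :, 1:3], pop.counts[:, :, 0:2])
        # open interval keeps its own survivors plus the incoming cohort
        np.testing.assert_allclose(out.counts[:, :, 3],
                                   pop.counts[:, :, 2] + pop.counts[:, :, 3])
        assert np.all(out.counts[:, :, 0] == 0)

    def test_matches_cell_by_cell_hand_oracle(self):
        # 2 birthplaces x 3 ages, d=0.01, e=0, I=10/cell, no fertility:
        # every cell follows the implicit one-cohort balance independently
        pop = toy_grid([100.0, 200.0, 300.0])
        rates = uniform_rates(2, 3, death=0.01)
        imm = uniform_flows(2, 3, per_cell=10.0)
        out, flows = step_year(pop, rates, imm)

        def cell(p_start):
            return (p_start * (1 - 0.005) + 10.0) / (1 + 0.005)

        expected_age1 = cell(100.0)
        expected_age2 = cell(200.0) + cell(300.0)
        for i in range(2):
            for s in range(2):
                assert out.counts[i, s, 0] == pytest.approx(0.0, abs=1e-9)
                assert out.counts[i, s, 1] == pytest.approx(expected_age1,
                                                            abs=1e-6)
                assert out.counts[i, s, 2] == pytest.approx(expected_age2,
                                                            abs=1e-6)
        # deaths recomputed from the same person-years
        py = 0.5 * (100.0 + cell(100.0))
        assert flows.deaths[0, 0, 0] == pytest.approx(0.01 * py, abs=1e-6)

    def test_births_credited_to_native_born_only(self):
        pop = toy_grid([0.0, 1000.0, 10.0], n_birthplaces=3)
        rates = uniform_rates(3, 3)
        rates.fertility[:, 1] = 0.1   # all birthplaces fertile
        out, flows = step_year(pop, rates, uniform_flows(3, 3))
        # mid-year female person-years at age 1: (1000 + 0)/2 per birthplace
        assert flows.births[0].sum() == pytest.approx(3 * 0.1 * 500.0)
        assert np.all(flows.births[1:] == 0)
        assert out.counts[0, :, 0].sum() == pytest.approx(150.0)
        assert np.all(out.counts[1:, :, 0] == 0)

    def test_sex_ratio_at_birth_split(self):
        pop = toy_grid([0.0, 1000.0, 10.0], n_birthplaces=2)
        rates = uniform_rates(2, 3)
        rates.fertility[:, 1] = 0.05
        out, flows = step_year(pop, rates, uniform_flows(2, 3),
                               sex_ratio_at_birth=105.0)
        assert flows.births[0, 1] / flows.births[0, 0] == pytest.approx(1.05)


class TestRunProjection:
    def test_zero_horizon_returns_jump_off(self, bundle):
        out = run_projection(bundle, horizon_years=0)
        assert len(out.grids) == 1
        np.testing.assert_array_equal(out.final.counts, bundle.jump_off.counts)

    def test_cohort_shift_oracle_all_rates_zero(self, bundle):
        zero = _zero_everything(bundle)
        out = run_projection(zero, ProjectionAssumptions(e0_annual_gain=0.0),
                             horizon_years=25)
        for k in (1, 10, 25):
            shifted = out.grids[k].aged_at_least(65)
            np.testing.assert_array_equal(shifted,
                                          zero.jump_off.aged_at_least(65 - k))

    def test_accounting_identity_holds(self, bundle):
        out = run_projection(bundle, horizon_years=10)
        assert accounting_residual(out) < 1e-9

    def test_no_migration_variant_overseas_born_non_increasing(self, bundle):
        out = run_projection(bundle, ProjectionAssumptions(no_migration=True),
                             horizon_years=10)
        totals = np.array([g.counts[1:].sum(axis=(1, 2)) for g in out.grids])
        assert np.all(np.diff(totals, axis=0) <= 1e-9)

    def test_overseas_born_receive_no_births_ever(self, bundle):
        out = run_projection(bundle, horizon_years=5)
        for flows in out.components:
            assert np.all(flows.births[1:] == 0)

    def test_raising_immigration_total_weakly_increases_everyone(self, bundle):
        lo = run_projection(bundle, horizon_years=8)
        boosted = ScenarioBundle(
            bundle.jump_off, bundle.rates,
            dataclasses.replace(
                bundle.immigration,
                national_total_by_year={y: 1.5 * v for y, v in
                                        bundle.immigration.national_total_by_year.items()}),
            bundle.classification, bundle.config_echo)
        hi = run_projection(boosted, horizon_years=8)
        assert np.all(hi.final.counts.sum(axis=(1, 2))
                      >= lo.final.counts.sum(axis=(1, 2)) - 1e-9)

    def test_mortality_trend_reduces_deaths_vs_fixed(self, bundle):
        trended = run_projection(bundle, ProjectionAssumptions(), 10)
        fixed = run_projection(bundle,
                               ProjectionAssumptions(fixed_mortality=True), 10)
        assert trended.final.total() > fixed.final.total()

    def test_deterministic_given_inputs(self, bundle):
        a = run_projection(bundle, horizon_years=5)
        b = run_projection(bundle, horizon_years=5)
        np.testing.assert_array_equal(a.final.counts, b.final.counts)


def _zero_everything(bundle) -> ScenarioBundle:
    """Variant of a bundle with all rates and flows zeroed and counts
    rounded to whole persons, so cohort shifts are exact in floating point."""
    n_bp, _, n_ages = bundle.jump_off.counts.shape
    from cohortcomp import PopulationGrid
    rounded = PopulationGrid(np.round(bundle.jump_off.counts),
                             bundle.jump_off.reference_year,
                             bundle.jump_off.birthplaces)
    return ScenarioBundle(
        rounded,
        uniform_rates(n_bp, n_ages),
        ImmigrationFlows(np.zeros((n_bp, 2, n_ages)), np.zeros((n_bp, 2)),
                         {bundle.jump_off.reference_year: 0.0}),
        bundle.classification, bundle.config_echo)
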
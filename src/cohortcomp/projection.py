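"""Multi-birthplace cohort-component projection engine.

The engine advances a population grid one year at a time through the
demographic accounting identity applied per birthplace i, sex s and
period-cohort a -> a+1:

    P[i,s,a+1](t+1) = P[i,s,a](t) - D + I - E

Deaths D and emigration E are occurrence-exposure products of rates with
person-years at risk, approximated by the mean of the start- and
end-of-year cohort populations; because the end population appears on both
sides, each cohort is solved implicitly:

    P_end = (P_start * (1 - (d+e)/2) + I) / (1 + (d+e)/2)

Immigration is applied directly as flows (not rates), scaled each year so
that the national inflow follows the assumed total trajectory.  Births are
the product of age-specific fertility rates and mid-year female
person-years; every birth, whatever the mother's birthplace, is added to
the native-born population (birthplace 0).  The top age is an open
interval advanced as its own period-cohort, and newborns pass through a
birth -> age-0 cohort with its own rates and immigrant newborns.

Mortality assumptions enter as life-expectancy targets: each projection
year the base death-rate schedules are proportionally rescaled so that
every birthplace-sex life table tracks a rising national e0 trend at its
fixed differential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import RateMagnitudeError, ValidationError
from .grids import (FEMALE, MALE, ComponentFlows, ImmigrationFlows,
                    PopulationGrid, RateSchedules)
from .lifetables import cumulative_e0_gain, find_e0_scale_factor, life_expectancy
from .synthetic import ScenarioBundle

logger = logging.getLogger(__name__)

#: Default sex ratio at birth, male births per 100 female births.
SEX_RATIO_AT_BIRTH = 105.0

#: Default annual national gain in life expectancy at birth (years/year),
#: continuing the long-run improvement trend.
E0_ANNUAL_GAIN = 0.15


@dataclass
class ProjectionAssumptions:
    """Per-scenario assumptions held constant over the horizon.

    ``fixed_mortality`` freezes jump-off death rates (the fixed-life-
    expectancy variant); ``no_migration`` zeroes both immigration and
    emigration (the no-international-migration variant).
    """

    e0_annual_gain: float = E0_ANNUAL_GAIN
    e0_damping: float = 1.0
    sex_ratio_at_birth: float = SEX_RATIO_AT_BIRTH
    fixed_mortality: bool = False
    no_migration: bool = False
    e0_scale_tol: float = 1e-6

    def variant(self, **changes) -> "ProjectionAssumptions":
        return replace(self, **changes)


@dataclass
class ProjectionOutput:
    """Yearly population grids (jump-off first) and component flows."""

    grids: list[PopulationGrid]
    components: list[ComponentFlows]
    assumptions: ProjectionAssumptions

    @property
    def jump_off(self) -> PopulationGrid:
        return self.grids[0]

    @property
    def final(self) -> PopulationGrid:
        return self.grids[-1]

    def growth_aged_at_least(self, threshold: int) -> np.ndarray:
        """End-minus-start population aged >= threshold, per birthplace."""
        return (self.final.aged_at_least(threshold)
                - self.jump_off.aged_at_least(threshold))


def advance_cohort(p_start, d, e, i_flow):
    """Advance one period-cohort through the implicit mid-period balance.

    Accepts scalars or aligned arrays.  Returns (p_end, deaths, emigrants),
    all computed from the same person-years at risk.
    """
    p_start = np.asarray(p_start, dtype=float)
    d = np.asarray(d, dtype=float)
    e = np.asarray(e, dtype=float)
    i_flow = np.asarray(i_flow, dtype=float)
    r = d + e
    if np.any(r >= 2.0):
        raise RateMagnitudeError(
            "death + emigration rate >= 2/year: the mid-period person-years "
            "approximation is invalid at this magnitude")
    p_end = (p_start * (1.0 - r / 2.0) + i_flow) / (1.0 + r / 2.0)
    if np.any(p_end < 0):
        logger.warning("negative end-of-year cohort population clipped to zero")
        p_end = np.clip(p_end, 0.0, None)
    person_years = 0.5 * (p_start + p_end)
    deaths = d * person_years
    emigrants = e * person_years
    if p_start.ndim == 0:
        return float(p_end), float(deaths), float(emigrants)
    return p_end, deaths, emigrants


def project_births(fertility: np.ndarray, female_start: np.ndarray,
                   female_end: np.ndarray) -> float:
    """Total births over one year from mid-year female person-years.

    ``fertility`` is (n_bp, n_ages) rates by mother's birthplace and age;
    the slices are the female population by (birthplace, age) at the start
    and end of the year.  The total is credited to the native-born
    population by the caller regardless of the mother's birthplace.
    """
    fertility = np.asarray(fertility, dtype=float)
    female_start = np.asarray(female_start, dtype=float)
    female_end = np.asarray(female_end, dtype=float)
    if not (fertility.shape == female_start.shape == female_end.shape):
        raise ValidationError("fertility and female population slices misaligned")
    return float((fertility * 0.5 * (female_start + female_end)).sum())


def constrain_immigration(base: ImmigrationFlows, year_total: float) -> ImmigrationFlows:
    """Scale all inflow cells so they sum to the national year total,
    preserving age-sex-birthplace shares."""
    if year_total < 0:
        raise ValidationError("year_total must be >= 0")
    base_sum = base.total()
    if base_sum <= 0:
        if year_total == 0:
            return base.scaled(0.0)
        raise ValidationError("cannot constrain all-zero base flows to a positive total")
    return base.scaled(year_total / base_sum)


def step_year(pop: PopulationGrid, rates: RateSchedules, imm: ImmigrationFlows,
              sex_ratio_at_birth: float = SEX_RATIO_AT_BIRTH
              ) -> tuple[PopulationGrid, ComponentFlows]:
    """Advance the whole grid one year.

    Order of operations: every closed period-cohort and the open interval
    are advanced through the implicit balance (the open interval receives
    both its own survivors and the cohort ageing in from top-1); births are
    then computed from start- and end-of-year female populations and passed
    through the birth -> age-0 cohort with its own rates and immigrant
    newborns.
    """
    n_bp, _, n_ages = pop.counts.shape
    if rates.death.shape != pop.counts.shape or imm.flows.shape != pop.counts.shape:
        raise ValidationError("rates/flows domain does not match population grid")

    new = np.zeros_like(pop.counts)
    # closed cohorts a -> a+1 for a = 0..top-1
    p_end, deaths_c, emig_c = advance_cohort(
        pop.counts[:, :, :-1], rates.death[:, :, :-1],
        rates.emigration[:, :, :-1], imm.flows[:, :, :-1])
    new[:, :, 1:] = p_end
    # open interval as its own period-cohort
    p_top, deaths_top, emig_top = advance_cohort(
        pop.counts[:, :, -1], rates.death[:, :, -1],
        rates.emigration[:, :, -1], imm.flows[:, :, -1])
    new[:, :, -1] += p_top

    deaths = np.concatenate([deaths_c, deaths_top[:, :, None]], axis=2)
    emigration = np.concatenate([emig_c, emig_top[:, :, None]], axis=2)

    # births from mid-year female person-years, all credited to birthplace 0
    total_births = project_births(rates.fertility, pop.counts[:, FEMALE, :],
                                  new[:, FEMALE, :])
    male_share = sex_ratio_at_birth / (100.0 + sex_ratio_at_birth)
    births = np.zeros((n_bp, 2))
    births[0, FEMALE] = total_births * (1.0 - male_share)
    births[0, MALE] = total_births * male_share

    # birth -> age 0 cohort, with immigrant newborns
    p0, deaths_b, emig_b = advance_cohort(births, rates.death_birth,
                                          rates.emigration_birth, imm.flows_birth)
    new[:, :, 0] = p0

    out = PopulationGrid(new, pop.reference_year + 1, pop.birthplaces)
    flows = ComponentFlows(pop.reference_year, births, deaths, imm.flows.copy(),
                           emigration, deaths_b, imm.flows_birth.copy(), emig_b)
    return out, flows


def _immigration_total_for(imm: ImmigrationFlows, year: int) -> float:
    """National inflow target for one projection year, extrapolating the
    trajectory's linear trend if the year lies beyond it."""
    totals = imm.national_total_by_year
    if year in totals:
        return totals[year]
    if not totals:
        return imm.total()
    years = sorted(totals)
    if len(years) == 1:
        return totals[years[0]]
    slope = (totals[years[-1]] - totals[years[0]]) / (years[-1] - years[0])
    return max(0.0, totals[years[-1]] + slope * (year - years[-1]))


def _mortality_factors(base_death: np.ndarray, e0_base: np.ndarray,
                       gain: float, tol: float) -> np.ndarray:
    """Per-(birthplace, sex) scaling factors hitting e0_base + gain."""
    n_bp, n_sex, _ = base_death.shape
    factors = np.ones((n_bp, n_sex))
    for i in range(n_bp):
        for s in range(n_sex):
            factors[i, s] = find_e0_scale_factor(base_death[i, s],
                                                 e0_base[i, s] + gain, tol)
    return factors


def run_projection(bundle: ScenarioBundle,
                   assumptions: ProjectionAssumptions | None = None,
                   horizon_years: int = 40) -> ProjectionOutput:
    """Project a scenario over a horizon of whole years.

    Fertility rates and emigration rates stay constant throughout; death
    rates are rescaled each year to life-expectancy targets that rise with
    the national trend at fixed birthplace-sex differentials (mid-period
    targets), unless ``fixed_mortality`` holds them at jump-off levels;
    immigration flows are constrained each year to the national total
    trajectory (zero under ``no_migration``).
    """
    if horizon_years < 0:
        raise ValidationError("horizon_years must be >= 0")
    assumptions = assumptions or ProjectionAssumptions()

    rates = bundle.rates
    imm_base = bundle.immigration
    if assumptions.no_migration:
        rates = rates.without_emigration()

    scale_mortality = (not assumptions.fixed_mortality
                       and assumptions.e0_annual_gain != 0.0)
    if scale_mortality:
        e0_base = np.array([[life_expectancy(rates.death[i, s])
                             for s in range(2)]
                            for i in range(rates.death.shape[0])])

    grids = [bundle.jump_off.copy()]
    components: list[ComponentFlows] = []
    pop = grids[0]
    for t in range(horizon_years):
        year = pop.reference_year
        if scale_mortality:
            gain = cumulative_e0_gain(assumptions.e0_annual_gain, t + 0.5,
                                      assumptions.e0_damping)
            factors = _mortality_factors(rates.death, e0_base, gain,
                                         assumptions.e0_scale_tol)
            rates_t = rates.with_scaled_mortality(factors)
        else:
            rates_t = rates
        if assumptions.no_migration:
            imm_t = imm_base.scaled(0.0)
        else:
            imm_t = constrain_immigration(imm_base,
                                          _immigration_total_for(imm_base, year))
        pop, flows = step_year(pop, rates_t, imm_t,
                               assumptions.sex_ratio_at_birth)
        logger.info("projected %d -> %d: total %.0f", year, year + 1, pop.total())
        grids.append(pop)
        components.append(flows)
    return ProjectionOutput(grids, components, assumptions)


def accounting_residual(output: ProjectionOutput) -> float:
    """Largest relative violation of the per-birthplace accounting identity
    total(t+1) - total(t) = B - D + I - E across all projected years."""
    worst = 0.0
    for t, flows in enumerate(output.components):
        start = output.grids[t].counts.sum(axis=(1, 2))
        end = output.grids[t + 1].counts.sum(axis=(1, 2))
        comp = flows.totals_by_birthplace()
        expected = (start + comp["births"].to_numpy() - comp["deaths"].to_numpy()
                    + comp["immigration"].to_numpy() - comp["emigration"].to_numpy())
        scale = np.maximum(np.abs(end), 1.0)
        worst = max(worst, float(np.max(np.abs(end - expected) / scale)))
    return worst
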
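"""Base-period migration calibration for population accounting consistency.

Projecting a start-year population forward with base-period rates and
flows should reproduce the observed end-year population; when it does not,
the discrepancy is absorbed into immigration.  One scale factor per
(birthplace, sex) is applied to the inflow schedule and solved iteratively
so the n-year projection matches the target's birthplace-sex totals.  An
optional second pass reshapes the inflow age profile against the target's
age detail and re-solves the scalars, leaving totals intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError
from .grids import ImmigrationFlows, PopulationGrid, RateSchedules
from .ipf import MarginalSpec, ipf_fit
from .projection import ProjectionAssumptions, run_projection
from .synthetic import ScenarioBundle

DEFAULT_TOL = 1e-6
MAX_ROUNDS = 50


@dataclass
class CalibrationDiagnostics:
    """Converged factors and the residual structure calibration cannot fix."""

    factors: np.ndarray                 # (n_bp, 2)
    rounds: int
    max_relative_residual: float        # on (birthplace, sex) totals
    age_abs_discrepancy: np.ndarray     # (n_bp, 2, n_ages), |projected - target|

    def summary(self) -> dict:
        return {
            "rounds": self.rounds,
            "max_relative_residual": self.max_relative_residual,
            "factor_min": float(self.factors.min()),
            "factor_max": float(self.factors.max()),
            "age_discrepancy_total": float(self.age_abs_discrepancy.sum()),
        }


def _project_totals(pop_start: PopulationGrid, rates: RateSchedules,
                    imm: ImmigrationFlows, factors: np.ndarray, n_years: int,
                    assumptions: ProjectionAssumptions) -> tuple[np.ndarray, PopulationGrid]:
    bundle = ScenarioBundle(pop_start, rates, imm.scaled(factors), None, None)
    out = run_projection(bundle, assumptions, n_years)
    return out.final.totals_by_birthplace_sex(), out.final


def calibrate_migration(pop_start: PopulationGrid, pop_target: PopulationGrid,
                        rates: RateSchedules, imm: ImmigrationFlows,
                        n_years: int, tol: float = DEFAULT_TOL,
                        max_rounds: int = MAX_ROUNDS,
                        assumptions: ProjectionAssumptions | None = None,
                        age_pattern_pass: bool = False
                        ) -> tuple[ImmigrationFlows, CalibrationDiagnostics]:
    """Scale immigration so an n-year projection reproduces the target.

    Uses an element-wise secant iteration on per-(birthplace, sex) factors.
    Base-period projections use jump-off mortality as-is (no trend) unless
    other assumptions are supplied.  A factor driven below zero means the
    target is unreachable by inflow scaling alone and raises
    :class:`CalibrationError` suggesting an emigration adjustment.
    """
    if pop_target.reference_year != pop_start.reference_year + n_years:
        raise CalibrationError(
            "target reference year must be start year + n_years "
            f"({pop_target.reference_year} != {pop_start.reference_year} + {n_years})")
    assumptions = assumptions or ProjectionAssumptions(fixed_mortality=True)
    # the projection constrains flows to the trajectory; calibration must
    # control the volumes directly, so drop the totals from the base flows
    base = ImmigrationFlows(imm.flows.copy(), imm.flows_birth.copy(), {})

    target = pop_target.totals_by_birthplace_sex()
    denom = np.maximum(target, 1.0)

    factors = np.ones_like(target)
    totals, final = _project_totals(pop_start, rates, base, factors, n_years,
                                    assumptions)
    prev_f, prev_t = factors.copy(), totals.copy()
    residual = float(np.max(np.abs(totals - target) / denom))
    rounds = 0
    if residual >= tol:
        factors = factors + 0.5   # open the secant bracket
        for rounds in range(1, max_rounds + 1):
            totals, final = _project_totals(pop_start, rates, base, factors,
                                            n_years, assumptions)
            residual = float(np.max(np.abs(totals - target) / denom))
            if residual < tol:
                break
            slope = totals - prev_t
            step = np.where(np.abs(slope) > 1e-12,
                            (target - totals) * (factors - prev_f)
                            / np.where(np.abs(slope) > 1e-12, slope, 1.0),
                            0.0)
            prev_f, prev_t = factors.copy(), totals.copy()
            factors = factors + step
            if np.any(factors < 0):
                bad = np.argwhere(factors < 0).tolist()
                raise CalibrationError(
                    f"calibration requires negative inflow factors at "
                    f"(birthplace, sex) {bad}; the target is unreachable by "
                    "immigration scaling alone - consider adjusting emigration")
        else:
            raise CalibrationError(
                f"calibration did not converge in {max_rounds} rounds; "
                f"max relative residual {residual:.3e}")

    adjusted = base.scaled(factors)
    if age_pattern_pass:
        adjusted = _reshape_age_pattern(adjusted, final, pop_target)
        adjusted.national_total_by_year.update(imm.national_total_by_year)
        # re-solve the scalars so totals stay consistent after reshaping
        return calibrate_migration(pop_start, pop_target, rates, adjusted,
                                   n_years, tol, max_rounds, assumptions,
                                   age_pattern_pass=False)

    _, final = _project_totals(pop_start, rates, base, factors, n_years,
                               assumptions)
    diag = CalibrationDiagnostics(
        factors=factors, rounds=rounds,
        max_relative_residual=residual,
        age_abs_discrepancy=np.abs(final.counts - pop_target.counts))
    adjusted.national_total_by_year.update(imm.national_total_by_year)
    return adjusted, diag


def _reshape_age_pattern(imm: ImmigrationFlows, projected: PopulationGrid,
                         target: PopulationGrid) -> ImmigrationFlows:
    """Tilt the inflow age profile towards the target's age structure while
    preserving each (birthplace, sex) volume via a one-marginal IPF."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(projected.counts > 0,
                         target.counts / np.where(projected.counts > 0,
                                                  projected.counts, 1.0), 1.0)
    ratio = np.clip(ratio, 0.2, 5.0)
    tilted = imm.flows * ratio
    totals = imm.flows.sum(axis=2)
    reshaped = np.zeros_like(tilted)
    for i in range(tilted.shape[0]):
        for s in range(tilted.shape[1]):
            if tilted[i, s].sum() > 0 and totals[i, s] > 0:
                reshaped[i, s] = ipf_fit(
                    tilted[i, s][None, :],
                    [MarginalSpec(0, np.array([totals[i, s]]))])[0]
    return ImmigrationFlows(reshaped, imm.flows_birth.copy(),
                            dict(imm.national_total_by_year))
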
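"""Variant-projection decomposition of older-population growth.

Growth of the population aged >= a threshold between the jump-off year and
the horizon end is attributed to three drivers by re-running the projection
under counterfactual variants sharing every other assumption:

* life expectancy: main minus the fixed-life-expectancy variant;
* international migration: main minus the no-migration variant (which
  zeroes immigration and emigration alike, since both flows make up the
  migration effect);
* cohort flow: the remainder - growth caused by differently sized cohorts
  crossing the age threshold, shaped by demographic history before the
  jump-off year.

The scheme ignores the mortality-migration interaction; an optional fourth
variant (both switched off) quantifies that interaction as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .projection import ProjectionAssumptions, ProjectionOutput, run_projection
from .synthetic import ScenarioBundle


@dataclass
class DecompositionResult:
    """Additive growth contributions per birthplace for ages >= threshold."""

    birthplaces: tuple[str, ...]
    total_growth: np.ndarray
    contrib_life_expectancy: np.ndarray
    contrib_migration: np.ndarray
    contrib_cohort_flow: np.ndarray
    age_threshold: int
    horizon: tuple[int, int]                 # (start_year, end_year)
    interaction: np.ndarray | None = None
    main_output: ProjectionOutput | None = None

    def national(self) -> dict[str, float]:
        return {
            "total_growth": float(self.total_growth.sum()),
            "contrib_life_expectancy": float(self.contrib_life_expectancy.sum()),
            "contrib_migration": float(self.contrib_migration.sum()),
            "contrib_cohort_flow": float(self.contrib_cohort_flow.sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "birthplace": list(self.birthplaces),
            "contrib_life_expectancy": self.contrib_life_expectancy,
            "contrib_migration": self.contrib_migration,
            "contrib_cohort_flow": self.contrib_cohort_flow,
            "total": self.total_growth,
        })


def decompose_growth(bundle: ScenarioBundle,
                     assumptions: ProjectionAssumptions | None = None,
                     horizon_years: int = 40, age_threshold: int = 65,
                     interaction_diagnostic: bool = False,
                     keep_output: bool = True) -> DecompositionResult:
    """Run the main projection and its two variants and attribute growth."""
    assumptions = assumptions or ProjectionAssumptions()
    if not 0 <= age_threshold <= bundle.jump_off.top_age:
        raise ValidationError("age_threshold outside the grid's age range")

    main = run_projection(bundle, assumptions, horizon_years)
    fixed = run_projection(bundle, assumptions.variant(fixed_mortality=True),
                           horizon_years)
    nomig = run_projection(bundle, assumptions.variant(no_migration=True),
                           horizon_years)

    g_main = main.growth_aged_at_least(age_threshold)
    g_fixed = fixed.growth_aged_at_least(age_threshold)
    g_nomig = nomig.growth_aged_at_least(age_threshold)

    contrib_le = g_main - g_fixed
    contrib_mig = g_main - g_nomig
    cohort = g_main - contrib_le - contrib_mig

    interaction = None
    if interaction_diagnostic:
        both = run_projection(
            bundle, assumptions.variant(fixed_mortality=True, no_migration=True),
            horizon_years)
        g_both = both.growth_aged_at_least(age_threshold)
        # joint effect minus the sum of single effects
        interaction = (g_main - g_both) - (contrib_le + contrib_mig)

    start_year = bundle.jump_off.reference_year
    return DecompositionResult(
        birthplaces=bundle.jump_off.birthplaces,
        total_growth=g_main,
        contrib_life_expectancy=contrib_le,
        contrib_migration=contrib_mig,
        contrib_cohort_flow=cohort,
        age_threshold=age_threshold,
        horizon=(start_year, start_year + horizon_years),
        interaction=interaction,
        main_output=main if keep_output else None)


def contribution_shares(contribs, total: float | None = None,
                        ndigits: int | None = 0):
    """Driver contributions as percentages of total growth.

    ``contribs`` may be a :class:`DecompositionResult` (national aggregate)
    or a (life expectancy, migration, cohort flow) triple with ``total``.
    Rounded half-away-from-zero to ``ndigits`` (None for unrounded).
    """
    if isinstance(contribs, DecompositionResult):
        nat = contribs.national()
        total = nat["total_growth"]
        values = (nat["contrib_life_expectancy"], nat["contrib_migration"],
                  nat["contrib_cohort_flow"])
    else:
        values = tuple(float(v) for v in contribs)
        if total is None:
            raise ValidationError("total is required for a raw contribution triple")
    if total == 0:
        raise ValidationError("shares undefined: total growth is zero")
    shares = tuple(100.0 * v / total for v in values)
    if ndigits is None:
        return shares
    return tuple(_round_half_away(s, ndigits) for s in shares)


def _round_half_away(x: float, ndigits: int) -> float:
    scale = 10.0 ** ndigits
    y = np.floor(abs(x) * scale + 0.5) / scale * np.sign(x)
    return float(int(y)) if ndigits <= 0 else float(y)
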
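"""Iterative proportional fitting (IPF) and age disaggregation.

IPF rescales a non-negative seed table so that selected marginal totals
match targets, while preserving the seed's interaction structure (for
two-way problems, all cross-product/odds ratios).  It is used here to split
grouped-age population tables to single years of age against a detailed
seed, mirroring the constraint of census age detail to published
grouped-age population estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError
from .grids import SEXES, PopulationGrid

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


@dataclass
class MarginalSpec:
    """Target totals along one axis (or tuple of axes) of the seed table."""

    axes: int | tuple[int, ...]
    totals: np.ndarray

    def __post_init__(self) -> None:
        if isinstance(self.axes, int):
            self.axes = (self.axes,)
        self.axes = tuple(self.axes)
        self.totals = np.asarray(self.totals, dtype=float)
        if np.any(self.totals < 0) or not np.all(np.isfinite(self.totals)):
            raise ValidationError("marginal targets must be finite and >= 0")


def _sum_to_margin(table: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    other = tuple(ax for ax in range(table.ndim) if ax not in axes)
    return table.sum(axis=other)


def ipf_fit(seed: np.ndarray, marginals: list[MarginalSpec],
            tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER) -> np.ndarray:
    """Fit a seed table to marginal targets by classical IPF.

    Marginals are swept in listed order; convergence is the maximum relative
    discrepancy between fitted and target marginals.  Structural zeros in
    the seed are never revived, and a positive target with an all-zero seed
    slice raises :class:`ConvergenceError` before iterating.
    """
    table = np.asarray(seed, dtype=float).copy()
    if np.any(table < 0) or not np.all(np.isfinite(table)):
        raise ValidationError("seed table must be finite and non-negative")
    if not marginals:
        raise ValidationError("at least one marginal spec is required")

    grand = marginals[0].totals.sum()
    for k, spec in enumerate(marginals):
        expected = tuple(table.shape[ax] for ax in spec.axes)
        if spec.totals.shape != expected:
            raise ValidationError(
                f"marginal {k}: totals shape {spec.totals.shape} does not "
                f"match axes {spec.axes} of the seed {expected}")
        if grand > 0 and abs(spec.totals.sum() - grand) > 1e-8 * grand:
            raise ValidationError(
                f"marginal {k}: grand total {spec.totals.sum():g} disagrees "
                f"with marginal 0 ({grand:g})")
        current = _sum_to_margin(table, spec.axes)
        bad = (spec.totals > 0) & (current == 0)
        if np.any(bad):
            raise ConvergenceError(
                f"marginal {k} (axes {spec.axes}): positive target with "
                f"all-zero seed cells at categories {np.argwhere(bad).tolist()}")

    def max_discrepancy() -> float:
        worst = 0.0
        for spec in marginals:
            current = _sum_to_margin(table, spec.axes)
            denom = np.where(spec.totals > 0, spec.totals, 1.0)
            worst = max(worst, float(np.max(np.abs(current - spec.totals) / denom)))
        return worst

    for _ in range(max_iter):
        for spec in marginals:
            current = _sum_to_margin(table, spec.axes)
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(current > 0, spec.totals / np.where(current > 0, current, 1.0), 1.0)
            # broadcast the factor over the summed-out axes
            shape = [1] * table.ndim
            for ax, size in zip(spec.axes, factor.shape):
                shape[ax] = size
            table *= factor.reshape(shape)
        if max_discrepancy() < tol:
            return table

    raise ConvergenceError(
        f"IPF did not converge in {max_iter} iterations; final max relative "
        f"marginal discrepancy {max_discrepancy():.3e}")


# -- age disaggregation ------------------------------------------------------

def parse_group_label(label: str) -> tuple[int, int | None]:
    """"a0-a1" -> (a0, a1); "100+" -> (100, None)."""
    text = str(label).strip()
    if text.endswith("+"):
        return int(text[:-1]), None
    lo, hi = text.replace("–", "-").split("-")
    return int(lo), int(hi)


def group_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


def _fit_one_series(seed_vec: np.ndarray, group_of_age: np.ndarray,
                    targets: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Fit one age vector to group totals through ipf_fit by scattering ages
    into a (group, offset) table, which makes the group totals a plain axis
    marginal.  Padding cells are structural zeros."""
    n_groups = targets.size
    width = int(np.max(np.bincount(group_of_age)))
    matrix = np.zeros((n_groups, width))
    offsets = np.zeros_like(group_of_age)
    counter: dict[int, int] = {}
    for a, g in enumerate(group_of_age):
        offsets[a] = counter.get(g, 0)
        counter[g] = offsets[a] + 1
        matrix[g, offsets[a]] = seed_vec[a]
    fitted = ipf_fit(matrix, [MarginalSpec(0, targets)], tol, max_iter)
    return fitted[group_of_age, offsets]


def disaggregate_ages(grouped: pd.DataFrame, seed_single: pd.DataFrame,
                      reference_year: int, tol: float = DEFAULT_TOL,
                      max_iter: int = DEFAULT_MAX_ITER) -> PopulationGrid:
    """Split a grouped-age population table to single years of age.

    Parameters
    ----------
    grouped
        Columns birthplace, sex, age_group ("a0-a1" / "top+"), count.
    seed_single
        Columns birthplace, sex, age, count: the detailed single-year seed
        whose within-group pattern is preserved.
    """
    birthplaces = tuple(pd.unique(seed_single["birthplace"]))
    seed_grid = PopulationGrid.from_frame(seed_single, reference_year, birthplaces)
    n_ages = seed_grid.n_ages

    group_keys = list(pd.unique(grouped["age_group"]))
    bounds = [parse_group_label(k) for k in group_keys]
    group_of_age = np.full(n_ages, -1, dtype=int)
    for g, (lo, hi) in enumerate(bounds):
        hi_incl = n_ages - 1 if hi is None else hi
        group_of_age[lo:hi_incl + 1] = g
    if np.any(group_of_age < 0):
        raise ValidationError("age groups do not cover the seed's age range")

    pivot = grouped.pivot_table(index=["birthplace", "sex"], columns="age_group",
                                values="count", aggfunc="sum")
    counts = np.zeros_like(seed_grid.counts)
    for i, bp in enumerate(birthplaces):
        for s, sex in enumerate(SEXES):
            try:
                targets = pivot.loc[(bp, sex), group_keys].to_numpy(dtype=float)
            except KeyError:
                raise ValidationError(
                    f"grouped table missing birthplace '{bp}' sex '{sex}'")
            seed_vec = seed_grid.counts[i, s]
            if np.any((targets > 0) & (np.bincount(group_of_age, seed_vec,
                                                   minlength=targets.size) == 0)):
                raise ConvergenceError(
                    f"empty seed group with positive target for ('{bp}', '{sex}')")
            counts[i, s] = _fit_one_series(seed_vec, group_of_age, targets,
                                           tol, max_iter)
    return PopulationGrid(counts, reference_year, birthplaces)
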
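"""Aggregation to birthplace categories and report-table arithmetic.

Conventions follow standard demographic reporting: population counts
rounded to the nearest 100 (ties away from zero), percentage change to
whole percent, composition shares to one decimal, sex ratios expressed as
males per 100 females.  Percentages are computed before any rounding of
the underlying counts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import DecompositionResult, _round_half_away
from .errors import ValidationError
from .grids import SEXES, BirthplaceClassification, PopulationGrid
from .projection import ProjectionOutput


def aggregate(pop: PopulationGrid, classification: BirthplaceClassification,
              scheme: str = "broad") -> pd.DataFrame:
    """Sum a population grid into classification categories.

    Returns a long table (category, sex, age, count); the grand total is
    invariant under aggregation.  An unmapped birthplace raises a
    classification error naming it.
    """
    frames = {}
    for i, bp in enumerate(pop.birthplaces):
        cat = classification.category_of(bp, scheme)
        frames.setdefault(cat, np.zeros_like(pop.counts[0]))
        frames[cat] += pop.counts[i]
    from .grids import age_labels
    labels = age_labels(pop.n_ages)
    rows = []
    for cat in sorted(frames):
        for s, sex in enumerate(SEXES):
            for a, lab in enumerate(labels):
                rows.append((cat, sex, lab, frames[cat][s, a]))
    return pd.DataFrame(rows, columns=["category", "sex", "age", "count"])


def pct_change(v0: float, v1: float, round_to: int | None = 0) -> float:
    """100 * (v1 - v0) / v0, rounded half away from zero."""
    if v0 <= 0:
        raise ValidationError("percentage change undefined for base <= 0")
    value = 100.0 * (v1 - v0) / v0
    return value if round_to is None else _round_half_away(value, round_to)


def composition_share(part: float, whole: float, round_to: int | None = 1) -> float:
    """100 * part / whole, with 0 <= part <= whole."""
    if whole <= 0:
        raise ValidationError("composition share undefined for whole <= 0")
    if not 0 <= part <= whole:
        raise ValidationError("part must lie within [0, whole]")
    value = 100.0 * part / whole
    return value if round_to is None else _round_half_away(value, round_to)


def sex_ratio(males: float, females: float) -> float:
    """Males per 100 females."""
    if females <= 0:
        raise ValidationError("sex ratio undefined for zero females")
    return 100.0 * males / females


def round_to_nearest(value, base: float = 100.0):
    """Round to the nearest multiple of base, ties away from zero."""
    if base <= 0:
        raise ValidationError("rounding base must be positive")
    value = np.asarray(value, dtype=float)
    out = np.sign(value) * np.floor(np.abs(value) / base + 0.5) * base
    return float(out) if out.ndim == 0 else out


# -- report tables -----------------------------------------------------------

def _aged_totals_by_category(pop: PopulationGrid,
                             classification: BirthplaceClassification,
                             scheme: str, threshold: int) -> pd.Series:
    agg = aggregate(pop, classification, scheme)
    from .grids import parse_age_label
    agg["age_idx"] = agg["age"].map(parse_age_label)
    old = agg[agg["age_idx"] >= threshold]
    return old.groupby("category")["count"].sum()


def growth_table(output: ProjectionOutput,
                 classification: BirthplaceClassification,
                 scheme: str = "main", threshold: int = 65,
                 mid_index: int | None = None) -> pd.DataFrame:
    """Population aged >= threshold by category at jump-off, mid-horizon and
    horizon end, with percentage-change columns; counts rounded to the
    nearest 100 after the percentages are taken."""
    n = len(output.grids) - 1
    mid_index = n // 2 if mid_index is None else mid_index
    points = {output.grids[k].reference_year:
              _aged_totals_by_category(output.grids[k], classification,
                                       scheme, threshold)
              for k in (0, mid_index, n)}
    years = sorted(points)
    table = pd.DataFrame(points).fillna(0.0)
    table[f"pct_change_{years[0]}_{years[1]}"] = [
        pct_change(a, b) if a > 0 else np.nan
        for a, b in zip(table[years[0]], table[years[1]])]
    table[f"pct_change_{years[1]}_{years[2]}"] = [
        pct_change(a, b) if a > 0 else np.nan
        for a, b in zip(table[years[1]], table[years[2]])]
    for y in years:
        table[y] = round_to_nearest(table[y].to_numpy(), 100.0)
    table.index.name = "category"
    return table.reset_index()


def drivers_table(result: DecompositionResult,
                  classification: BirthplaceClassification | None = None,
                  scheme: str = "main") -> pd.DataFrame:
    """Growth-driver contributions per category plus overseas-born and
    all-birthplace totals, rounded to the nearest 100."""
    df = result.to_frame()
    if classification is not None:
        df["category"] = [classification.category_of(bp, scheme)
                          for bp in df["birthplace"]]
        df = df.groupby("category", as_index=False).sum(numeric_only=True)
    else:
        df = df.rename(columns={"birthplace": "category"})
    overseas = df.iloc[1:].sum(numeric_only=True) if classification is None else None
    value_cols = ["contrib_life_expectancy", "contrib_migration",
                  "contrib_cohort_flow", "total"]
    total_row = {"category": "Total", **{c: df[c].sum() for c in value_cols}}
    rows = [df]
    if overseas is not None:
        rows.append(pd.DataFrame([{"category": "Overseas born",
                                   **{c: overseas[c] for c in value_cols}}]))
    rows.append(pd.DataFrame([total_row]))
    out = pd.concat(rows, ignore_index=True)
    for c in value_cols:
        out[c] = round_to_nearest(out[c].to_numpy(), 100.0)
    return out


def composition_by_year(output: ProjectionOutput,
                        classification: BirthplaceClassification,
                        scheme: str = "broad", threshold: int = 65) -> pd.DataFrame:
    """Share of the >= threshold population per category, by year
    (percentages computed before rounding, one decimal)."""
    rows = []
    for grid in output.grids:
        totals = _aged_totals_by_category(grid, classification, scheme, threshold)
        whole = totals.sum()
        for cat, part in totals.items():
            rows.append((grid.reference_year, cat,
                         composition_share(part, whole, 1)))
    return pd.DataFrame(rows, columns=["year", "category", "share_pct"])


def write_report(output: ProjectionOutput,
                 classification: BirthplaceClassification, out_dir: str | Path,
                 result: DecompositionResult | None = None,
                 threshold: int = 65) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    growth_table(output, classification, "main", threshold).to_csv(
        out_dir / "table2_style.csv", index=False)
    composition_by_year(output, classification, "broad", threshold).to_csv(
        out_dir / "composition_by_year.csv", index=False)
    if result is not None:
        drivers_table(result).to_csv(out_dir / "table3_style.csv", index=False)


def plot_composition(output: ProjectionOutput,
                     classification: BirthplaceClassification,
                     path: str | Path, threshold: int = 65) -> None:
    """Stacked area chart of the >= threshold population by broad category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    years = [g.reference_year for g in output.grids]
    series = {}
    for g in output.grids:
        totals = _aged_totals_by_category(g, classification, "broad", threshold)
        for cat, v in totals.items():
            series.setdefault(cat, []).append(v)
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.stackplot(years, series.values(), labels=series.keys())
    ax.set_xlabel("year")
    ax.set_ylabel(f"population aged {threshold}+")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
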
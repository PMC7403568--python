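"""Period life tables and life-expectancy-targeted mortality scaling.

A life table converts a schedule of age-specific death rates ``mx`` (deaths
per person-year, single-year intervals with an open-ended top interval) into
the standard columns:

    qx = mx / (1 + (1 - ax) * mx)        probability of dying in [x, x+1)
    l(x+1) = lx * (1 - qx)               survivors from radix l0 = 1
    Lx = l(x+1) + ax * dx                person-years lived in [x, x+1)
    L(top) = l(top) / m(top)             open interval person-years
    Tx = sum of Lx at ages >= x,  ex = Tx / lx

``ax`` is the average time lived within the interval by those who die in it.
Mortality assumptions are expressed as target life expectancies at birth
(e0): :func:`scale_rates_to_e0` finds the uniform proportional scaling of a
rate schedule that hits a target e0, and :func:`make_e0_trajectory` builds
national-trend-plus-fixed-differential e0 paths by birthplace and sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BracketingError, ValidationError

#: Default time-lived-by-the-dying conventions: infant deaths cluster early
#: in the first year of life, deaths elsewhere are spread evenly.
A0_DEFAULT = 0.1
AX_DEFAULT = 0.5

_LOG_FACTOR_MIN = np.log(1e-6)
_LOG_FACTOR_MAX = np.log(1e6)


@dataclass
class LifeTable:
    """Complete single-year period life table with an open top interval."""

    ages: np.ndarray
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    @property
    def e0(self) -> float:
        return float(self.ex[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages, "mx": self.mx, "ax": self.ax, "qx": self.qx,
            "lx": self.lx, "Lx": self.Lx, "Tx": self.Tx, "ex": self.ex,
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _resolve_ax(n: int, ax_convention) -> np.ndarray:
    """Accept a scalar, an array, or the "standard" convention (a0 = 0.1,
    0.5 elsewhere).  The top (open) entry is never used."""
    if isinstance(ax_convention, str):
        if ax_convention != "standard":
            raise ValidationError(f"unknown ax convention '{ax_convention}'")
        ax = np.full(n, AX_DEFAULT)
        ax[0] = A0_DEFAULT
        return ax
    ax = np.broadcast_to(np.asarray(ax_convention, dtype=float), (n,)).copy()
    if np.any((ax < 0) | (ax > 1)):
        raise ValidationError("ax values must lie in [0, 1]")
    return ax


def build_life_table(mx, ax_convention="standard") -> LifeTable:
    """Build a period life table from single-year death rates.

    Parameters
    ----------
    mx
        Death rates for ages 0..top; the last entry is the open interval and
        must be strictly positive.
    ax_convention
        "standard" (a0 = 0.1, 0.5 elsewhere), a scalar, or an array.
    """
    mx = np.asarray(mx, dtype=float)
    if mx.ndim != 1 or mx.size < 1:
        raise ValidationError("mx must be a 1-D schedule with at least one age")
    if np.any(mx < 0) or not np.all(np.isfinite(mx)):
        raise ValidationError("death rates must be finite and non-negative")
    if mx[-1] <= 0:
        raise ValidationError("open-interval death rate must be positive")

    n = mx.size
    ax = _resolve_ax(n, ax_convention)

    qx = np.empty(n)
    qx[:-1] = mx[:-1] / (1.0 + (1.0 - ax[:-1]) * mx[:-1])
    qx[-1] = 1.0

    lx = np.empty(n)
    lx[0] = 1.0
    if n > 1:
        np.cumprod(1.0 - qx[:-1], out=lx[1:])
    dx = lx * qx

    Lx = np.empty(n)
    if n > 1:
        Lx[:-1] = lx[1:] + ax[:-1] * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1]

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)

    return LifeTable(np.arange(n), mx, ax, qx, lx, Lx, Tx, ex)


def life_expectancy(mx, ax_convention="standard") -> float:
    """e0 of a rate schedule; shorthand for build_life_table(...).e0."""
    return build_life_table(mx, ax_convention).e0


def find_e0_scale_factor(mx, target_e0: float, tol: float = 1e-6,
                         max_iter: int = 200,
                         ax_convention="standard") -> float:
    """Uniform proportional factor f such that e0(f * mx) = target_e0.

    Solved by bisection on log(f) over f in [1e-6, 1e6]; e0 is strictly
    decreasing in f, so the bracket is checked up front and a target outside
    the achievable range raises :class:`BracketingError` reporting the
    achievable bounds.
    """
    mx = np.asarray(mx, dtype=float)
    e0_current = life_expectancy(mx, ax_convention)
    if abs(e0_current - target_e0) < tol:
        return 1.0

    lo, hi = _LOG_FACTOR_MIN, _LOG_FACTOR_MAX
    e0_hi = life_expectancy(np.exp(lo) * mx, ax_convention)   # low rates
    e0_lo = life_expectancy(np.exp(hi) * mx, ax_convention)   # high rates
    if not (e0_lo <= target_e0 <= e0_hi):
        raise BracketingError(
            f"target e0 {target_e0:.3f} outside achievable range "
            f"[{e0_lo:.3f}, {e0_hi:.3f}] for proportional scaling"
        )

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        e0_mid = life_expectancy(np.exp(mid) * mx, ax_convention)
        if abs(e0_mid - target_e0) < tol:
            return float(np.exp(mid))
        if e0_mid > target_e0:   # mortality too low -> raise rates
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


def scale_rates_to_e0(mx, target_e0: float, tol: float = 1e-6,
                      max_iter: int = 200, ax_convention="standard") -> np.ndarray:
    """Return the schedule factor * mx whose life table hits target_e0."""
    factor = find_e0_scale_factor(mx, target_e0, tol, max_iter, ax_convention)
    return factor * np.asarray(mx, dtype=float)


@dataclass
class E0Trajectory:
    """Life expectancy at birth by birthplace, sex and calendar year.

    With the default settings every birthplace-sex series keeps a fixed
    additive differential from the shared national trend.
    """

    years: np.ndarray                 # (T,)
    e0: np.ndarray                    # (n_bp, 2, T)
    birthplaces: tuple[str, ...]

    def at(self, year: int) -> np.ndarray:
        """(n_bp, 2) targets for one calendar year."""
        idx = int(np.searchsorted(self.years, year))
        if idx >= self.years.size or self.years[idx] != year:
            raise ValidationError(f"year {year} not covered by trajectory")
        return self.e0[:, :, idx]

    def to_frame(self) -> pd.DataFrame:
        from .grids import SEXES
        rows = []
        for i, bp in enumerate(self.birthplaces):
            for s, sex in enumerate(SEXES):
                for t, year in enumerate(self.years):
                    rows.append((int(year), bp, sex, self.e0[i, s, t]))
        return pd.DataFrame(rows, columns=["year", "birthplace", "sex", "e0"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def cumulative_e0_gain(annual_gain: float, t: float | np.ndarray,
                       damping: float = 1.0):
    """National e0 gain accumulated over t years.

    ``damping`` = 1 gives the linear trend gain * t; damping < 1 gives the
    damped-linear trend gain * (1 - damping**t) / (1 - damping), in which the
    annual increment shrinks geometrically.
    """
    if not 0.0 < damping <= 1.0:
        raise ValidationError("damping must lie in (0, 1]")
    t = np.asarray(t, dtype=float)
    if damping == 1.0:
        out = annual_gain * t
    else:
        out = annual_gain * (1.0 - damping ** t) / (1.0 - damping)
    return float(out) if out.ndim == 0 else out


def make_e0_trajectory(national_e0_start: float, annual_gain: float,
                       horizon_years: int, differentials: np.ndarray,
                       birthplaces: tuple[str, ...] | None = None,
                       start_year: int = 0, damping: float = 1.0,
                       sex_convergence_fraction: float = 1.0) -> E0Trajectory:
    """Build e0 targets: national trend plus fixed birthplace-sex offsets.

    e0[i, s, t] = national(t) + differentials[i, s], with national(t) the
    (optionally damped) linear trend from ``national_e0_start``.

    ``sex_convergence_fraction`` < 1 shrinks each birthplace's female-male
    e0 gap linearly so that by the horizon end it is that fraction of its
    starting size, emulating assumed convergence of male and female
    mortality; the birthplace-level mean differential stays fixed.
    """
    differentials = np.asarray(differentials, dtype=float)
    if differentials.ndim != 2 or differentials.shape[1] != 2:
        raise ValidationError("differentials must have shape (n_birthplaces, 2)")
    if not 0.0 <= sex_convergence_fraction <= 1.0:
        raise ValidationError("sex_convergence_fraction must lie in [0, 1]")
    n_bp = differentials.shape[0]
    if birthplaces is None:
        birthplaces = tuple(f"birthplace_{i}" for i in range(n_bp))

    t = np.arange(horizon_years + 1, dtype=float)
    national = national_e0_start + cumulative_e0_gain(annual_gain, t, damping)

    mean_diff = differentials.mean(axis=1, keepdims=True)        # (n_bp, 1)
    sex_gap = differentials - mean_diff                          # (n_bp, 2)
    if horizon_years > 0:
        shrink = 1.0 - (1.0 - sex_convergence_fraction) * t / horizon_years
    else:
        shrink = np.ones_like(t)

    e0 = (national[None, None, :] + mean_diff[:, :, None]
          + sex_gap[:, :, None] * shrink[None, None, :])
    if np.any(e0 <= 0):
        raise ValidationError("trajectory produces non-positive e0 values")
    return E0Trajectory(start_year + t.astype(int), e0, tuple(birthplaces))
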
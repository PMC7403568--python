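"""Core data containers for multi-birthplace cohort-component projections.

All demographic arrays share one layout: axis 0 is birthplace (index 0 is
always the native-born population), axis 1 is sex (0 = female, 1 = male),
axis 2 is single year of age from 0 up to an open-ended top interval
(e.g. ages 0..99 closed plus "100+").  Rates and flows indexed by age refer
to the period-cohort ageing from a to a+1 during the year; the top index is
the open interval treated as its own period-cohort, and the cohort running
from birth to age 0 is carried in separate ``*_birth`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ClassificationError, ValidationError

SEXES = ("female", "male")
FEMALE, MALE = 0, 1

BIRTH_LABEL = "birth"


def age_labels(n_ages: int) -> list[str]:
    """Labels "0".."top-1" plus an open "top+" row."""
    return [str(a) for a in range(n_ages - 1)] + [f"{n_ages - 1}+"]


def parse_age_label(label: str) -> int:
    """Map an age label back to its index; "100+" -> 100, "birth" is rejected."""
    text = str(label).strip()
    if text.endswith("+"):
        return int(text[:-1])
    return int(text)


def _check_nonneg_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ValidationError(f"{name} contains negative values")


@dataclass
class PopulationGrid:
    """Population counts by birthplace x sex x single year of age.

    ``reference_year`` is the mid-year point the counts refer to.
    """

    counts: np.ndarray
    reference_year: int
    birthplaces: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[1] != len(SEXES):
            raise ValidationError(
                "counts must have shape (n_birthplaces, 2, n_ages), got "
                f"{self.counts.shape}"
            )
        self.birthplaces = tuple(self.birthplaces)
        if len(self.birthplaces) != self.counts.shape[0]:
            raise ValidationError("birthplaces length does not match counts")
        _check_nonneg_finite("population counts", self.counts)

    @property
    def n_birthplaces(self) -> int:
        return self.counts.shape[0]

    @property
    def n_ages(self) -> int:
        return self.counts.shape[2]

    @property
    def top_age(self) -> int:
        return self.n_ages - 1

    def total(self) -> float:
        return float(self.counts.sum())

    def totals_by_birthplace_sex(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def aged_at_least(self, threshold: int) -> np.ndarray:
        """Counts aged >= threshold, per birthplace (summed over sexes)."""
        return self.counts[:, :, threshold:].sum(axis=(1, 2))

    def copy(self) -> "PopulationGrid":
        return replace(self, counts=self.counts.copy())

    # -- CSV round trip (columns: birthplace,sex,age,count) -----------------

    def to_frame(self) -> pd.DataFrame:
        labels = age_labels(self.n_ages)
        rows = []
        for i, bp in enumerate(self.birthplaces):
            for s, sex in enumerate(SEXES):
                for a, lab in enumerate(labels):
                    rows.append((bp, sex, lab, self.counts[i, s, a]))
        return pd.DataFrame(rows, columns=["birthplace", "sex", "age", "count"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_year: int,
                   birthplaces: tuple[str, ...] | None = None) -> "PopulationGrid":
        if birthplaces is None:
            birthplaces = tuple(pd.unique(df["birthplace"]))
        ages = sorted({parse_age_label(x) for x in df["age"]})
        n_ages = max(ages) + 1
        counts = np.zeros((len(birthplaces), len(SEXES), n_ages))
        bp_idx = {b: i for i, b in enumerate(birthplaces)}
        sex_idx = {s: i for i, s in enumerate(SEXES)}
        for _, row in df.iterrows():
            counts[bp_idx[row["birthplace"]], sex_idx[row["sex"]],
                   parse_age_label(row["age"])] += float(row["count"])
        return cls(counts, reference_year, birthplaces)

    @classmethod
    def read_csv(cls, path: str | Path, reference_year: int) -> "PopulationGrid":
        return cls.from_frame(pd.read_csv(path), reference_year)


@dataclass
class RateSchedules:
    """Occurrence-exposure rate schedules driving a projection.

    ``death`` and ``emigration`` are per-person-year rates by period-cohort;
    ``fertility`` is births per woman-year by mother's birthplace and age,
    zero outside the reproductive span.
    """

    death: np.ndarray                # (n_bp, 2, n_ages)
    emigration: np.ndarray           # (n_bp, 2, n_ages)
    fertility: np.ndarray            # (n_bp, n_ages)
    death_birth: np.ndarray          # (n_bp, 2) birth -> age-0 cohort
    emigration_birth: np.ndarray     # (n_bp, 2)

    def __post_init__(self) -> None:
        self.death = np.asarray(self.death, dtype=float)
        self.emigration = np.asarray(self.emigration, dtype=float)
        self.fertility = np.asarray(self.fertility, dtype=float)
        self.death_birth = np.asarray(self.death_birth, dtype=float)
        self.emigration_birth = np.asarray(self.emigration_birth, dtype=float)
        for name in ("death", "emigration", "fertility", "death_birth",
                     "emigration_birth"):
            _check_nonneg_finite(f"{name} rates", getattr(self, name))
        if self.death.shape != self.emigration.shape:
            raise ValidationError("death and emigration schedules misaligned")
        if self.fertility.shape != (self.death.shape[0], self.death.shape[2]):
            raise ValidationError("fertility schedule misaligned with death rates")

    @property
    def n_ages(self) -> int:
        return self.death.shape[2]

    def copy(self) -> "RateSchedules":
        return RateSchedules(self.death.copy(), self.emigration.copy(),
                             self.fertility.copy(), self.death_birth.copy(),
                             self.emigration_birth.copy())

    def with_scaled_mortality(self, factors: np.ndarray) -> "RateSchedules":
        """Multiply death rates by per-(birthplace, sex) factors."""
        factors = np.asarray(factors, dtype=float)
        return RateSchedules(self.death * factors[:, :, None], self.emigration,
                             self.fertility, self.death_birth * factors,
                             self.emigration_birth)

    def without_emigration(self) -> "RateSchedules":
        return RateSchedules(self.death, np.zeros_like(self.emigration),
                             self.fertility, self.death_birth,
                             np.zeros_like(self.emigration_birth))


@dataclass
class ImmigrationFlows:
    """Absolute immigration inflows (persons/year) by period-cohort, plus the
    national total trajectory the flows are constrained to."""

    flows: np.ndarray                    # (n_bp, 2, n_ages)
    flows_birth: np.ndarray              # (n_bp, 2) immigrant newborns
    national_total_by_year: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flows = np.asarray(self.flows, dtype=float)
        self.flows_birth = np.asarray(self.flows_birth, dtype=float)
        _check_nonneg_finite("immigration flows", self.flows)
        _check_nonneg_finite("immigrant newborn flows", self.flows_birth)
        for year, total in self.national_total_by_year.items():
            if total < 0:
                raise ValidationError(f"national total for {year} is negative")

    def total(self) -> float:
        return float(self.flows.sum() + self.flows_birth.sum())

    def scaled(self, factor: float | np.ndarray) -> "ImmigrationFlows":
        """Scale by a scalar or per-(birthplace, sex) factor array."""
        factor = np.asarray(factor, dtype=float)
        if factor.ndim == 0:
            return ImmigrationFlows(self.flows * factor, self.flows_birth * factor,
                                    dict(self.national_total_by_year))
        return ImmigrationFlows(self.flows * factor[:, :, None],
                                self.flows_birth * factor,
                                dict(self.national_total_by_year))

    def copy(self) -> "ImmigrationFlows":
        return self.scaled(1.0)


@dataclass
class ComponentFlows:
    """Component events of one projection year (persons, not rates)."""

    year: int                       # flows cover year -> year + 1
    births: np.ndarray              # (n_bp, 2); nonzero only for birthplace 0
    deaths: np.ndarray              # (n_bp, 2, n_ages) by period-cohort
    immigration: np.ndarray
    emigration: np.ndarray
    deaths_birth: np.ndarray        # (n_bp, 2) birth -> age-0 cohort
    immigration_birth: np.ndarray
    emigration_birth: np.ndarray

    def totals_by_birthplace(self) -> pd.DataFrame:
        def tot(cohorts, birth):
            return cohorts.sum(axis=(1, 2)) + birth.sum(axis=1)
        return pd.DataFrame({
            "births": self.births.sum(axis=1),
            "deaths": tot(self.deaths, self.deaths_birth),
            "immigration": tot(self.immigration, self.immigration_birth),
            "emigration": tot(self.emigration, self.emigration_birth),
        })


@dataclass
class BirthplaceClassification:
    """Mapping from fine birthplace units to broad and main category schemes."""

    broad: dict[str, str]
    main: dict[str, str]

    def category_of(self, unit: str, scheme: str) -> str:
        mapping = self._scheme(scheme)
        if unit not in mapping:
            raise ClassificationError(f"birthplace '{unit}' has no {scheme} category")
        return mapping[unit]

    def _scheme(self, scheme: str) -> dict[str, str]:
        if scheme == "broad":
            return self.broad
        if scheme == "main":
            return self.main
        raise ValidationError(f"unknown classification scheme '{scheme}'")

    def to_frame(self) -> pd.DataFrame:
        units = sorted(set(self.broad) | set(self.main))
        return pd.DataFrame({
            "birthplace": units,
            "broad_category": [self.broad.get(u, "") for u in units],
            "main_category": [self.main.get(u, "") for u in units],
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "BirthplaceClassification":
        df = pd.read_csv(path)
        return cls(dict(zip(df["birthplace"], df["broad_category"])),
                   dict(zip(df["birthplace"], df["main_category"])))


# -- rate / flow CSV helpers -------------------------------------------------

def rates_to_frame(values: np.ndarray, birth_values: np.ndarray | None,
                   birthplaces: tuple[str, ...], value_name: str) -> pd.DataFrame:
    """Long-format (birthplace, sex, age, value) table; birth-cohort rows are
    labelled "birth"."""
    n_ages = values.shape[-1]
    labels = age_labels(n_ages)
    rows = []
    for i, bp in enumerate(birthplaces):
        if values.ndim == 3:
            for s, sex in enumerate(SEXES):
                if birth_values is not None:
                    rows.append((bp, sex, BIRTH_LABEL, birth_values[i, s]))
                for a, lab in enumerate(labels):
                    rows.append((bp, sex, lab, values[i, s, a]))
        else:  # fertility: no sex axis
            for a, lab in enumerate(labels):
                rows.append((bp, "female", lab, values[i, a]))
    return pd.DataFrame(rows, columns=["birthplace", "sex", "age", value_name])


def frame_to_rates(df: pd.DataFrame, birthplaces: tuple[str, ...], n_ages: int,
                   value_name: str, with_sex: bool = True):
    """Inverse of :func:`rates_to_frame`; returns (values, birth_values)."""
    bp_idx = {b: i for i, b in enumerate(birthplaces)}
    sex_idx = {s: i for i, s in enumerate(SEXES)}
    if with_sex:
        values = np.zeros((len(birthplaces), len(SEXES), n_ages))
        birth = np.zeros((len(birthplaces), len(SEXES)))
    else:
        values = np.zeros((len(birthplaces), n_ages))
        birth = None
    for _, row in df.iterrows():
        i = bp_idx[row["birthplace"]]
        v = float(row[value_name])
        if str(row["age"]).strip() == BIRTH_LABEL:
            if birth is not None:
                birth[i, sex_idx[row["sex"]]] = v
            continue
        a = parse_age_label(row["age"])
        if with_sex:
            values[i, sex_idx[row["sex"]], a] = v
        else:
            values[i, a] = v
    return values, birth
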
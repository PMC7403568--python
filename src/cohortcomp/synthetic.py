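"""Synthetic projection scenarios with migration-wave cohort structure.

Real birthplace-specific projection inputs (jump-off populations, rate
schedules and migration flows) are built from official population estimates
that cannot be redistributed, so this module generates complete scenarios
whose statistical shape matches them: overseas-born stocks accumulated from
historical arrival waves and depleted by Gompertz survival (long-ceased
waves old-skewed, recent waves young-adult-skewed), a native-born stock
from a stationary-population approximation of its birth history,
young-adult-peaked migration age profiles, and below-replacement fertility.

Every quantity is derived deterministically from the scenario seed, so a
bundle regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .grids import (FEMALE, MALE, SEXES, BirthplaceClassification,
                    ImmigrationFlows, PopulationGrid, RateSchedules,
                    frame_to_rates, rates_to_frame)
from .lifetables import life_expectancy, scale_rates_to_e0

#: Assumed female-minus-male gap in life expectancy at birth (years),
#: split symmetrically around each birthplace's overall e0.
SEX_E0_GAP = 4.0

#: Residual inflow for a wave that has ceased, as a fraction of its peak
#: annual arrivals (family reunion / trickle migration).
CEASED_WAVE_RESIDUAL = 0.05

#: Native-born immigration (returning expatriates) as a fraction of the
#: annual birth scale.
NATIVE_RETURN_FRACTION = 0.08

#: Immigrant newborns (babies arriving in their year of birth) as a
#: fraction of a birthplace's annual inflow.
NEWBORN_INFLOW_FRACTION = 0.005

_BROAD_REGIONS = ("Europe", "Asia", "Africa", "Americas", "Oceania")


@dataclass
class WaveProfile:
    """One birthplace's migration wave and demographic regime.

    For birthplace 0 (the native-born) ``annual_arrival_scale`` is the
    annual number of births over its history and the wave years are ignored.
    """

    wave_start_year: int
    wave_end_year: int
    annual_arrival_scale: float          # persons/year at the wave's plateau
    gompertz_alpha: float = 8e-5         # baseline hazard /year
    gompertz_beta: float = 0.085         # hazard slope /year of age
    e0_differential: float = 0.0         # years relative to national e0
    emigration_scale: float = 1.0        # multiplier on the base schedule
    fertility_tfr: float = 1.8           # children per woman


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic projection scenario."""

    n_birthplaces: int
    birthplace_profiles: list[WaveProfile]
    jump_off_year: int = 2016
    top_age: int = 100
    seed: int = 0
    national_immigration_start: float = 200_000.0   # persons/year
    national_immigration_growth: float = 2_500.0    # persons/year^2
    arrival_age_dist: str = "gamma"                 # or "triangular"

    def __post_init__(self) -> None:
        if self.n_birthplaces < 2:
            raise ConfigurationError("n_birthplaces must be >= 2 (index 0 is native-born)")
        if len(self.birthplace_profiles) != self.n_birthplaces:
            raise ConfigurationError("birthplace_profiles length must equal n_birthplaces")
        if self.top_age < 65:
            raise ConfigurationError("top_age must be >= 65")
        if self.national_immigration_start < 0:
            raise ConfigurationError("national_immigration_start must be >= 0")
        if self.arrival_age_dist not in ("gamma", "triangular"):
            raise ConfigurationError("arrival_age_dist must be 'gamma' or 'triangular'")
        for j, p in enumerate(self.birthplace_profiles):
            if p.annual_arrival_scale < 0:
                raise ConfigurationError(f"annual_arrival_scale must be >= 0 (birthplace {j})")
            if p.gompertz_alpha <= 0 or p.gompertz_beta < 0:
                raise ConfigurationError(f"gompertz_alpha/gompertz_beta invalid (birthplace {j})")
            if p.emigration_scale < 0:
                raise ConfigurationError(f"emigration_scale must be >= 0 (birthplace {j})")
            if p.fertility_tfr < 0:
                raise ConfigurationError(f"fertility_tfr must be >= 0 (birthplace {j})")
            if j > 0 and not (p.wave_start_year < p.wave_end_year <= self.jump_off_year):
                raise ConfigurationError(
                    f"wave years must satisfy start < end <= jump_off (birthplace {j})")

    def birthplace_names(self) -> tuple[str, ...]:
        return ("AUS",) + tuple(f"OB{j:02d}" for j in range(1, self.n_birthplaces))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["birthplace_profiles"] = [WaveProfile(**p) for p in raw["birthplace_profiles"]]
        return cls(**raw)


@dataclass
class ScenarioBundle:
    """Jump-off population plus every assumption schedule of one scenario."""

    jump_off: PopulationGrid
    rates: RateSchedules
    immigration: ImmigrationFlows
    classification: BirthplaceClassification
    config_echo: ScenarioConfig

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        bps = self.jump_off.birthplaces
        self.jump_off.write_csv(path / "population.csv")
        rates_to_frame(self.rates.death, self.rates.death_birth, bps,
                       "rate").to_csv(path / "death_rates.csv", index=False)
        rates_to_frame(self.rates.emigration, self.rates.emigration_birth, bps,
                       "rate").to_csv(path / "emigration_rates.csv", index=False)
        fert = rates_to_frame(self.rates.fertility, None, bps, "rate")
        fert.drop(columns=["sex"]).to_csv(path / "fertility_rates.csv", index=False)
        imm = rates_to_frame(self.immigration.flows, self.immigration.flows_birth,
                             bps, "count")
        imm.to_csv(path / "immigration.csv", index=False)
        self.classification.write_csv(path / "classification.csv")
        self.config_echo.to_yaml(path / "config.yaml")

    @classmethod
    def read_dir(cls, path: str | Path) -> "ScenarioBundle":
        import pandas as pd
        path = Path(path)
        config = ScenarioConfig.from_yaml(path / "config.yaml")
        bps = config.birthplace_names()
        n_ages = config.top_age + 1
        jump_off = PopulationGrid.read_csv(path / "population.csv",
                                           config.jump_off_year)
        death, death_birth = frame_to_rates(
            pd.read_csv(path / "death_rates.csv"), bps, n_ages, "rate")
        emig, emig_birth = frame_to_rates(
            pd.read_csv(path / "emigration_rates.csv"), bps, n_ages, "rate")
        fert_df = pd.read_csv(path / "fertility_rates.csv")
        fert_df["sex"] = "female"
        fert, _ = frame_to_rates(fert_df, bps, n_ages, "rate", with_sex=False)
        flows, flows_birth = frame_to_rates(
            pd.read_csv(path / "immigration.csv"), bps, n_ages, "count")
        totals = national_totals(config)
        return cls(jump_off,
                   RateSchedules(death, emig, fert, death_birth, emig_birth),
                   ImmigrationFlows(flows, flows_birth, totals),
                   BirthplaceClassification.read_csv(path / "classification.csv"),
                   config)


# -- building blocks ---------------------------------------------------------

def gompertz_hazard(alpha: float, beta: float, age) -> np.ndarray:
    return alpha * np.exp(beta * np.asarray(age, dtype=float))


def gompertz_survival(alpha: float, beta: float, a_from, a_to) -> np.ndarray:
    """P(survive from exact age a_from to a_to) under a Gompertz hazard."""
    a_from = np.asarray(a_from, dtype=float)
    a_to = np.asarray(a_to, dtype=float)
    if beta == 0:
        return np.exp(-alpha * (a_to - a_from))
    return np.exp(-(alpha / beta) * (np.exp(beta * a_to) - np.exp(beta * a_from)))


def gompertz_mortality_schedule(alpha: float, beta: float, top_age: int) -> np.ndarray:
    """Single-year mx schedule, hazard evaluated at interval midpoints.

    The open interval uses the hazard a few years above ``top_age`` as a
    stand-in for the mean age of the open-interval population.
    """
    ages = np.arange(top_age + 1, dtype=float)
    mx = gompertz_hazard(alpha, beta, ages + 0.5)
    mx[-1] = gompertz_hazard(alpha, beta, top_age + 3.0)
    return mx


def arrival_age_profile(top_age: int, family: str = "gamma") -> np.ndarray:
    """Discrete age-at-arrival distribution, unimodal with mode in the 20s."""
    ages = np.arange(top_age + 1, dtype=float)
    if family == "gamma":
        k, theta = 7.0, 4.5                       # mode (k-1)*theta = 27
        from scipy.stats import gamma as _gamma   # noqa: PLC0415
        weights = _gamma.pdf(ages + 0.5, a=k, scale=theta)
    elif family == "triangular":
        peak, upper = 27.0, 70.0
        weights = np.where(ages <= peak, ages / peak,
                           np.clip((upper - ages) / (upper - peak), 0.0, None))
    else:
        raise ConfigurationError(f"unknown arrival age family '{family}'")
    return weights / weights.sum()


def emigration_age_profile(top_age: int) -> np.ndarray:
    """Base departure rates: small everywhere, peaked at young adult ages."""
    ages = np.arange(top_age + 1, dtype=float)
    return 0.003 + 0.022 * np.exp(-0.5 * ((ages - 25.0) / 8.0) ** 2)


def fertility_schedule(tfr: float, top_age: int,
                       span: tuple[int, int] = (15, 49)) -> np.ndarray:
    """Age-specific fertility rates summing to the TFR over the span."""
    ages = np.arange(top_age + 1, dtype=float)
    lo, hi = span
    weights = np.exp(-0.5 * ((ages - 29.0) / 6.0) ** 2)
    weights[(ages < lo) | (ages > hi)] = 0.0
    return tfr * weights / weights.sum()


def national_totals(config: ScenarioConfig, horizon: int = 80) -> dict[int, float]:
    return {
        config.jump_off_year + t:
            max(0.0, config.national_immigration_start
                + config.national_immigration_growth * t)
        for t in range(horizon + 1)
    }


# -- scenario assembly -------------------------------------------------------

def _wave_stock(profile: WaveProfile, config: ScenarioConfig,
                arrival_ages: np.ndarray) -> np.ndarray:
    """Jump-off age structure of one overseas-born group: each arrival-year
    cohort carried forward by Gompertz survival, ages beyond the top folded
    into the open interval."""
    top = config.top_age
    extended = top + 60
    stock = np.zeros(extended + 1)
    for year in range(profile.wave_start_year, profile.wave_end_year + 1):
        elapsed = config.jump_off_year - year
        entry_ages = np.arange(0, extended + 1 - elapsed, dtype=float)
        now_ages = entry_ages + elapsed
        surv = gompertz_survival(profile.gompertz_alpha, profile.gompertz_beta,
                                 entry_ages, now_ages)
        stock[elapsed:] += (profile.annual_arrival_scale
                            * arrival_ages[: entry_ages.size] * surv)
    out = stock[: top + 1].copy()
    out[top] += stock[top + 1:].sum()
    return out


def _native_stock(profile: WaveProfile, config: ScenarioConfig) -> np.ndarray:
    """Stationary-population native-born stock: constant annual births
    survived to the jump-off year."""
    top = config.top_age
    extended = top + 60
    ages = np.arange(extended + 1, dtype=float)
    surv = gompertz_survival(profile.gompertz_alpha, profile.gompertz_beta,
                             np.zeros_like(ages), ages)
    stock = profile.annual_arrival_scale * surv
    out = stock[: top + 1].copy()
    out[top] += stock[top + 1:].sum()
    return out


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate a complete, internally consistent projection scenario."""
    n_bp, top = config.n_birthplaces, config.top_age
    n_ages = top + 1
    names = config.birthplace_names()
    profiles = config.birthplace_profiles

    streams = np.random.SeedSequence(config.seed).spawn(2)
    rng_struct = np.random.default_rng(streams[0])

    arrival_ages = np.zeros(n_ages + 60)
    base_profile = arrival_age_profile(top, config.arrival_age_dist)
    arrival_ages[: base_profile.size] = base_profile

    # per-birthplace female share of inflows: mild, reproducible imbalance
    female_share = rng_struct.uniform(0.47, 0.55, size=n_bp)

    # jump-off stocks
    counts = np.zeros((n_bp, 2, n_ages))
    for j, profile in enumerate(profiles):
        stock = (_native_stock(profile, config) if j == 0
                 else _wave_stock(profile, config, arrival_ages))
        counts[j, FEMALE] = female_share[j] * stock
        counts[j, MALE] = (1.0 - female_share[j]) * stock
    jump_off = PopulationGrid(counts, config.jump_off_year, names)

    # mortality: group Gompertz schedules scaled to national e0 + differential,
    # with a fixed female-male gap split around the group level
    national_mx = gompertz_mortality_schedule(profiles[0].gompertz_alpha,
                                              profiles[0].gompertz_beta, top)
    national_e0 = life_expectancy(national_mx)
    death = np.zeros((n_bp, 2, n_ages))
    death_birth = np.zeros((n_bp, 2))
    for j, profile in enumerate(profiles):
        group_mx = gompertz_mortality_schedule(profile.gompertz_alpha,
                                               profile.gompertz_beta, top)
        group_e0 = national_e0 + profile.e0_differential
        for s, offset in ((FEMALE, +SEX_E0_GAP / 2), (MALE, -SEX_E0_GAP / 2)):
            death[j, s] = scale_rates_to_e0(group_mx, group_e0 + offset)
            death_birth[j, s] = death[j, s, 0]

    emig_base = emigration_age_profile(top)
    emigration = np.stack([
        np.stack([p.emigration_scale * emig_base] * 2) for p in profiles
    ])
    emigration_birth = emigration[:, :, 0].copy()

    fertility = np.stack([fertility_schedule(p.fertility_tfr, top)
                          for p in profiles])

    rates = RateSchedules(death, emigration, fertility, death_birth,
                          emigration_birth)

    # base immigration flows: current waves at full scale, ceased waves at a
    # residual trickle, native-born return migration
    flows = np.zeros((n_bp, 2, n_ages))
    flows_birth = np.zeros((n_bp, 2))
    for j, profile in enumerate(profiles):
        if j == 0:
            level = NATIVE_RETURN_FRACTION * profile.annual_arrival_scale
        elif profile.wave_end_year >= config.jump_off_year:
            level = profile.annual_arrival_scale
        else:
            level = CEASED_WAVE_RESIDUAL * profile.annual_arrival_scale
        shares = np.array([female_share[j], 1.0 - female_share[j]])
        flows[j] = level * shares[:, None] * base_profile[None, :]
        flows_birth[j] = NEWBORN_INFLOW_FRACTION * level * shares
    immigration = ImmigrationFlows(flows, flows_birth, national_totals(config))

    broad = {"AUS": "Australia"}
    main = {"AUS": "AUS"}
    for j in range(1, n_bp):
        broad[names[j]] = _BROAD_REGIONS[(j - 1) % len(_BROAD_REGIONS)]
        main[names[j]] = names[j]
    classification = BirthplaceClassification(broad, main)

    return ScenarioBundle(jump_off, rates, immigration, classification, config)


def default_config(n_birthplaces: int = 5, seed: int = 0,
                   jump_off_year: int = 2016) -> ScenarioConfig:
    """A representative scenario: a native-born majority plus overseas-born
    groups spanning long-ceased, mid-century, tapering and current waves."""
    wave_templates = [
        # (start offset, end offset, scale, e0 diff, emig scale, tfr)
        (-65, -45, 40_000.0, +1.5, 0.6, 1.7),    # long-ceased post-war wave
        (-45, -25, 30_000.0, +0.5, 0.8, 1.8),    # ceased mid-century wave
        (-30, 0, 25_000.0, -0.5, 1.0, 1.9),      # long-running ongoing flow
        (-15, 0, 60_000.0, +2.0, 1.4, 1.6),      # recent student/skilled wave
        (-55, -35, 20_000.0, -1.0, 0.7, 2.0),
        (-20, 0, 35_000.0, +1.0, 1.2, 1.7),
    ]
    profiles = [WaveProfile(wave_start_year=jump_off_year - 100,
                            wave_end_year=jump_off_year,
                            annual_arrival_scale=250_000.0,
                            fertility_tfr=1.8)]
    for j in range(n_birthplaces - 1):
        s, e, scale, diff, emig, tfr = wave_templates[j % len(wave_templates)]
        profiles.append(WaveProfile(
            wave_start_year=jump_off_year + s, wave_end_year=jump_off_year + e,
            annual_arrival_scale=scale, e0_differential=diff,
            emigration_scale=emig, fertility_tfr=tfr))
    return ScenarioConfig(n_birthplaces=n_birthplaces,
                          birthplace_profiles=profiles,
                          jump_off_year=jump_off_year, seed=seed)


# -- grouped census seed -----------------------------------------------------

def generate_grouped_census_seed(bundle: ScenarioBundle, group_width: int = 5,
                                 sigma: float = 0.05):
    """Grouped-age truth plus a noisy single-year seed for testing IPF.

    Returns ``(grouped, seed)`` data frames.  The grouped table is the
    jump-off truth summed over ``group_width``-year bands (the open top age
    is its own group), so grouping conserves totals exactly.  The seed is
    the truth under multiplicative lognormal noise with scale ``sigma``
    (sigma = 0 reproduces the truth bit-for-bit), emulating the mismatch
    between detailed census age patterns and published population totals.
    """
    import pandas as pd
    from .ipf import group_label
    if group_width <= 0:
        raise ConfigurationError("group_width must be positive")
    grid = bundle.jump_off
    top = grid.top_age
    if top % group_width != 0:
        raise ConfigurationError(
            f"group_width {group_width} does not divide the closed age range 0..{top - 1}")
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")

    labels = [group_label(lo, lo + group_width - 1)
              for lo in range(0, top, group_width)] + [group_label(top, None)]
    group_of_age = np.minimum(np.arange(top + 1) // group_width,
                              len(labels) - 1)
    group_of_age[top] = len(labels) - 1

    rows = []
    for i, bp in enumerate(grid.birthplaces):
        for s, sex in enumerate(SEXES):
            sums = np.bincount(group_of_age, weights=grid.counts[i, s],
                               minlength=len(labels))
            rows.extend((bp, sex, lab, sums[g]) for g, lab in enumerate(labels))
    grouped = pd.DataFrame(rows, columns=["birthplace", "sex", "age_group", "count"])

    seed_stream = np.random.SeedSequence(bundle.config_echo.seed).spawn(2)[1]
    rng = np.random.default_rng(seed_stream)
    if sigma == 0:
        noisy = grid.counts.copy()
    else:
        noise = rng.lognormal(mean=0.0, sigma=sigma, size=grid.counts.shape)
        noisy = grid.counts * noise
    seed = PopulationGrid(noisy, grid.reference_year, grid.birthplaces).to_frame()
    return grouped, seed
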
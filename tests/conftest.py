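import numpy as np
import pytest

from cohortcomp import (ImmigrationFlows, PopulationGrid, RateSchedules,
                        ScenarioBundle, WaveProfile)
from cohortcomp.synthetic import ScenarioConfig, generate_scenario


def small_config(seed: int = 0, n_birthplaces: int = 3,
                 top_age: int = 85) -> ScenarioConfig:
    """Compact scenario used across tests: native-born plus one ceased and
    one ongoing migration wave."""
    profiles = [
        WaveProfile(wave_start_year=1916, wave_end_year=2016,
                    annual_arrival_scale=50_000.0, fertility_tfr=1.8),
        WaveProfile(wave_start_year=1950, wave_end_year=1970,
                    annual_arrival_scale=8_000.0, e0_differential=1.0,
                    emigration_scale=0.6, fertility_tfr=1.7),
        WaveProfile(wave_start_year=2001, wave_end_year=2016,
                    annual_arrival_scale=12_000.0, e0_differential=-0.5,
                    emigration_scale=1.2, fertility_tfr=1.9),
    ]
    extra_starts = [1960, 1975, 1990]
    for k in range(n_birthplaces - 3):
        start = extra_starts[k % len(extra_starts)]
        profiles.append(WaveProfile(wave_start_year=start,
                                    wave_end_year=min(start + 25, 2016),
                                    annual_arrival_scale=5_000.0,
                                    fertility_tfr=1.8))
    return ScenarioConfig(n_birthplaces=n_birthplaces,
                          birthplace_profiles=profiles,
                          jump_off_year=2016, top_age=top_age, seed=seed,
                          national_immigration_start=40_000.0,
                          national_immigration_growth=500.0)


@pytest.fixture(scope="session")
def bundle() -> ScenarioBundle:
    return generate_scenario(small_config(seed=7))


def toy_grid(counts_by_age, n_birthplaces=2, reference_year=2016) -> PopulationGrid:
    """Tiny grid with identical counts in every birthplace-sex cell."""
    n_ages = len(counts_by_age)
    counts = np.tile(np.asarray(counts_by_age, dtype=float),
                     (n_birthplaces, 2, 1))
    names = ("AUS",) + tuple(f"OB{j:02d}" for j in range(1, n_birthplaces))
    return PopulationGrid(counts, reference_year, names)


def uniform_rates(n_birthplaces, n_ages, death=0.0, emigration=0.0,
                  fertility=0.0) -> RateSchedules:
    return RateSchedules(
        death=np.full((n_birthplaces, 2, n_ages), float(death)),
        emigration=np.full((n_birthplaces, 2, n_ages), float(emigration)),
        fertility=np.full((n_birthplaces, n_ages), float(fertility)),
        death_birth=np.full((n_birthplaces, 2), float(death)),
        emigration_birth=np.full((n_birthplaces, 2), float(emigration)),
    )


def volumes_only(bundle) -> ScenarioBundle:
    """Copy of a bundle whose inflows act as base-period volumes: no
    national-total trajectory, so projections do not rescale them."""
    imm = ImmigrationFlows(bundle.immigration.flows.copy(),
                           bundle.immigration.flows_birth.copy(), {})
    return ScenarioBundle(bundle.jump_off, bundle.rates, imm,
                          bundle.classification, bundle.config_echo)


def uniform_flows(n_birthplaces, n_ages, per_cell=0.0,
                  newborn=0.0) -> ImmigrationFlows:
    return ImmigrationFlows(
        flows=np.full((n_birthplaces, 2, n_ages), float(per_cell)),
        flows_birth=np.full((n_birthplaces, 2), float(newborn)),
    )
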
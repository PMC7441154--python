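import numpy as np
import pytest

from ecoperturb.climate import EnvironmentSeries
from ecoperturb.core import Cohort, FunctionalGroup, GridCell, ModelParams, Stock


@pytest.fixture
def params():
    return ModelParams()


def flat_env(temperature=20.0, precipitation=50.0, soil_water=0.5, frost_days=0.0):
    """A constant 12-month climatology for targeted unit tests."""
    return EnvironmentSeries(
        temperature=(temperature,) * 12,
        precipitation=(precipitation,) * 12,
        soil_water=(soil_water,) * 12,
        frost_days=(frost_days,) * 12,
        npp_seasonality=(1.0,) * 12,
    )


AUTOTROPH = FunctionalGroup(
    realm_role="autotroph", trophic_group="autotroph", mobility="sessile",
    leaf_strategy="deciduous",
)


def heterotroph_group(trophic_group="herbivore", thermoregulation="ectotherm",
                      reproductive_strategy="iteroparous", mobility="mobile"):
    return FunctionalGroup(
        realm_role="heterotroph",
        trophic_group=trophic_group,
        thermoregulation=thermoregulation,
        reproductive_strategy=reproductive_strategy,
        mobility=mobility,
    )


def make_cohort(trophic_group="herbivore", abundance=10.0, body_mass=10.0,
                adult_mass=None, juvenile_mass=None, reproductive_mass=0.0,
                optimal_prey_mass=None, trophic_index=None, lineage=(0, 0, 1),
                **group_kwargs):
    adult = adult_mass if adult_mass is not None else body_mass
    juvenile = juvenile_mass if juvenile_mass is not None else 0.3 * adult
    if trophic_index is None:
        trophic_index = {"herbivore": 2.0, "omnivore": 2.5, "carnivore": 3.0}[trophic_group]
    return Cohort(
        group=heterotroph_group(trophic_group=trophic_group, **group_kwargs),
        abundance=abundance,
        body_mass=body_mass,
        juvenile_mass=juvenile,
        adult_mass=adult,
        reproductive_mass=reproductive_mass,
        optimal_prey_mass=optimal_prey_mass if optimal_prey_mass is not None else 0.2 * adult,
        trophic_index=trophic_index,
        lineage=lineage,
    )


def make_cell(stock_biomass=None, cohorts=(), env=None, cell_id=(0, 0),
              appropriation=0.0):
    cell = GridCell(
        cell_id=cell_id,
        environment=env if env is not None else flat_env(),
        appropriation_fraction=appropriation,
    )
    if stock_biomass is not None:
        cell.stocks.append(Stock(group=AUTOTROPH, biomass=stock_biomass))
    cell.cohorts.extend(cohorts)
    return cell


def rng(seed=0):
    return np.random.default_rng(seed)
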
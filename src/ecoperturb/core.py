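"""A simplified cohort-and-stock terrestrial ecosystem simulator.

The model advances a small rectangular grid of cells on a monthly time
step.  Plants are pooled biomass *stocks* grown by climate-driven net
primary production (NPP); animals are *cohorts* — groups of identical
individuals characterized by categorical traits (trophic group,
thermoregulation, reproductive strategy, mobility) and continuous traits
(current/juvenile/adult body mass, reproductive mass, optimal prey mass,
a running diet-weighted trophic index).  Each month every cell applies, in
order: stock growth, eating, metabolism, reproduction, mortality; then the
grid applies dispersal, per-cell cohort merging (to cap cohort counts) and
the trophic-index update from the month's realized diets.

Functional forms are deliberately simple and standard: a saturating
(min-of-limitations) climate-driven NPP; Holling type-II intake with a
Gaussian log-body-mass prey-selection kernel; 3/4-power metabolic scaling
with an exponential temperature factor for ectotherms; proportional
background, starvation and senescence hazards.  Human pressure enters as
``appropriation_fraction``: the fraction of each cell's NPP removed before
plants receive it, a pure sink.

Units: grams wet mass per grid cell; cell area is an implicit constant.
Abundances are continuous.  All stochasticity (encounter jitter, mortality
jitter, dispersal destinations) flows through an explicit numpy Generator,
so runs are exactly reproducible from a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

from .climate import EnvironmentSeries, N_MONTHS, temperature_limitation

__all__ = [
    "MIN_BODY_MASS",
    "MAX_BODY_MASS",
    "FunctionalGroup",
    "Stock",
    "Cohort",
    "GridCell",
    "Grid",
    "ModelParams",
    "DietRecord",
    "DietLedger",
    "compute_npp",
    "grow_stocks",
    "eat_step",
    "metabolism_step",
    "reproduction_step",
    "mortality_step",
    "dispersal_step",
    "merge_cohorts",
    "advance_month",
    "spin_up",
    "seed_grid",
    "grid_state",
    "grid_from_state",
    "heterotroph_biomass",
]

#: Hard bounds on individual body mass (g); the standardization bounds of
#: the body-mass-range metric use the same constants.
MIN_BODY_MASS = 1e-5
MAX_BODY_MASS = 1.5e8

#: Annual NPP of an unlimited cell (g wet mass per cell per year).  Sets
#: the overall biomass scale of the model.
NPP_MAX_ANNUAL = 1.0e7
#: Annual moisture-limitation coefficients (per mm rain; per soil-water
#: unit-month).
KP_ANNUAL = 0.000664
KW_ANNUAL = 0.25

TROPHIC_GROUPS = ("herbivore", "omnivore", "carnivore")
_T0_BY_GROUP = {"herbivore": 2.0, "omnivore": 2.5, "carnivore": 3.0}
_HERB, _OMN, _CARN = 1, 2, 3
_TG_CODE = {"herbivore": _HERB, "omnivore": _OMN, "carnivore": _CARN}


@dataclass(frozen=True)
class FunctionalGroup:
    """Categorical trait combination standing in for species identity."""

    realm_role: str  # "autotroph" | "heterotroph"
    trophic_group: str  # "autotroph" | "herbivore" | "omnivore" | "carnivore"
    thermoregulation: str | None = None  # heterotrophs: "endotherm" | "ectotherm"
    reproductive_strategy: str | None = None  # heterotrophs: "semelparous" | "iteroparous"
    mobility: str = "mobile"  # "mobile" | "sessile"
    leaf_strategy: str | None = None  # autotrophs: "deciduous" | "evergreen"

    def __post_init__(self):
        if (self.trophic_group == "autotroph") != (self.realm_role == "autotroph"):
            raise ValueError("trophic_group is 'autotroph' iff realm_role is 'autotroph'")
        if self.realm_role == "heterotroph":
            if self.thermoregulation not in ("endotherm", "ectotherm"):
                raise ValueError("heterotrophs need a thermoregulation mode")
            if self.reproductive_strategy not in ("semelparous", "iteroparous"):
                raise ValueError("heterotrophs need a reproductive strategy")
        if self.mobility not in ("mobile", "sessile"):
            raise ValueError("mobility must be 'mobile' or 'sessile'")


@dataclass(slots=True, eq=False)
class Stock:
    """A pooled autotroph biomass compartment; trophic index fixed at 1."""

    group: FunctionalGroup
    biomass: float = 0.0

    @property
    def trophic_index(self) -> float:
        return 1.0

    def __post_init__(self):
        if self.group.realm_role != "autotroph":
            raise ValueError("Stock requires an autotroph functional group")
        if self.biomass < 0:
            raise ValueError("stock biomass must be >= 0")


@dataclass(slots=True, eq=False)
class Cohort:
    """A group of identical heterotroph individuals in one cell."""

    group: FunctionalGroup
    abundance: float
    body_mass: float
    juvenile_mass: float
    adult_mass: float
    reproductive_mass: float = 0.0
    optimal_prey_mass: float = 1.0
    trophic_index: float = 2.0
    max_body_mass: float = 0.0  # largest body mass attained (0 -> init to body_mass)
    adult_months: float = 0.0  # months spent at adult mass (senescence clock)
    lineage: tuple = ()

    def __post_init__(self):
        if self.group.realm_role != "heterotroph":
            raise ValueError("Cohort requires a heterotroph functional group")
        if not (MIN_BODY_MASS <= self.juvenile_mass <= self.adult_mass <= MAX_BODY_MASS):
            raise ValueError("need 1e-5 g <= juvenile_mass <= adult_mass <= 1.5e8 g")
        if self.abundance < 0 or self.body_mass <= 0 or self.reproductive_mass < 0:
            raise ValueError("abundance >= 0, body_mass > 0, reproductive_mass >= 0")
        if self.trophic_index < 1.0:
            raise ValueError("trophic_index must be >= 1")
        if self.max_body_mass <= 0.0:
            self.max_body_mass = self.body_mass

    @property
    def total_mass(self) -> float:
        """Cohort mass including reproductive potential, N * (M + R)."""
        return self.abundance * (self.body_mass + self.reproductive_mass)


@dataclass(slots=True)
class ModelParams:
    """Tunable coefficients of the simplified simulator.

    Defaults are calibrated so that, with the bundled archetype climates,
    spun-up communities persist in all four systems, carnivores are
    top-down-relevant in the productive aseasonal system and marginal in
    the deserts, and heavy NPP appropriation collapses consumer biomass.
    """

    assimilation_efficiency_herbivory: float = 0.4
    assimilation_efficiency_predation: float = 0.8
    metabolic_exponent: float = 0.75
    metabolic_normalization_endotherm: float = 0.7  # g^(1-exp) per month
    metabolic_normalization_ectotherm: float = 0.35
    temperature_coefficient: float = 0.05  # per degC, ectotherms only
    reference_temperature: float = 20.0  # degC
    max_intake_herbivory: float = 2.0  # g per g^intake_exp per month
    max_intake_predation: float = 5.0
    intake_mass_exponent: float = 0.75
    herbivory_half_saturation: float = 5.0e4  # g plant per cell
    predation_half_saturation: float = 4.0e3  # g kernel-weighted prey per cell
    predator_interference: float = 0.85  # half-saturation inflation per unit demand
    prey_size_width: float = 1.2  # natural-log body-mass units
    same_rank_prey_weight: float = 0.5  # preference for prey of equal trophic rank
    higher_rank_prey_weight: float = 0.1  # preference for prey of higher rank
    omnivore_plant_fraction: float = 0.7
    stock_turnover: float = 0.05  # per month
    background_mortality: float = 0.04  # per month
    starvation_body_mass_floor: float = 0.2  # fraction of adult mass
    starvation_mortality_rate: float = 8.0  # per month at full deficit
    senescence_mortality_rate: float = 0.002  # per month per adult-month/12
    mortality_jitter_sd: float = 0.15
    encounter_jitter_sd: float = 0.08
    max_consumption_fraction: float = 0.5  # of any stock/cohort per month
    min_reproductive_ratio: float = 1.0  # juvenile-masses per individual to spawn
    dispersal_fraction: float = 0.05  # expected per month, mobile cohorts
    dispersal_probability: float = 0.2  # chance a cohort disperses this month
    max_cohorts_per_cell: int = 40
    extinction_threshold: float = 1e-6  # individuals per cell
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("assimilation_efficiency_herbivory", "assimilation_efficiency_predation"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.max_cohorts_per_cell < 8:
            raise ValueError("max_cohorts_per_cell must be >= 8")
        if not 0.0 <= self.dispersal_fraction <= 1.0:
            raise ValueError("dispersal_fraction must lie in [0, 1]")
        if not 0.0 < self.dispersal_probability <= 1.0:
            raise ValueError("dispersal_probability must lie in (0, 1]")
        if not 0.0 < self.max_consumption_fraction <= 1.0:
            raise ValueError("max_consumption_fraction must lie in (0, 1]")


class DietRecord(NamedTuple):
    """One realized feeding transfer: what was eaten, how much, at what
    trophic index (snapshotted at the moment of eating)."""

    prey: object
    mass_eaten: float
    prey_trophic_index: float


class DietLedger:
    """Per-step record of every feeding transfer, keyed by eater cohort.

    Houses the realized dietary fractions used by the trophic-index
    update: for eater *i*, the recorded ``mass_eaten`` of prey *j* equals
    N_j * M_j * P_ij (or B_k * P_ik for a stock), so dietary fractions are
    the recorded masses normalized per eater.  Stored columnar per eater
    (prey, mass and trophic-index lists) for speed; :meth:`records`
    materializes :class:`DietRecord` tuples on demand.
    """

    def __init__(self):
        self._data: dict = {}  # eater -> (prey list, mass list, index list)

    def _entry(self, eater):
        entry = self._data.get(eater)
        if entry is None:
            entry = ([], [], [])
            self._data[eater] = entry
        return entry

    def add(self, eater, prey, mass_eaten: float, prey_trophic_index: float) -> None:
        if mass_eaten <= 0.0:
            return
        preys, masses, indices = self._entry(eater)
        preys.append(prey)
        masses.append(float(mass_eaten))
        indices.append(float(prey_trophic_index))

    def add_batch(self, eater, preys, masses, indices) -> None:
        p, m, t = self._entry(eater)
        p.extend(preys)
        m.extend(masses)
        t.extend(indices)

    def eaters(self):
        return self._data.keys()

    def items(self):
        for eater in self._data:
            yield eater, self.records(eater)

    def diet_totals(self):
        """Yield (eater, total eaten mass, mass-weighted index sum)."""
        for eater, (_, masses, indices) in self._data.items():
            total = 0.0
            weighted = 0.0
            for m, t in zip(masses, indices):
                total += m
                weighted += m * t
            yield eater, total, weighted

    def records(self, eater) -> list[DietRecord]:
        entry = self._data.get(eater)
        if entry is None:
            return []
        return [DietRecord(p, m, t) for p, m, t in zip(*entry)]

    def total_eaten(self, eater) -> float:
        entry = self._data.get(eater)
        return sum(entry[1]) if entry else 0.0

    def dietary_fractions(self, eater) -> list[tuple]:
        """(prey, fraction) pairs; fractions sum to 1 when anything was eaten."""
        entry = self._data.get(eater)
        if not entry:
            return []
        total = sum(entry[1])
        if total <= 0.0:
            return []
        return [(p, m / total) for p, m in zip(entry[0], entry[1])]

    def __len__(self):
        return len(self._data)

    def __bool__(self):
        return bool(self._data)


@dataclass
class GridCell:
    """One grid cell: a homogeneous environment plus its stocks and cohorts."""

    cell_id: tuple
    environment: EnvironmentSeries
    stocks: list = field(default_factory=list)
    cohorts: list = field(default_factory=list)
    appropriation_fraction: float = 0.0
    lineage_counter: int = 0

    def __post_init__(self):
        if not 0.0 <= self.appropriation_fraction <= 1.0:
            raise ValueError("appropriation_fraction must lie in [0, 1]")

    def new_lineage(self) -> tuple:
        self.lineage_counter += 1
        return (*self.cell_id, self.lineage_counter)


class Grid:
    """A rectangular, bounded (non-wrapping) arrangement of grid cells."""

    def __init__(self, cells: list[list[GridCell]]):
        if not cells or not cells[0]:
            raise ValueError("grid must have at least one cell")
        ncols = len(cells[0])
        if any(len(row) != ncols for row in cells):
            raise ValueError("grid must be rectangular")
        self._cells = cells

    @property
    def shape(self) -> tuple:
        return (len(self._cells), len(self._cells[0]))

    def cell(self, row: int, col: int) -> GridCell:
        return self._cells[row][col]

    def cells(self) -> Iterator[GridCell]:
        """Iterate cells in deterministic row-major order."""
        for row in self._cells:
            yield from row

    def neighbors(self, row: int, col: int) -> list[GridCell]:
        """Rook-adjacent cells; edges have fewer neighbours, no wrap."""
        nrows, ncols = self.shape
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r, c = row + dr, col + dc
            if 0 <= r < nrows and 0 <= c < ncols:
                out.append(self._cells[r][c])
        return out


# ---------------------------------------------------------------------------
# Primary production and stock growth


def compute_npp(env: EnvironmentSeries, month: int) -> float:
    """Monthly NPP (g wet mass per cell) for one cell's climatology.

    The annual potential is ``NPP_MAX_ANNUAL`` times a saturating
    temperature limitation (of the annual mean temperature) times a
    saturating moisture limitation (of annual precipitation and soil
    water); the month's value distributes that potential by the
    climatology's production seasonality profile.
    """
    if not isinstance(month, (int, np.integer)) or not 0 <= month < N_MONTHS:
        raise ValueError(f"month must be a 0-based index in [0, {N_MONTHS - 1}]")
    t_lim = float(temperature_limitation(np.mean(env.temperature)))
    water = KP_ANNUAL * sum(env.precipitation) + KW_ANNUAL * sum(env.soil_water)
    m_lim = 1.0 - np.exp(-water)
    return (NPP_MAX_ANNUAL / N_MONTHS) * t_lim * m_lim * env.npp_seasonality[month]


def annual_npp(env: EnvironmentSeries) -> float:
    """Convenience: NPP summed over the 12 months (g per cell per year)."""
    return sum(compute_npp(env, m) for m in range(N_MONTHS))


def grow_stocks(cell: GridCell, params: ModelParams, month: int) -> None:
    """Grow plant stocks by their share of non-appropriated NPP, then apply
    proportional turnover.  Appropriated production is a pure sink."""
    if not cell.stocks:
        return
    npp = compute_npp(cell.environment, month)
    usable = (1.0 - cell.appropriation_fraction) * npp
    share = usable / len(cell.stocks)
    for stock in cell.stocks:
        stock.biomass = max(0.0, (stock.biomass + share) * (1.0 - params.stock_turnover))


# ---------------------------------------------------------------------------
# Eating


def eat_step(
    cell: GridCell, params: ModelParams, rng: np.random.Generator, month: int = 0
) -> DietLedger:
    """One month of feeding in one cell.

    Herbivores (and omnivores, for a configurable effort fraction) remove
    plant biomass with Holling type-II intake in total stock biomass.
    Carnivores (and omnivores with the remaining effort) remove prey-cohort
    mass with a sigmoidal (type-III) intake in kernel-weighted prey
    availability — predators are efficient on dense prey and give up on
    sparse prey — the kernel being Gaussian in log body mass around the
    eater's optimal prey mass.  Ectotherm feeding activity scales with the
    month's temperature exactly as ectotherm metabolism does.  No more than
    ``max_consumption_fraction`` of any stock or cohort can be removed in
    one month.  Eaten mass times the relevant assimilation efficiency is
    credited to eaters — body growth up to adult mass, reproductive mass
    beyond — and every transfer is recorded in the returned
    :class:`DietLedger`.
    """
    ledger = DietLedger()
    cohorts = cell.cohorts
    n = len(cohorts)
    if n == 0:
        return ledger

    M = np.array([c.body_mass for c in cohorts])
    R = np.array([c.reproductive_mass for c in cohorts])
    N = np.array([c.abundance for c in cohorts])
    T = np.array([c.trophic_index for c in cohorts])
    tg = np.array([_TG_CODE[c.group.trophic_group] for c in cohorts])
    indiv_mass = M + R
    jitter = np.exp(params.encounter_jitter_sd * rng.standard_normal(n))

    temp = cell.environment.temperature[month]
    ecto_factor = math.exp(
        params.temperature_coefficient * (temp - params.reference_temperature)
    )
    activity = np.array(
        [
            ecto_factor if c.group.thermoregulation == "ectotherm" else 1.0
            for c in cohorts
        ]
    )
    intake_base = M ** params.intake_mass_exponent * N * jitter * activity
    herb_effort = np.where(
        tg == _HERB, 1.0, np.where(tg == _OMN, params.omnivore_plant_fraction, 0.0)
    )
    pred_effort = np.where(
        tg == _CARN, 1.0, np.where(tg == _OMN, 1.0 - params.omnivore_plant_fraction, 0.0)
    )

    # --- herbivory on stocks -------------------------------------------------
    stock_biomass = np.array([s.biomass for s in cell.stocks]) if cell.stocks else np.zeros(0)
    b_tot = float(stock_biomass.sum())
    plant_eaten = np.zeros(n)
    if b_tot > 0.0:
        saturation = b_tot / (b_tot + params.herbivory_half_saturation)
        demand = herb_effort * params.max_intake_herbivory * intake_base * saturation
        total_demand = demand.sum()
        avail = params.max_consumption_fraction * b_tot
        scale = min(1.0, avail / total_demand) if total_demand > 0.0 else 0.0
        plant_eaten = demand * scale

    # --- predation on cohorts ------------------------------------------------
    pred_gain = np.zeros(n)
    eaten_from = np.zeros(n)
    actual = None
    any_pred = bool(np.any(pred_effort > 0.0)) and n > 1
    if any_pred:
        ln_m = np.log(M)
        ln_opt = np.log([c.optimal_prey_mass for c in cohorts])
        z = (ln_m[None, :] - ln_opt[:, None]) / params.prey_size_width
        z2 = z * z
        kernel = np.where(z2 > 18.0, 0.0, np.exp(-0.5 * z2))  # cut far tails
        # trophic-rank preference: hunting down the web is easy, within
        # rank harder, up the web hardest (keeps intraguild predation from
        # letting omnivores cap their own predators)
        rank_diff = tg[None, :] - tg[:, None]  # prey rank minus eater rank
        pref = np.where(
            rank_diff < 0,
            1.0,
            np.where(rank_diff == 0, params.same_rank_prey_weight, params.higher_rank_prey_weight),
        )
        kernel *= pref
        np.fill_diagonal(kernel, 0.0)
        prey_pool = N * indiv_mass
        weighted = kernel * prey_pool[None, :]
        avail_i = weighted.sum(axis=1)
        # sigmoidal (type-III) response with predator interference: the
        # effective half-saturation grows with the cell's total predation
        # pressure, so prey are pinned in proportion to predator density
        # (ratio dependence) while sparse prey still escape entirely
        demand_ceiling = pred_effort * params.max_intake_predation * intake_base
        k_eff = (
            params.predation_half_saturation
            + params.predator_interference * float(demand_ceiling.sum())
        )
        sat = avail_i * avail_i / (avail_i * avail_i + k_eff * k_eff)
        demand_i = demand_ceiling * sat
        with np.errstate(invalid="ignore", divide="ignore"):
            alloc = np.where(
                avail_i[:, None] > 0.0, weighted / np.where(avail_i == 0.0, 1.0, avail_i)[:, None], 0.0
            ) * demand_i[:, None]
        desired_j = alloc.sum(axis=0)
        avail_j = params.max_consumption_fraction * prey_pool
        with np.errstate(invalid="ignore", divide="ignore"):
            scale_j = np.where(desired_j > avail_j, avail_j / np.where(desired_j == 0.0, 1.0, desired_j), 1.0)
        actual = alloc * scale_j[None, :]
        # drop numerically negligible transfers (< 1e-6 of the eater's
        # realized intake, i.e. irrelevant to any dietary fraction) before
        # anything is applied, so removals, gains and the ledger stay
        # exactly consistent with each other
        row_tot = actual.sum(axis=1)
        tiny = actual < (1e-6 * row_tot)[:, None]
        if tiny.any():
            actual[tiny] = 0.0
        eaten_from = actual.sum(axis=0)
        pred_gain = actual.sum(axis=1)

    # --- apply removals ------------------------------------------------------
    if b_tot > 0.0 and plant_eaten.sum() > 0.0:
        removed = plant_eaten.sum()
        for stock, b in zip(cell.stocks, stock_biomass):
            stock.biomass = max(0.0, b - removed * (b / b_tot))
    if actual is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            dN = np.where(indiv_mass > 0.0, eaten_from / indiv_mass, 0.0)
        for j, c in enumerate(cohorts):
            if dN[j] > 0.0:
                c.abundance = max(0.0, c.abundance - dN[j])

    # --- credit gains (distributed over post-predation survivors) -----------
    gain = (
        params.assimilation_efficiency_herbivory * plant_eaten
        + params.assimilation_efficiency_predation * pred_gain
    )
    for i, c in enumerate(cohorts):
        if gain[i] <= 0.0 or c.abundance <= 0.0:
            continue
        per_individual = gain[i] / c.abundance
        room = max(0.0, c.adult_mass - c.body_mass)
        growth = min(per_individual, room)
        c.body_mass += growth
        c.reproductive_mass += per_individual - growth
        if c.body_mass > c.max_body_mass:
            c.max_body_mass = c.body_mass

    # --- ledger --------------------------------------------------------------
    if b_tot > 0.0:
        stock_shares = (stock_biomass / b_tot).tolist()
        for i, c in enumerate(cohorts):
            eaten = plant_eaten[i]
            if eaten > 0.0:
                ledger.add_batch(
                    c,
                    cell.stocks,
                    [eaten * share for share in stock_shares],
                    [1.0] * len(cell.stocks),
                )
    if actual is not None:
        t_list = T.tolist()
        for i in range(n):
            row = actual[i]
            if row_tot[i] <= 0.0:
                continue
            nz = np.nonzero(row)[0]
            if len(nz) == 0:
                continue
            ledger.add_batch(
                cohorts[i],
                [cohorts[j] for j in nz],
                row[nz].tolist(),
                [t_list[j] for j in nz],
            )
    return ledger


# ---------------------------------------------------------------------------
# Metabolism, reproduction, mortality


def metabolism_step(cell: GridCell, params: ModelParams, month: int) -> None:
    """Deduct metabolic costs from body mass.

    Cost per individual scales as body_mass to the metabolic exponent.
    Ectotherm costs scale exponentially with the month's air temperature;
    endotherm costs do not (their normalization constant is higher).  Body
    mass floors at the model's minimum; the resulting deficit expresses
    itself through the starvation hazard in :func:`mortality_step`.
    """
    temp = cell.environment.temperature[month]
    ecto_factor = math.exp(
        params.temperature_coefficient * (temp - params.reference_temperature)
    )
    k_endo = params.metabolic_normalization_endotherm
    k_ecto = params.metabolic_normalization_ectotherm * ecto_factor
    exponent = params.metabolic_exponent
    for c in cell.cohorts:
        k = k_endo if c.group.thermoregulation == "endotherm" else k_ecto
        cost = k * c.body_mass ** exponent
        c.body_mass = max(c.body_mass - cost, MIN_BODY_MASS)


def reproduction_step(cell: GridCell, params: ModelParams, rng: np.random.Generator) -> None:
    """Convert accumulated reproductive mass of adult cohorts to offspring.

    Offspring abundance is parent abundance times reproductive mass per
    juvenile mass (total mass exactly conserved); offspring start at
    juvenile mass with the parent's trophic index and a fresh lineage tag.
    Iteroparous parents persist with reproductive mass reset; semelparous
    parents are set to zero abundance (removed by the mortality step).
    A cohort counts as adult once its largest attained body mass has
    reached adult mass (current mass dips below it every month through
    metabolic costs), and it spawns once its reproductive store reaches
    ``min_reproductive_ratio`` juvenile masses per individual.
    """
    offspring = []
    for c in cell.cohorts:
        if c.abundance <= 0.0 or c.reproductive_mass <= 0.0:
            continue
        if c.max_body_mass < c.adult_mass * (1.0 - 1e-12):
            continue
        if c.reproductive_mass < params.min_reproductive_ratio * c.juvenile_mass:
            continue
        off_abundance = c.abundance * c.reproductive_mass / c.juvenile_mass
        if off_abundance < params.extinction_threshold:
            continue
        offspring.append(
            Cohort(
                group=c.group,
                abundance=off_abundance,
                body_mass=c.juvenile_mass,
                juvenile_mass=c.juvenile_mass,
                adult_mass=c.adult_mass,
                reproductive_mass=0.0,
                optimal_prey_mass=c.optimal_prey_mass,
                trophic_index=c.trophic_index,
                max_body_mass=c.juvenile_mass,
                adult_months=0.0,
                lineage=cell.new_lineage(),
            )
        )
        c.reproductive_mass = 0.0
        if c.group.reproductive_strategy == "semelparous":
            c.abundance = 0.0
    cell.cohorts.extend(offspring)


def mortality_step(cell: GridCell, params: ModelParams, rng: np.random.Generator) -> None:
    """Apply background, starvation and senescence hazards.

    Survival is ``exp(-(h_bg + h_starv + h_sen) * jitter)``: a constant
    background hazard; a starvation hazard rising quadratically as body
    mass falls below ``starvation_body_mass_floor`` times adult mass; a
    senescence hazard growing with months spent at adult mass.  Dead mass
    leaves the system (no detrital pool).  Cohorts falling below the
    extinction threshold are removed.
    """
    cohorts = cell.cohorts
    if not cohorts:
        return
    jitter = np.exp(params.mortality_jitter_sd * rng.standard_normal(len(cohorts)))
    floor_frac = params.starvation_body_mass_floor
    h_bg = params.background_mortality
    h_starv = params.starvation_mortality_rate
    h_sen = params.senescence_mortality_rate / 12.0
    threshold = params.extinction_threshold
    survivors = []
    for c, jit in zip(cohorts, jitter.tolist()):
        if c.abundance >= threshold:
            if c.max_body_mass >= c.adult_mass * (1.0 - 1e-12):
                c.adult_months += 1.0
            floor = floor_frac * c.adult_mass
            deficit = 1.0 - c.body_mass / floor if (floor > 0 and c.body_mass < floor) else 0.0
            hazard = h_bg + h_starv * deficit * deficit + h_sen * c.adult_months
            c.abundance *= math.exp(-hazard * jit)
        if c.abundance >= threshold:
            survivors.append(c)
    cell.cohorts[:] = survivors


# ---------------------------------------------------------------------------
# Dispersal and cohort merging


def dispersal_step(grid: Grid, params: ModelParams, rng: np.random.Generator) -> None:
    """Move abundance of mobile cohorts to random rook neighbours.

    Each mobile cohort disperses this month with probability
    ``dispersal_probability``; when it does, it sends
    ``dispersal_fraction / dispersal_probability`` of its abundance (so the
    expected monthly flux is ``dispersal_fraction``) to one uniformly
    chosen adjacent cell (edge cells have fewer neighbours; no
    wrap-around).  The emigrants form a clone cohort carrying the same
    lineage tag and traits, so grid-wide abundance per lineage is exactly
    conserved at every step.  Sessile cohorts and stocks never move.
    """
    d = params.dispersal_fraction
    if d <= 0.0:
        return
    p = params.dispersal_probability
    moved_fraction = min(1.0, d / p)
    arrivals: list[tuple[GridCell, Cohort]] = []
    for cell in grid.cells():
        row, col = cell.cell_id
        nbrs = grid.neighbors(row, col)
        if not nbrs:
            continue
        movers = [c for c in cell.cohorts if c.group.mobility == "mobile" and c.abundance > 0.0]
        if not movers:
            continue
        events = rng.random(len(movers)) < p
        choices = rng.integers(0, len(nbrs), size=len(movers))
        for c, moves, k in zip(movers, events, choices):
            if not moves:
                continue
            moved = moved_fraction * c.abundance
            c.abundance -= moved
            clone = replace(c, abundance=moved)
            arrivals.append((nbrs[k], clone))
    for target, clone in arrivals:
        target.cohorts.append(clone)


_MERGE_TRAITS = ("trophic_group", "thermoregulation", "reproductive_strategy", "mobility")


def merge_cohorts(cell: GridCell, params: ModelParams) -> None:
    """Merge the most similar same-trait cohort pairs down to the cap.

    While the cell holds more cohorts than ``max_cohorts_per_cell``, the
    pair with identical categorical traits and the smallest distance in
    (log juvenile, log adult, log current body mass) is merged: abundances
    add, continuous traits combine as abundance-weighted means, and the
    trophic index combines as a total-mass-weighted mean, so total mass and
    abundance are conserved.  If no mergeable pair remains, the cap is
    advisory: a warning is issued and the cell is left over the cap.
    """
    cohorts = cell.cohorts
    n = len(cohorts)
    cap = params.max_cohorts_per_cell
    if n <= cap:
        return

    # Partition by categorical traits; distances only exist within a
    # partition, so each trait class keeps its own small distance matrix.
    groups: dict[tuple, list[int]] = {}
    for idx, c in enumerate(cohorts):
        key = tuple(getattr(c.group, t) for t in _MERGE_TRAITS)
        groups.setdefault(key, []).append(idx)

    class _TraitClass:
        __slots__ = ("members", "x", "dist")

        def __init__(self, members):
            self.members = members  # cohort indices
            self.x = np.log(
                np.array(
                    [
                        [cohorts[i].juvenile_mass, cohorts[i].adult_mass, cohorts[i].body_mass]
                        for i in members
                    ]
                )
            )
            diff = self.x[:, None, :] - self.x[None, :, :]
            d = np.einsum("ijk,ijk->ij", diff, diff)
            m = len(members)
            d[np.triu_indices(m)] = np.inf
            self.dist = d

        def min_pair(self):
            if len(self.members) < 2:
                return np.inf, -1, -1
            flat = int(np.argmin(self.dist))
            a, b = divmod(flat, len(self.members))
            return self.dist[a, b], a, b

        def merge(self, a, b):
            """Merge local positions a and b (a > b); returns merged cohort index."""
            ia, ib = self.members[a], self.members[b]
            _merge_into(cohorts[ia], cohorts[ib])
            # drop b from the bookkeeping
            keep = [k for k in range(len(self.members)) if k != b]
            self.members.pop(b)
            self.x = self.x[keep]
            self.dist = self.dist[np.ix_(keep, keep)]
            a_new = a - 1 if a > b else a
            ci = cohorts[self.members[a_new]]
            xi = np.log([ci.juvenile_mass, ci.adult_mass, ci.body_mass])
            self.x[a_new] = xi
            di = ((self.x - xi[None, :]) ** 2).sum(axis=1)
            for k in range(len(self.members)):
                if k == a_new:
                    continue
                lo, hi = (a_new, k) if a_new > k else (k, a_new)
                self.dist[lo, hi] = di[k]
            return ib

    classes = [_TraitClass(m) for m in groups.values() if len(m) >= 2]
    mins = [tc.min_pair() for tc in classes]
    dead: set[int] = set()
    n_alive = n
    while n_alive > cap:
        best_k = -1
        best_d = np.inf
        for k, (d, _, _) in enumerate(mins):
            if d < best_d:
                best_d, best_k = d, k
        if best_k < 0 or not np.isfinite(best_d):
            warnings.warn(
                "cohort cap exceeded but no mergeable same-trait pair remains",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        tc = classes[best_k]
        _, a, b = mins[best_k]
        dead.add(tc.merge(a, b))
        mins[best_k] = tc.min_pair()
        n_alive -= 1
    if dead:
        cell.cohorts[:] = [c for idx, c in enumerate(cohorts) if idx not in dead]


def _merge_into(a: Cohort, b: Cohort) -> None:
    """Fold cohort ``b`` into ``a``: abundances add, continuous traits are
    abundance-weighted means, the trophic index a total-mass-weighted mean;
    total mass and abundance are conserved exactly."""
    na, nb = a.abundance, b.abundance
    total_n = na + nb
    if total_n <= 0.0:
        return
    wa, wb = na / total_n, nb / total_n
    ma = na * (a.body_mass + a.reproductive_mass)
    mb = nb * (b.body_mass + b.reproductive_mass)
    tm = ma + mb
    if tm > 0.0:
        a.trophic_index = (ma * a.trophic_index + mb * b.trophic_index) / tm
    a.body_mass = max(wa * a.body_mass + wb * b.body_mass, MIN_BODY_MASS)
    a.juvenile_mass = max(wa * a.juvenile_mass + wb * b.juvenile_mass, MIN_BODY_MASS)
    a.adult_mass = wa * a.adult_mass + wb * b.adult_mass
    a.reproductive_mass = wa * a.reproductive_mass + wb * b.reproductive_mass
    a.optimal_prey_mass = wa * a.optimal_prey_mass + wb * b.optimal_prey_mass
    a.max_body_mass = max(a.max_body_mass, wa * a.max_body_mass + wb * b.max_body_mass)
    a.adult_months = wa * a.adult_months + wb * b.adult_months
    if nb > na:
        a.lineage = b.lineage
    a.abundance = total_n


# ---------------------------------------------------------------------------
# Monthly step, spin-up, seeding


def advance_month(
    grid: Grid, params: ModelParams, month: int, rng: np.random.Generator
) -> dict:
    """Advance the whole grid by one month.

    Applies, in order: stock growth, eating, metabolism, reproduction and
    mortality within each cell; then grid-wide dispersal; then per-cell
    cohort merging and the trophic-index update from the month's diet
    ledgers.  Returns the per-cell ledgers keyed by ``cell_id``.
    Deterministic for a given generator state.
    """
    from .metrics import update_trophic_indices

    ledgers: dict = {}
    for cell in grid.cells():
        grow_stocks(cell, params, month)
        ledgers[cell.cell_id] = eat_step(cell, params, rng, month)
        metabolism_step(cell, params, month)
        reproduction_step(cell, params, rng)
        mortality_step(cell, params, rng)
    dispersal_step(grid, params, rng)
    for cell in grid.cells():
        merge_cohorts(cell, params)
        update_trophic_indices(cell, ledgers[cell.cell_id])
    return ledgers


def cohort_records(grid: Grid, time_step: int) -> list[dict]:
    """Tidy per-cohort dump of the grid (one dict per cohort)."""
    rows = []
    for cell in grid.cells():
        r, c = cell.cell_id
        for coh in cell.cohorts:
            rows.append(
                {
                    "time_step": time_step,
                    "cell_row": r,
                    "cell_col": c,
                    "trophic_group": coh.group.trophic_group,
                    "thermoregulation": coh.group.thermoregulation,
                    "abundance": coh.abundance,
                    "body_mass": coh.body_mass,
                    "reproductive_mass": coh.reproductive_mass,
                    "trophic_index": coh.trophic_index,
                }
            )
    return rows


def heterotroph_biomass(grid: Grid) -> float:
    """Total heterotroph mass (incl. reproductive mass) across the grid."""
    return sum(c.total_mass for cell in grid.cells() for c in cell.cohorts)


def spin_up(
    grid: Grid, params: ModelParams, years: int, rng: np.random.Generator
) -> tuple:
    """Run the grid with no human impact until a dynamic steady state.

    Requires ``years >= 1`` and zero appropriation everywhere.  Returns the
    advanced grid and a diagnostics dict holding, per trophic group, the
    relative drift of the 10-year-mean grid biomass over the final two
    decades (``nan`` when the run is shorter than 20 years), plus an
    ``extinct`` flag.  A fully heterotroph-extinct end state triggers a
    warning, not an error: some archetypes legitimately lack whole groups.
    """
    if years < 1:
        raise ValueError("spin_up requires years >= 1")
    for cell in grid.cells():
        if cell.appropriation_fraction != 0.0:
            raise ValueError("spin_up requires zero appropriation everywhere")
    history = {g: [] for g in TROPHIC_GROUPS}
    for year in range(years):
        for month in range(N_MONTHS):
            advance_month(grid, params, month, rng)
        totals = {g: 0.0 for g in TROPHIC_GROUPS}
        for cell in grid.cells():
            for c in cell.cohorts:
                totals[c.group.trophic_group] += c.total_mass
        for g in TROPHIC_GROUPS:
            history[g].append(totals[g])

    drift = {}
    for g in TROPHIC_GROUPS:
        series = np.array(history[g])
        if years >= 20:
            recent = series[-10:].mean()
            earlier = series[-20:-10].mean()
            drift[g] = abs(recent - earlier) / earlier if earlier > 0 else np.nan
        else:
            drift[g] = np.nan
    extinct = heterotroph_biomass(grid) <= 0.0
    if extinct:
        warnings.warn("all heterotrophs extinct at end of spin-up", RuntimeWarning, stacklevel=2)
    return grid, {"drift": drift, "extinct": extinct, "years": years}


#: Adult body masses (g) of the seeding lattice, per trait combination.
#: The floor keeps per-month relative metabolic turnover below ~1, the
#: fastest dynamics a monthly step can resolve.
SEED_ADULT_MASSES = tuple(float(m) for m in np.geomspace(1e-1, 1e6, 4))
#: Initial biomass (g) given to every seeded cohort and stock.
SEED_COHORT_BIOMASS = 2e3
SEED_STOCK_BIOMASS = 1e5
#: Juvenile mass as a fraction of adult mass.
JUVENILE_MASS_RATIO = 0.3
#: Optimal prey mass as a fraction of the eater's adult mass.
OPTIMAL_PREY_RATIO = 0.2


def _seed_cell(cell_id: tuple, env: EnvironmentSeries) -> GridCell:
    stocks = [
        Stock(
            group=FunctionalGroup(
                realm_role="autotroph",
                trophic_group="autotroph",
                mobility="sessile",
                leaf_strategy=leaf,
            ),
            biomass=SEED_STOCK_BIOMASS,
        )
        for leaf in ("deciduous", "evergreen")
    ]
    cell = GridCell(cell_id=cell_id, environment=env, stocks=stocks)
    for tg in TROPHIC_GROUPS:
        for thermo in ("endotherm", "ectotherm"):
            for strategy in ("semelparous", "iteroparous"):
                group = FunctionalGroup(
                    realm_role="heterotroph",
                    trophic_group=tg,
                    thermoregulation=thermo,
                    reproductive_strategy=strategy,
                    mobility="mobile",
                )
                for adult in SEED_ADULT_MASSES:
                    juvenile = max(MIN_BODY_MASS, JUVENILE_MASS_RATIO * adult)
                    cell.cohorts.append(
                        Cohort(
                            group=group,
                            abundance=SEED_COHORT_BIOMASS / adult,
                            body_mass=adult,
                            juvenile_mass=juvenile,
                            adult_mass=adult,
                            optimal_prey_mass=OPTIMAL_PREY_RATIO * adult,
                            trophic_index=_T0_BY_GROUP[tg],
                            lineage=cell.new_lineage(),
                        )
                    )
    return cell


def seed_grid(env: EnvironmentSeries, shape: tuple = (3, 3), params: ModelParams | None = None) -> Grid:
    """Build a freshly seeded grid sharing one climatology.

    Every cell receives one stock per leaf strategy and a trait-spanning
    lattice of heterotroph cohorts (log-spaced adult masses per trophic
    group x thermoregulation x reproductive strategy), each with a small
    equal biomass; spin-up then selects the viable subset.
    """
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise ValueError("grid shape must be at least 1 x 1")
    cells = [[_seed_cell((r, c), env) for c in range(ncols)] for r in range(nrows)]
    return Grid(cells)


# ---------------------------------------------------------------------------
# State snapshots


_STATE_SCHEMA = 1


def _group_to_dict(g: FunctionalGroup) -> dict:
    return {
        "realm_role": g.realm_role,
        "trophic_group": g.trophic_group,
        "thermoregulation": g.thermoregulation,
        "reproductive_strategy": g.reproductive_strategy,
        "mobility": g.mobility,
        "leaf_strategy": g.leaf_strategy,
    }


def grid_state(grid: Grid) -> dict:
    """Serialize the full grid state to a JSON-compatible dict.

    Floats are stored as Python floats, so in-memory snapshot/restore is
    bit-exact and a JSON file round-trip is too (shortest-repr floats).
    """
    cells = []
    for cell in grid.cells():
        cells.append(
            {
                "cell_id": list(cell.cell_id),
                "environment": cell.environment.to_dict(),
                "appropriation_fraction": cell.appropriation_fraction,
                "lineage_counter": cell.lineage_counter,
                "stocks": [
                    {"group": _group_to_dict(s.group), "biomass": s.biomass}
                    for s in cell.stocks
                ],
                "cohorts": [
                    {
                        "group": _group_to_dict(c.group),
                        "abundance": c.abundance,
                        "body_mass": c.body_mass,
                        "juvenile_mass": c.juvenile_mass,
                        "adult_mass": c.adult_mass,
                        "reproductive_mass": c.reproductive_mass,
                        "optimal_prey_mass": c.optimal_prey_mass,
                        "trophic_index": c.trophic_index,
                        "max_body_mass": c.max_body_mass,
                        "adult_months": c.adult_months,
                        "lineage": list(c.lineage),
                    }
                    for c in cell.cohorts
                ],
            }
        )
    return {"schema": _STATE_SCHEMA, "shape": list(grid.shape), "cells": cells}


def grid_from_state(state: dict) -> Grid:
    """Rebuild a grid from :func:`grid_state` output (bit-exact restore)."""
    if state.get("schema") != _STATE_SCHEMA:
        raise ValueError("unsupported state schema")
    nrows, ncols = state["shape"]
    lookup = {tuple(c["cell_id"]): c for c in state["cells"]}
    rows = []
    for r in range(nrows):
        row = []
        for c in range(ncols):
            d = lookup[(r, c)]
            env = EnvironmentSeries.from_dict(d["environment"])
            cell = GridCell(
                cell_id=(r, c),
                environment=env,
                appropriation_fraction=d["appropriation_fraction"],
                lineage_counter=d["lineage_counter"],
            )
            for s in d["stocks"]:
                cell.stocks.append(
                    Stock(group=FunctionalGroup(**s["group"]), biomass=s["biomass"])
                )
            for cd in d["cohorts"]:
                cell.cohorts.append(
                    Cohort(
                        group=FunctionalGroup(**cd["group"]),
                        abundance=cd["abundance"],
                        body_mass=cd["body_mass"],
                        juvenile_mass=cd["juvenile_mass"],
                        adult_mass=cd["adult_mass"],
                        reproductive_mass=cd["reproductive_mass"],
                        optimal_prey_mass=cd["optimal_prey_mass"],
                        trophic_index=cd["trophic_index"],
                        max_body_mass=cd["max_body_mass"],
                        adult_months=cd["adult_months"],
                        lineage=tuple(cd["lineage"]),
                    )
                )
            row.append(cell)
        rows.append(row)
    return Grid(rows)
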
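"""Synthetic monthly climatologies for four archetype terrestrial ecosystems.

The simulator is driven by idealized 12-month climatologies rather than
downloaded climate data.  Four bundled archetypes span the major global
productivity x seasonality gradients: a humid aseasonal tropical system
(``uganda_like``), a seasonal temperate system (``france_like``), a cold,
strongly seasonal semi-desert (``gobi_like``) and a hot aseasonal desert
(``libya_like``).  Each archetype is a small parameter bundle (mean
temperature, seasonal temperature amplitude, annual precipitation and its
seasonal concentration, soil bucket capacity); the generator expands it
deterministically into monthly air temperature, precipitation, soil water
availability, frost days and a plant-production seasonality profile.  The
same twelve monthly values repeat in every simulated year, i.e. there is no
interannual climatic variability.

The archetype parameter values are configuration choices that satisfy the
qualitative productivity/seasonality ordering of the four systems; they are
not measurements of the real locations they are loosely named after.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np

N_MONTHS = 12

#: Months with mean temperature below this (degC) accumulate frost days.
FROST_THRESHOLD_C = 0.0
#: Temperature span (degC) over which frost days ramp from 0 to a full month.
FROST_RAMP_C = 10.0
#: Soil-bucket evaporative demand, mm of water per degC per month.
PET_MM_PER_DEGC = 5.0
#: Years the soil bucket is cycled before the climatological year is read off.
_BUCKET_SPINUP_YEARS = 10

# Monthly moisture-limitation coefficients used for the within-year
# production profile (per mm rain; per unit soil-water fraction).
KP_MONTHLY = 0.008
KW_MONTHLY = 2.0

PRODUCTIVITY_CLASSES = ("very_high", "moderately_high", "moderately_low", "very_low")
SEASONALITY_CLASSES = ("low", "high")


def temperature_limitation(t_celsius):
    """Saturating temperature limitation on plant production, in (0, 1).

    Logistic in temperature with the classic climate-envelope constants
    (half-saturation near 11 degC); vectorizes over arrays.
    """
    return 1.0 / (1.0 + np.exp(1.315 - 0.119 * np.asarray(t_celsius, dtype=float)))


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameter bundle describing one archetype climate.

    Parameters
    ----------
    name:
        Label of the archetype (``uganda_like`` etc. for the bundled four).
    productivity_class, seasonality_class:
        Ordinal class labels placing the archetype on the productivity x
        seasonality grid.
    mean_temperature:
        Annual mean air temperature, degC.
    temperature_amplitude:
        Half the peak-to-trough seasonal temperature swing, degC.
    annual_precipitation:
        Total precipitation, mm per year.
    precipitation_seasonality:
        Dimensionless in [0, 1]; 0 spreads rain uniformly over the year,
        1 concentrates it maximally in the wet half-year.
    soil_capacity_mm:
        Capacity of the single-bucket soil water store, mm.
    wet_peak_month:
        0-based month at which the precipitation sinusoid peaks.
    """

    name: str
    productivity_class: str
    seasonality_class: str
    mean_temperature: float
    temperature_amplitude: float
    annual_precipitation: float
    precipitation_seasonality: float
    soil_capacity_mm: float = 100.0
    wet_peak_month: int = 6

    def __post_init__(self):
        if self.productivity_class not in PRODUCTIVITY_CLASSES:
            raise ValueError(f"unknown productivity class {self.productivity_class!r}")
        if self.seasonality_class not in SEASONALITY_CLASSES:
            raise ValueError(f"unknown seasonality class {self.seasonality_class!r}")
        if self.temperature_amplitude < 0:
            raise ValueError("temperature_amplitude must be >= 0")
        if self.annual_precipitation < 0:
            raise ValueError("annual_precipitation must be >= 0")
        if not 0.0 <= self.precipitation_seasonality <= 1.0:
            raise ValueError("precipitation_seasonality must lie in [0, 1]")
        if self.soil_capacity_mm <= 0:
            raise ValueError("soil_capacity_mm must be positive")
        if not 0 <= self.wet_peak_month < N_MONTHS:
            raise ValueError("wet_peak_month must be a 0-based month index")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchetypeSpec":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ArchetypeSpec":
        return cls.from_dict(json.loads(s))


#: The four bundled archetypes.  Productivity ordering (annual production
#: computed by :func:`ecoperturb.core.compute_npp`) is
#: uganda_like > france_like > gobi_like > libya_like, and the two
#: ``seasonality_class='high'`` archetypes have larger temperature
#: amplitudes and more peaked within-year production than the two
#: ``'low'`` ones.  Libya's rain peaks in winter (Mediterranean timing),
#: which keeps its within-year production profile flat.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "uganda_like": ArchetypeSpec(
        name="uganda_like",
        productivity_class="very_high",
        seasonality_class="low",
        mean_temperature=24.0,
        temperature_amplitude=1.5,
        annual_precipitation=1400.0,
        precipitation_seasonality=0.10,
        soil_capacity_mm=150.0,
        wet_peak_month=6,
    ),
    "france_like": ArchetypeSpec(
        name="france_like",
        productivity_class="moderately_high",
        seasonality_class="high",
        mean_temperature=11.0,
        temperature_amplitude=10.0,
        annual_precipitation=800.0,
        precipitation_seasonality=0.45,
        soil_capacity_mm=120.0,
        wet_peak_month=6,
    ),
    "gobi_like": ArchetypeSpec(
        name="gobi_like",
        productivity_class="moderately_low",
        seasonality_class="high",
        mean_temperature=6.0,
        temperature_amplitude=15.0,
        annual_precipitation=150.0,
        precipitation_seasonality=0.75,
        soil_capacity_mm=60.0,
        wet_peak_month=6,
    ),
    "libya_like": ArchetypeSpec(
        name="libya_like",
        productivity_class="very_low",
        seasonality_class="low",
        mean_temperature=23.0,
        temperature_amplitude=8.0,
        annual_precipitation=25.0,
        precipitation_seasonality=0.15,
        soil_capacity_mm=30.0,
        wet_peak_month=0,
    ),
}


@dataclass(frozen=True)
class EnvironmentSeries:
    """A deterministic 12-month climatology for one grid cell.

    All fields are 12-tuples (January-first, 0-based months): air
    temperature (degC), precipitation (mm/month), available soil water
    (dimensionless fraction of bucket capacity in [0, 1]), frost days
    (days/month in [0, 31]) and the plant-production seasonality profile
    (dimensionless monthly weights with mean exactly 1).
    """

    temperature: tuple
    precipitation: tuple
    soil_water: tuple
    frost_days: tuple
    npp_seasonality: tuple

    def __post_init__(self):
        for field_name in (
            "temperature",
            "precipitation",
            "soil_water",
            "frost_days",
            "npp_seasonality",
        ):
            vals = tuple(float(v) for v in getattr(self, field_name))
            if len(vals) != N_MONTHS:
                raise ValueError(f"{field_name} must have {N_MONTHS} monthly values")
            if not all(math.isfinite(v) for v in vals):
                raise ValueError(f"{field_name} contains non-finite values")
            object.__setattr__(self, field_name, vals)
        if any(p < 0 for p in self.precipitation):
            raise ValueError("precipitation must be non-negative")
        if any(not 0.0 <= w <= 1.0 for w in self.soil_water):
            raise ValueError("soil_water must lie in [0, 1]")
        if any(not 0.0 <= d <= 31.0 for d in self.frost_days):
            raise ValueError("frost_days must lie in [0, 31]")
        if abs(sum(self.npp_seasonality) / N_MONTHS - 1.0) > 1e-9:
            raise ValueError("npp_seasonality must have mean 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSeries":
        return cls(**{k: tuple(v) for k, v in d.items()})


def make_archetype(name: str) -> ArchetypeSpec:
    """Return the bundled parameterization for one of the four archetypes.

    Raises ``ValueError`` for unknown labels, listing the valid ones.
    """
    try:
        return ARCHETYPES[name]
    except KeyError:
        valid = ", ".join(sorted(ARCHETYPES))
        raise ValueError(f"unknown archetype {name!r}; valid labels: {valid}") from None


def _soil_bucket(spec: ArchetypeSpec, temperature: np.ndarray, precipitation: np.ndarray) -> np.ndarray:
    """Cycle a single-bucket soil water model to its climatological year.

    Monthly refill equals precipitation; demand is proportional to
    above-freezing temperature; storage is clipped to [0, capacity].
    """
    cap = spec.soil_capacity_mm
    demand = PET_MM_PER_DEGC * np.maximum(temperature, 0.0)
    store = cap / 2.0
    series = np.zeros(N_MONTHS)
    for year in range(_BUCKET_SPINUP_YEARS):
        for m in range(N_MONTHS):
            store = min(max(store + precipitation[m] - demand[m], 0.0), cap)
            series[m] = store
    return series / cap


def generate_environment(spec: ArchetypeSpec) -> EnvironmentSeries:
    """Expand an archetype into its deterministic monthly climatology.

    Temperature is a sinusoid around the annual mean; precipitation
    partitions the annual total with a sinusoidal wet-season concentration;
    soil water comes from the bucket model; frost days ramp in below
    :data:`FROST_THRESHOLD_C`; the production seasonality profile is the
    normalized product of the monthly temperature, moisture and frost
    limitations.  Pure function of the spec (bit-identical on repeat calls).
    """
    months = np.arange(N_MONTHS)
    phase_t = 2.0 * math.pi * (months - 6) / N_MONTHS
    temperature = spec.mean_temperature + spec.temperature_amplitude * np.cos(phase_t)

    phase_p = 2.0 * math.pi * (months - spec.wet_peak_month) / N_MONTHS
    precipitation = (spec.annual_precipitation / N_MONTHS) * (
        1.0 + spec.precipitation_seasonality * np.cos(phase_p)
    )
    precipitation = np.maximum(precipitation, 0.0)

    soil_water = _soil_bucket(spec, temperature, precipitation)

    frost_days = 31.0 * np.clip(
        (FROST_THRESHOLD_C - temperature) / FROST_RAMP_C, 0.0, 1.0
    )

    # Within-year production profile: product of monthly limitations,
    # normalized to mean 1 (uniform when the climate shuts production off
    # entirely, so the profile stays well defined).
    t_lim = temperature_limitation(temperature)
    m_lim = 1.0 - np.exp(-(KP_MONTHLY * precipitation + KW_MONTHLY * soil_water))
    f_lim = 1.0 - frost_days / 31.0
    share = t_lim * m_lim * f_lim
    total = share.sum()
    if total <= 0.0:
        seasonality = np.ones(N_MONTHS)
    else:
        seasonality = share * (N_MONTHS / total)
        # guard against rounding drift in the mean-1 invariant
        seasonality = seasonality * (N_MONTHS / seasonality.sum())

    return EnvironmentSeries(
        temperature=tuple(temperature),
        precipitation=tuple(precipitation),
        soil_water=tuple(soil_water),
        frost_days=tuple(frost_days),
        npp_seasonality=tuple(seasonality),
    )


def environment_table(env: EnvironmentSeries):
    """Return the climatology as a list of per-month dicts (CSV-friendly)."""
    rows = []
    for m in range(N_MONTHS):
        rows.append(
            {
                "month": m,
                "temperature": env.temperature[m],
                "precipitation": env.precipitation[m],
                "soil_water": env.soil_water[m],
                "frost_days": env.frost_days[m],
                "npp_seasonality": env.npp_seasonality[m],
            }
        )
    return rows
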
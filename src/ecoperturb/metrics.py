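"""Ecosystem-structure metrics.

Implements the continuous per-cohort trophic index (a Christensen–Pauly
style diet-weighted mean over the month's realized diet), the
biomass-weighted mean trophic level, standardized trophic and body-mass
ranges, and per-trophic-group biomass/abundance summaries of a whole
grid.  Undefined quantities (e.g. the mean trophic level of an empty
community) are reported as ``nan`` rather than 0 so downstream series can
gap instead of plunging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .core import DietLedger, Grid, GridCell

UNDEFINED = float("nan")

HETEROTROPH_GROUPS = ("herbivore", "omnivore", "carnivore")


@dataclass(frozen=True)
class MetricsParams:
    """Standardization bounds of the range metrics.

    ``t_max``/``t_min`` bound the trophic index (hypothetical maximum 40.0,
    minimum possible 1.0); ``m_max``/``m_min`` are the model's potential
    body-mass bounds (1.5e8 g and 1e-5 g).
    """

    t_max: float = 40.0
    t_min: float = 1.0
    m_max: float = 1.5e8
    m_min: float = 1e-5

    def __post_init__(self):
        if not (self.t_max > self.t_min and self.m_max > self.m_min):
            raise ValueError("require t_max > t_min and m_max > m_min")


DEFAULT_METRICS_PARAMS = MetricsParams()


@dataclass(frozen=True)
class MetricsRow:
    """Per-timestep grid-wide ecosystem summary."""

    time_step: int
    biomass_autotroph: float = 0.0
    biomass_herbivore: float = 0.0
    biomass_omnivore: float = 0.0
    biomass_carnivore: float = 0.0
    abundance_herbivore: float = 0.0
    abundance_omnivore: float = 0.0
    abundance_carnivore: float = 0.0
    mean_trophic_level: float = UNDEFINED
    trophic_range: float = UNDEFINED
    body_mass_range: float = UNDEFINED

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_FIELDS = tuple(f.name for f in fields(MetricsRow) if f.name != "time_step")


def update_trophic_indices(cell, ledger) -> None:
    """Refresh cohort trophic indices from the month's realized diets.

    For each eater with a non-empty diet ledger, the new index is one plus
    the eaten-mass-weighted mean of prey trophic indices (prey states and
    indices as snapshotted at the moment of eating).  Eaters with empty
    diets this month keep their previous index; stocks are always at 1.
    """
    for eater, total, weighted in ledger.diet_totals():
        if total <= 0.0:
            if ledger.records(eater):
                raise ValueError("diet ledger has records but zero eaten mass")
            continue
        eater.trophic_index = 1.0 + weighted / total


def mean_trophic_level(cohorts) -> float:
    """Total-mass-weighted mean trophic index over cohorts (nan if empty)."""
    num = 0.0
    den = 0.0
    for c in cohorts:
        w = c.abundance * (c.body_mass + c.reproductive_mass)
        num += w * c.trophic_index
        den += w
    if den <= 0.0:
        return UNDEFINED
    return num / den


def trophic_range(cohorts, params: MetricsParams = DEFAULT_METRICS_PARAMS) -> float:
    """(max - min) cohort trophic index, standardized to [0, 1]."""
    values = [c.trophic_index for c in cohorts]
    if not values:
        return UNDEFINED
    return (max(values) - min(values)) / (params.t_max - params.t_min)


def body_mass_range(cohorts, params: MetricsParams = DEFAULT_METRICS_PARAMS) -> float:
    """(max - min) current cohort body mass, standardized to [0, 1]."""
    values = [c.body_mass for c in cohorts]
    if not values:
        return UNDEFINED
    return (max(values) - min(values)) / (params.m_max - params.m_min)


def summarize(grid, time_step: int, params: MetricsParams = DEFAULT_METRICS_PARAMS) -> MetricsRow:
    """Grid-wide totals and pooled functional-structure metrics.

    Biomasses and abundances are summed over all cells (autotrophs from
    stocks; heterotroph groups from N * (body + reproductive) mass); the
    mean trophic level and the two range metrics pool cohorts across the
    whole grid, since responses are reported at landscape level.
    """
    biomass = {g: 0.0 for g in HETEROTROPH_GROUPS}
    abundance = {g: 0.0 for g in HETEROTROPH_GROUPS}
    autotroph = 0.0
    pooled = []
    for cell in grid.cells():
        for s in cell.stocks:
            autotroph += s.biomass
        for c in cell.cohorts:
            if c.abundance <= 0.0:
                continue
            g = c.group.trophic_group
            biomass[g] += c.total_mass
            abundance[g] += c.abundance
            pooled.append(c)
    return MetricsRow(
        time_step=time_step,
        biomass_autotroph=autotroph,
        biomass_herbivore=biomass["herbivore"],
        biomass_omnivore=biomass["omnivore"],
        biomass_carnivore=biomass["carnivore"],
        abundance_herbivore=abundance["herbivore"],
        abundance_omnivore=abundance["omnivore"],
        abundance_carnivore=abundance["carnivore"],
        mean_trophic_level=mean_trophic_level(pooled),
        trophic_range=trophic_range(pooled, params),
        body_mass_range=body_mass_range(pooled, params),
    )


def summarize_cell(cell, time_step: int, params: MetricsParams = DEFAULT_METRICS_PARAMS) -> MetricsRow:
    """Per-cell variant of :func:`summarize` (non-default granularity)."""

    class _One:
        def cells(self):
            yield cell

    return summarize(_One(), time_step, params)


def relative_to_baseline(impacted: MetricsRow, baseline: MetricsRow) -> dict:
    """Each metric as a percentage of the paired undisturbed baseline.

    Both rows must come from the same time step; quantities whose baseline
    is zero or undefined map to ``nan``.
    """
    if impacted.time_step != baseline.time_step:
        raise ValueError(
            f"time steps differ: impacted {impacted.time_step} vs baseline {baseline.time_step}"
        )
    out = {}
    for name in METRIC_FIELDS:
        b = getattr(baseline, name)
        v = getattr(impacted, name)
        if b == 0.0 or math.isnan(b) or math.isnan(v):
            out[name] = UNDEFINED
        else:
            out[name] = 100.0 * v / b
    return out
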
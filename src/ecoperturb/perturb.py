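"""NPP-appropriation forcing protocols.

Human pressure is expressed as the fraction of each cell's net primary
production appropriated (removed before plants receive it); appropriated
production is a pure sink.  Two protocols are encoded:

* **Protocol 1** ramps the fraction up by ``ramp_rate`` per year (default
  1 %/yr) to a target level and holds it there until a fixed horizon
  (default 100 years from the onset of escalation).
* **Protocol 2** ramps up at the same rate to a peak (0.95 by default,
  with 0.80 and 0.90 variants) and then back down to zero, to probe
  reversibility.

The fraction changes at year boundaries and is constant over the 12
monthly steps within a year.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

MAX_FRACTION = 0.95
DEFAULT_RAMP_RATE = 0.01
DEFAULT_PROTOCOL2_PEAKS = (0.80, 0.90, 0.95)


@dataclass(frozen=True)
class PerturbationSchedule:
    """Mapping from simulation year to NPP appropriation fraction."""

    protocol: int
    target_fraction: float
    ramp_rate: float
    total_years: int

    def __post_init__(self):
        if self.protocol not in (1, 2):
            raise ValueError("protocol must be 1 or 2")
        if not 0.0 <= self.target_fraction <= MAX_FRACTION:
            raise ValueError(f"target_fraction must lie in [0, {MAX_FRACTION}]")
        if self.ramp_rate <= 0.0:
            raise ValueError("ramp_rate must be positive")
        if self.total_years < 0:
            raise ValueError("total_years must be >= 0")

    def fraction_at(self, year: float) -> float:
        """Appropriation fraction in effect during (real-valued) ``year``.

        Piecewise linear with breakpoints at year granularity;
        ``fraction_at(0) == 0`` for ramped schedules.
        """
        if self.protocol == 1:
            return min(self.ramp_rate * year, self.target_fraction)
        peak_year = self.target_fraction / self.ramp_rate
        if year <= peak_year:
            return min(self.ramp_rate * year, self.target_fraction)
        return max(self.target_fraction - self.ramp_rate * (year - peak_year), 0.0)

    def as_table(self) -> list[dict]:
        """Year-by-year fraction table (integer years 0..total_years)."""
        return [
            {"year": y, "fraction": self.fraction_at(y)}
            for y in range(self.total_years + 1)
        ]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "PerturbationSchedule":
        return cls(**json.loads(s))


def schedule_protocol1(
    target_fraction: float,
    total_years: int = 100,
    ramp_rate: float = DEFAULT_RAMP_RATE,
) -> PerturbationSchedule:
    """Ramp-and-hold schedule: up at ``ramp_rate``/yr to the target, then
    held until ``total_years`` have elapsed from the onset of escalation."""
    return PerturbationSchedule(
        protocol=1,
        target_fraction=target_fraction,
        ramp_rate=ramp_rate,
        total_years=total_years,
    )


def schedule_protocol2(
    peak_fraction: float = 0.95, ramp_rate: float = DEFAULT_RAMP_RATE
) -> PerturbationSchedule:
    """Escalate-release schedule: up at ``ramp_rate``/yr to the peak, then
    down at the same rate to zero (symmetric about the peak year)."""
    total_years = int(round(2.0 * peak_fraction / ramp_rate))
    return PerturbationSchedule(
        protocol=2,
        target_fraction=peak_fraction,
        ramp_rate=ramp_rate,
        total_years=total_years,
    )


def apply_schedule(grid, schedule: PerturbationSchedule, year: float) -> None:
    """Set every cell's appropriation fraction to the schedule's value for
    ``year`` (the impact is spatially uniform across the grid)."""
    if not 0 <= year <= schedule.total_years:
        raise ValueError(
            f"year {year} outside schedule horizon [0, {schedule.total_years}]"
        )
    fraction = schedule.fraction_at(year)
    for cell in grid.cells():
        cell.appropriation_fraction = fraction
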
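"""Quality-adjusted life years and life years from an occupancy trace.

Person-time in each health state is weighted by its utility (progression-free
0.85, progressed 0.69, dead 0 in the base case), discounted at the same
annual rate as costs, and accumulated cycle by cycle.  Grade >=3 adverse
events subtract utility once, in the first cycle, for one cycle's duration,
scaled by the summed incidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psm import OccupancyTrace, discount_factor

__all__ = ["UtilitySet", "qaly", "life_years"]


@dataclass(frozen=True)
class UtilitySet:
    u_pf: float = 0.85
    u_pd: float = 0.69
    u_dead: float = 0.0
    ae_disutility: float = -0.28

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pd <= self.u_pf <= 1.02):
            raise ValueError("utilities must satisfy 0 <= u_pd <= u_pf <= 1.02")
        if self.ae_disutility > 0:
            raise ValueError("adverse-event disutility must be non-positive")


def _state_years(
    trace: OccupancyTrace, w_pf: float, w_pd: float, annual_discount: float
) -> float:
    cycle_years = trace.grid.cycle_months / 12.0
    disc = discount_factor(trace.time_months, annual_discount)
    frac = trace.grid.cycle_fractions
    per_cycle = (w_pf * trace.pf + w_pd * trace.pd) * frac * disc
    return float(per_cycle.sum() * cycle_years)


def qaly(
    trace: OccupancyTrace,
    utilities: UtilitySet,
    total_ae_incidence: float = 0.0,
    annual_discount: float = 0.05,
) -> float:
    """Discounted QALYs for one arm.

    The AE term is ``ae_disutility * total_ae_incidence * one cycle`` applied
    at time zero (undiscounted), matching the assumption that grade >=3
    events occur in the first treatment cycle.
    """
    cycle_years = trace.grid.cycle_months / 12.0
    base = _state_years(trace, utilities.u_pf, utilities.u_pd, annual_discount)
    ae_term = utilities.ae_disutility * total_ae_incidence * cycle_years
    return base + ae_term


def life_years(trace: OccupancyTrace, annual_discount: float = 0.0) -> float:
    """(Optionally discounted) life years: utility 1 while alive, no AE term."""
    return _state_years(trace, 1.0, 1.0, annual_discount)
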
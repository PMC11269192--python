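"""Mechanistic per-arm costing over an occupancy trace.

Six cost categories are accrued in discounted US dollars: drug acquisition,
administration (hospitalization, infusion and premedication on intravenous
days), monitoring (a per-cycle laboratory panel and contrast CT every second
cycle), grade >=3 adverse-event management (a lump applied in the first
cycle), post-progression management, and end-of-life care triggered by the
per-cycle death increment.

Treatment-driven categories (acquisition, administration, monitoring) accrue
in proportion to progression-free occupancy, reflecting treatment until
progression.  Drug quantities are rounded to dispensable units (vials or
tablets) with surplus discarded; the rounding level and mode are configurable
per drug.

The adverse-event and post-progression categories additionally accept
override totals.  The published analysis reports category totals for these
two that a direct unit-cost mechanism does not reproduce, so the shipped
defaults carry the reported totals as overrides while the mechanistic value
is always computed and reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psm import OccupancyTrace, discount_factor

__all__ = [
    "GlobalAssumptions",
    "PackSpec",
    "DrugSchedule",
    "Regimen",
    "UnitCosts",
    "AEProfile",
    "CostBreakdown",
    "ConfigurationError",
    "dose_mg",
    "packs_needed",
    "drug_cost_per_cycle",
    "admin_cost_per_cycle",
    "lab_panel_cost",
    "monitoring_cost",
    "ae_expected_cost",
    "terminal_cost",
    "pd_management_cost",
    "total_costs",
]

AE_NAMES = (
    "anemia",
    "neutropenia",
    "diarrhoea",
    "peripheral_neuropathy",
    "palmar_plantar_erythrodysesthesia",
    "leucopenia",
)


class ConfigurationError(ValueError):
    """A cost category cannot be resolved from the supplied configuration."""


@dataclass(frozen=True)
class GlobalAssumptions:
    """Cohort-level assumptions shared by every stage."""

    bsa_m2: float = 1.73
    rmb_per_usd: float = 7.238  # provenance of the currency conversion only
    annual_discount: float = 0.05
    wtp_per_qaly: float = 35_519.39

    def __post_init__(self) -> None:
        if min(self.bsa_m2, self.rmb_per_usd, self.wtp_per_qaly) <= 0:
            raise ValueError("assumptions must be positive")
        if self.annual_discount < 0:
            raise ValueError("discount rate must be non-negative")


@dataclass(frozen=True)
class PackSpec:
    """Dispensing rule for one drug.

    ``pack_content_mg`` is the dispensable unit (vial or tablet) in mg;
    ``units_per_pack`` groups units into the priced pack.  ``rounding_level``
    says at which granularity the mg dose is rounded to whole units
    (per administration, per day, or per cycle) and ``rounding_mode`` how
    ("nearest" or "up"); packs per cycle are then rounded per
    ``pack_rounding``.
    """

    drug: str
    pack_content_mg: float
    price_usd_per_pack: float
    units_per_pack: int = 1
    rounding_level: str = "administration"
    rounding_mode: str = "nearest"
    pack_rounding: str = "up"

    def __post_init__(self) -> None:
        if self.pack_content_mg <= 0:
            raise ValueError("pack content must be positive")
        if self.price_usd_per_pack < 0:
            raise ValueError("pack price must be non-negative")
        if self.rounding_level not in ("administration", "day", "cycle"):
            raise ValueError(f"unknown rounding level {self.rounding_level!r}")
        if self.rounding_mode not in ("nearest", "up"):
            raise ValueError(f"unknown rounding mode {self.rounding_mode!r}")
        if self.pack_rounding not in ("nearest", "up"):
            raise ValueError(f"unknown pack rounding {self.pack_rounding!r}")


@dataclass(frozen=True)
class DrugSchedule:
    """Dosing of one drug within a 21-day cycle."""

    drug: str
    dose_per_m2: float
    administrations_per_day: int
    days_per_cycle: int
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose_per_m2 <= 0:
            raise ValueError("dose must be positive")
        if self.days_per_cycle > 21:
            raise ValueError("days per cycle cannot exceed the 21-day cycle")


@dataclass(frozen=True)
class Regimen:
    drugs: tuple[DrugSchedule, ...]


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in USD (2023 price level)."""

    cimetidine: float = 3.38
    diphenhydramine: float = 4.69
    dexamethasone: float = 0.99
    hospitalization: float = 17.27
    infusion: float = 1.64
    ecg: float = 3.73
    hematology: float = 3.45
    serum_chemistry: float = 24.87
    urinalysis: float = 4.14
    ct: float = 296.96
    ae_costs: dict = field(
        default_factory=lambda: {
            "anemia": 275.30,
            "neutropenia": 483.54,
            "diarrhoea": 10.36,
            "peripheral_neuropathy": 621.69,
            "palmar_plantar_erythrodysesthesia": 93.25,
            "leucopenia": 483.54,
        }
    )
    end_of_life: float = 1_036.15
    pd_management_per_cycle: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "cimetidine",
            "diphenhydramine",
            "dexamethasone",
            "hospitalization",
            "infusion",
            "ecg",
            "hematology",
            "serum_chemistry",
            "urinalysis",
            "ct",
            "end_of_life",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"unit cost {name} must be non-negative")
        if any(v < 0 for v in self.ae_costs.values()):
            raise ValueError("adverse-event unit costs must be non-negative")


@dataclass(frozen=True)
class AEProfile:
    """Grade >=3 adverse-event incidences for one arm."""

    incidence: dict

    def __post_init__(self) -> None:
        for name, p in self.incidence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"incidence for {name} must lie in [0, 1]")

    @property
    def total_incidence(self) -> float:
        return float(sum(self.incidence.values()))


@dataclass
class CostBreakdown:
    """Discounted per-category arm costs (USD) plus diagnostics."""

    acquisition: float
    administration: float
    monitoring: float
    ae: float
    pd_management: float
    terminal: float
    mechanistic_ae: float = float("nan")
    mechanistic_pd: float = float("nan")

    CATEGORIES = (
        "acquisition",
        "administration",
        "monitoring",
        "ae",
        "pd_management",
        "terminal",
    )

    @property
    def total(self) -> float:
        return float(sum(getattr(self, c) for c in self.CATEGORIES))

    def to_series(self) -> pd.Series:
        data = {c: getattr(self, c) for c in self.CATEGORIES}
        data["total"] = self.total
        return pd.Series(data)


def dose_mg(dose_per_m2: float, assumptions: GlobalAssumptions) -> float:
    """Absolute dose for the reference body surface area."""
    if dose_per_m2 < 0:
        raise ValueError("dose must be non-negative")
    return dose_per_m2 * assumptions.bsa_m2


def _round_units(units: float, mode: str) -> int:
    if mode == "up":
        return math.ceil(units - 1e-9)
    # round half up, the pharmacy convention for "nearest vial"
    return int(math.floor(units + 0.5))


def packs_needed(mg: float, spec: PackSpec) -> int:
    """Whole dispensable units covering ``mg`` under the pack's rounding mode."""
    if mg < 0:
        raise ValueError("mg must be non-negative")
    return max(_round_units(mg / spec.pack_content_mg, spec.rounding_mode), 0)


def drug_cost_per_cycle(
    regimen: Regimen,
    pack_specs: dict[str, PackSpec],
    assumptions: GlobalAssumptions,
) -> float:
    """Acquisition cost of one treatment cycle under the dispensing rules."""
    total = 0.0
    for sched in regimen.drugs:
        spec = pack_specs.get(sched.drug)
        if spec is None:
            raise ConfigurationError(f"no pack specification for drug {sched.drug!r}")
        per_admin_mg = dose_mg(sched.dose_per_m2, assumptions)
        admins_per_cycle = sched.administrations_per_day * sched.days_per_cycle
        if spec.rounding_level == "administration":
            units = packs_needed(per_admin_mg, spec) * admins_per_cycle
        elif spec.rounding_level == "day":
            daily = per_admin_mg * sched.administrations_per_day
            units = packs_needed(daily, spec) * sched.days_per_cycle
        else:  # cycle
            units = packs_needed(per_admin_mg * admins_per_cycle, spec)
        packs = _round_units(units / spec.units_per_pack, spec.pack_rounding)
        total += packs * spec.price_usd_per_pack
    return total


def admin_cost_per_cycle(
    premedicated_infusion_days: int, unit_costs: UnitCosts
) -> float:
    """Hospitalization + infusion + one premedication set per intravenous day.

    Oral-only regimens have zero administration cost.
    """
    per_day = (
        unit_costs.hospitalization
        + unit_costs.infusion
        + unit_costs.cimetidine
        + unit_costs.diphenhydramine
        + unit_costs.dexamethasone
    )
    return premedicated_infusion_days * per_day


def lab_panel_cost(unit_costs: UnitCosts) -> float:
    return (
        unit_costs.ecg
        + unit_costs.hematology
        + unit_costs.serum_chemistry
        + unit_costs.urinalysis
    )


def monitoring_cost(
    trace: OccupancyTrace,
    unit_costs: UnitCosts,
    annual_discount: float,
    ct_every: int = 2,
    ct_offset: int = 1,
) -> float:
    """Discounted labs every on-treatment cycle plus CT every ``ct_every``-th.

    Both accrue in proportion to progression-free occupancy (monitoring stops
    at progression or death).
    """
    disc = discount_factor(trace.time_months, annual_discount)
    frac = trace.grid.cycle_fractions
    cycles = np.arange(trace.grid.n_cycles)
    panel = lab_panel_cost(unit_costs) * np.sum(trace.pf * frac * disc)
    ct_mask = (cycles % ct_every) == ct_offset
    ct = unit_costs.ct * np.sum(trace.pf[ct_mask] * frac[ct_mask] * disc[ct_mask])
    return float(panel + ct)


def ae_expected_cost(profile: AEProfile, unit_costs: UnitCosts) -> float:
    """Mechanistic expected AE cost: sum of incidence x unit cost, cycle 0."""
    return float(
        sum(p * unit_costs.ae_costs.get(name, 0.0) for name, p in profile.incidence.items())
    )


def terminal_cost(
    trace: OccupancyTrace, unit_costs: UnitCosts, annual_discount: float
) -> float:
    """End-of-life cost weighted by the per-cycle death increment, discounted."""
    disc = discount_factor(trace.time_months, annual_discount)
    return float(unit_costs.end_of_life * np.sum(trace.new_deaths * disc))


def pd_management_cost(
    trace: OccupancyTrace,
    unit_costs: UnitCosts,
    annual_discount: float,
    override: float | None = None,
) -> float:
    """Post-progression consultation costs.

    Either a per-cycle rate applied to progressed-state occupancy or, when an
    override total is configured, that total directly.
    """
    if override is not None:
        return float(override)
    rate = unit_costs.pd_management_per_cycle
    if rate is None:
        raise ConfigurationError(
            "pd_management_per_cycle is unset and no override total was given"
        )
    disc = discount_factor(trace.time_months, annual_discount)
    frac = trace.grid.cycle_fractions
    return float(rate * np.sum(trace.pd * frac * disc))


def total_costs(
    trace: OccupancyTrace,
    regimen: Regimen,
    pack_specs: dict[str, PackSpec],
    premedicated_infusion_days: int,
    ae_profile: AEProfile,
    unit_costs: UnitCosts,
    assumptions: GlobalAssumptions,
    ae_override: float | None = None,
    pd_override: float | None = None,
) -> CostBreakdown:
    """All discounted cost categories for one arm."""
    r = assumptions.annual_discount
    disc = discount_factor(trace.time_months, r)
    frac = trace.grid.cycle_fractions
    pf_weight = float(np.sum(trace.pf * frac * disc))

    acquisition = drug_cost_per_cycle(regimen, pack_specs, assumptions) * pf_weight
    administration = admin_cost_per_cycle(premedicated_infusion_days, unit_costs) * pf_weight
    monitoring = monitoring_cost(trace, unit_costs, r)
    mech_ae = ae_expected_cost(ae_profile, unit_costs)
    ae = float(ae_override) if ae_override is not None else mech_ae
    try:
        mech_pd = pd_management_cost(trace, unit_costs, r, override=None)
    except ConfigurationError:
        mech_pd = float("nan")
    pd_cost = pd_management_cost(trace, unit_costs, r, override=pd_override)
    terminal = terminal_cost(trace, unit_costs, r)
    return CostBreakdown(
        acquisition=acquisition,
        administration=administration,
        monitoring=monitoring,
        ae=ae,
        pd_management=pd_cost,
        terminal=terminal,
        mechanistic_ae=mech_ae,
        mechanistic_pd=mech_pd,
    )
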
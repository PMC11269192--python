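"""Analysis configuration: parameter table, arm structure, validation, I/O.

The model is driven by a flat table of named parameters (base value, bounds,
sampling distribution, category) mirroring the published input table, plus
structural settings: the cycle grid, the two arm definitions (curves,
regimens, dispensing rules, adverse-event profiles) and the subgroup hazard
ratios.  A canonical base-case fixture ships with the package so every stage
runs offline; ``load_config`` accepts a user JSON file in the same layout.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .costing import (
    AE_NAMES,
    AEProfile,
    DrugSchedule,
    GlobalAssumptions,
    PackSpec,
    Regimen,
    UnitCosts,
)
from .outcomes import UtilitySet
from .psm import ArmModel, CycleGrid
from .survival import ParametricSurvival

__all__ = [
    "Parameter",
    "AnalysisConfig",
    "ValidationError",
    "default_config",
    "load_config",
    "write_config",
    "default_subgroups",
]

_STRUCT_KEYS = {
    "grid",
    "assumptions",
    "treated",
    "comparator",
    "use_category_overrides",
    "arms",
    "pack_specs",
    "parameters",
}


class ValidationError(ValueError):
    """A configuration field violates a model invariant; names the field."""


@dataclass(frozen=True)
class Parameter:
    """One model input: base value, sensitivity bounds, sampling family."""

    name: str
    value: float
    lower: float | None
    upper: float | None
    distribution: str
    category: str

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValidationError(f"{self.name}: lower bound exceeds upper bound")


def _validate_parameter(p: Parameter) -> None:
    if p.category in ("cost", "override") and p.value < 0:
        raise ValidationError(f"{p.name}: costs must be non-negative, got {p.value}")
    if p.category == "incidence" and not 0 <= p.value <= 1:
        raise ValidationError(f"{p.name}: incidence must lie in [0, 1], got {p.value}")
    if p.category == "utility" and p.name != "utility.ae_disutility":
        if not 0 <= p.value <= 1.02:
            raise ValidationError(
                f"{p.name}: utilities must lie in [0, 1.02], got {p.value}"
            )
    if p.name == "utility.ae_disutility" and p.value > 0:
        raise ValidationError(f"{p.name}: disutility must be non-positive, got {p.value}")
    if p.category == "discount" and not 0 <= p.value <= 0.08 + 1e-9:
        raise ValidationError(
            f"{p.name}: discount rate must lie in [0, 0.08], got {p.value}"
        )
    if p.category in ("curve", "curve_shape") and p.value <= 0:
        raise ValidationError(f"{p.name}: curve parameters must be positive")


class AnalysisConfig:
    """Validated, immutable-by-convention bundle of all model inputs."""

    def __init__(
        self,
        params: dict[str, Parameter],
        grid: CycleGrid,
        assumptions_base: dict,
        arms: dict,
        pack_specs: dict,
        treated: str,
        comparator: str,
        use_category_overrides: bool = True,
        subgroups: pd.DataFrame | None = None,
    ) -> None:
        self.params = dict(params)
        self.grid = grid
        self._assumptions_base = dict(assumptions_base)
        self._arms = arms
        self._pack_specs = pack_specs
        self.treated = treated
        self.comparator = comparator
        self.use_category_overrides = bool(use_category_overrides)
        self.subgroups = subgroups if subgroups is not None else default_subgroups()
        for p in self.params.values():
            _validate_parameter(p)
        for label in (treated, comparator):
            if label not in arms:
                raise ValidationError(f"arm {label!r} is not defined")
        # fail fast if anything structural is unresolvable
        for label in arms:
            self.arm_model(label)
            self.regimen(label)
            self.ae_profile(label)
        self.pack_specs()

    # -- parameter access ---------------------------------------------------

    def __getitem__(self, name: str) -> float:
        return self.params[name].value

    def with_values(self, values: dict[str, float]) -> "AnalysisConfig":
        """A copy of the config with the named parameter values replaced."""
        params = dict(self.params)
        for name, value in values.items():
            if name not in params:
                raise KeyError(f"unknown parameter {name!r}")
            p = params[name]
            params[name] = Parameter(p.name, float(value), p.lower, p.upper, p.distribution, p.category)
        cfg = object.__new__(AnalysisConfig)
        cfg.__dict__.update(self.__dict__)
        cfg.params = params
        return cfg

    def parameter_table(self) -> pd.DataFrame:
        return pd.DataFrame([dict(vars(p)) for p in self.params.values()])

    # -- derived model objects ----------------------------------------------

    @property
    def assumptions(self) -> GlobalAssumptions:
        return GlobalAssumptions(
            bsa_m2=self._assumptions_base.get("bsa_m2", 1.73),
            rmb_per_usd=self._assumptions_base.get("rmb_per_usd", 7.238),
            annual_discount=self["discount.annual"],
            wtp_per_qaly=self._assumptions_base.get("wtp_per_qaly", 35_519.39),
        )

    def curve(self, arm: str, endpoint: str) -> ParametricSurvival:
        scale = self.params[f"curve.{arm}.{endpoint}.scale"]
        shape = self.params[f"curve.{arm}.{endpoint}.shape"]
        return ParametricSurvival(scale.distribution, scale.value, shape.value)

    def arm_model(self, arm: str) -> ArmModel:
        return ArmModel(arm, self.curve(arm, "os"), self.curve(arm, "pfs"))

    def regimen(self, arm: str) -> Regimen:
        return Regimen(
            tuple(DrugSchedule(**d) for d in self._arms[arm]["regimen"])
        )

    def premedicated_infusion_days(self, arm: str) -> int:
        return int(self._arms[arm].get("premedicated_infusion_days", 0))

    def pack_specs(self) -> dict[str, PackSpec]:
        specs = {}
        for drug, raw in self._pack_specs.items():
            raw = dict(raw)
            price_param = raw.pop("price_param")
            specs[drug] = PackSpec(
                drug=drug, price_usd_per_pack=self[price_param], **raw
            )
        return specs

    def unit_costs(self) -> UnitCosts:
        return UnitCosts(
            cimetidine=self["cost.cimetidine"],
            diphenhydramine=self["cost.diphenhydramine"],
            dexamethasone=self["cost.dexamethasone"],
            hospitalization=self["cost.hospitalization"],
            infusion=self["cost.infusion"],
            ecg=self["cost.ecg"],
            hematology=self["cost.hematology"],
            serum_chemistry=self["cost.serum_chemistry"],
            urinalysis=self["cost.urinalysis"],
            ct=self["cost.ct"],
            ae_costs={name: self[f"cost.ae.{name}"] for name in AE_NAMES},
            end_of_life=self["cost.end_of_life"],
            pd_management_per_cycle=None,
        )

    def ae_profile(self, arm: str) -> AEProfile:
        return AEProfile({name: self[f"inc.{arm}.{name}"] for name in AE_NAMES})

    def overrides(self, arm: str) -> tuple[float | None, float | None]:
        """(AE category total, PD category total) or (None, None)."""
        if not self.use_category_overrides:
            return None, None
        return self[f"cost.ae_total.{arm}"], self[f"cost.pd_total.{arm}"]

    def utilities(self) -> UtilitySet:
        # independent PSA draws can invert the ordering; progressed-state
        # utility is capped at the progression-free one
        u_pf = self["utility.pf"]
        return UtilitySet(
            u_pf=u_pf,
            u_pd=min(self["utility.pd"], u_pf),
            ae_disutility=self["utility.ae_disutility"],
        )

    @property
    def arm_labels(self) -> tuple[str, str]:
        return self.treated, self.comparator

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid": {
                "cycle_length_days": self.grid.cycle_length_days,
                "horizon_years": self.grid.horizon_years,
                "days_per_month": self.grid.days_per_month,
            },
            "assumptions": dict(self._assumptions_base),
            "treated": self.treated,
            "comparator": self.comparator,
            "use_category_overrides": self.use_category_overrides,
            "arms": copy.deepcopy(self._arms),
            "pack_specs": copy.deepcopy(self._pack_specs),
            "parameters": [dict(vars(p)) for p in self.params.values()],
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _config_from_dict(raw: dict, subgroups: pd.DataFrame | None = None) -> AnalysisConfig:
    unknown = set(raw) - _STRUCT_KEYS
    if unknown:
        raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
    missing = {"arms", "pack_specs", "parameters"} - set(raw)
    if missing:
        raise ValidationError(f"missing required configuration keys: {sorted(missing)}")
    params = {}
    for entry in raw["parameters"]:
        p = Parameter(**entry)
        if p.name in params:
            raise ValidationError(f"parameter {p.name!r} defined more than once")
        params[p.name] = p
    grid = CycleGrid(**raw.get("grid", {}))
    return AnalysisConfig(
        params=params,
        grid=grid,
        assumptions_base=raw.get("assumptions", {}),
        arms=raw["arms"],
        pack_specs=raw["pack_specs"],
        treated=raw.get("treated", "utidelone_capecitabine"),
        comparator=raw.get("comparator", "capecitabine"),
        use_category_overrides=raw.get("use_category_overrides", True),
        subgroups=subgroups,
    )


def default_config() -> AnalysisConfig:
    """The packaged base-case configuration (published input table)."""
    raw = json.loads(
        resources.files("psmcea.data").joinpath("base_case.json").read_text()
    )
    return _config_from_dict(raw)


def default_subgroups() -> pd.DataFrame:
    """Published subgroup OS hazard ratios with 95% CIs."""
    with resources.files("psmcea.data").joinpath("subgroups.csv").open() as fh:
        return pd.read_csv(fh)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and fully validate a configuration JSON file."""
    raw = json.loads(Path(path).read_text())
    return _config_from_dict(raw)


def write_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.to_dict(), indent=2))
    return path
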
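"""Base-case comparison, one-way sensitivity analysis, and Monte Carlo PSA.

The incremental cost-effectiveness ratio (ICER) is the incremental cost per
quality-adjusted life year of the treated arm over the comparator.  One-way
deterministic sensitivity analysis (DSA) moves each parameter to its bounds
(default +/-20%, discount 0-8%, survival scales +/-20%) and re-evaluates the
ICER; the tornado ordering ranks parameters by the induced ICER span.

The probabilistic sensitivity analysis (PSA) redraws all cost parameters from
gamma and all utility/probability parameters from beta distributions, with
moments matched so the mean equals the base value and the standard deviation
is (upper - lower) / (2 * 1.96), i.e. the published range read as a 95%
interval.  Survival-curve parameters stay at base values (no sampling bounds
are published for them).  Each parameter draws from its own child stream of
the master seed, so adding a parameter does not reshuffle the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, Parameter
from .costing import CostBreakdown, total_costs
from .outcomes import qaly
from .psm import OccupancyTrace, build_trace

__all__ = [
    "CEResult",
    "ArmOutcome",
    "PsaResult",
    "compute_icer",
    "evaluate_arm",
    "evaluate_base_case",
    "run_dsa",
    "sample_distribution",
    "run_psa",
    "ce_probability",
    "ceac",
]


@dataclass
class ArmOutcome:
    label: str
    costs: CostBreakdown
    qalys: float


@dataclass
class CEResult:
    """Incremental comparison of two strategies."""

    cost_treated: float
    qaly_treated: float
    cost_comparator: float
    qaly_comparator: float

    @property
    def delta_cost(self) -> float:
        return self.cost_treated - self.cost_comparator

    @property
    def delta_qaly(self) -> float:
        return self.qaly_treated - self.qaly_comparator

    @property
    def dominance(self) -> str | None:
        """'dominant' (cheaper, more effective), 'dominated', or 'undefined'."""
        if self.delta_qaly == 0:
            return "undefined"
        if self.delta_cost < 0 and self.delta_qaly > 0:
            return "dominant"
        if self.delta_cost > 0 and self.delta_qaly < 0:
            return "dominated"
        return None

    @property
    def icer(self) -> float:
        """Incremental cost per QALY; NaN when a dominance label applies."""
        if self.dominance is not None:
            return float("nan")
        return self.delta_cost / self.delta_qaly

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "cost_treated": self.cost_treated,
                "qaly_treated": self.qaly_treated,
                "cost_comparator": self.cost_comparator,
                "qaly_comparator": self.qaly_comparator,
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "icer": self.icer,
                "dominance": self.dominance,
            }
        )


def compute_icer(
    cost_treated: float,
    qaly_treated: float,
    cost_comparator: float,
    qaly_comparator: float,
) -> CEResult:
    return CEResult(cost_treated, qaly_treated, cost_comparator, qaly_comparator)


def evaluate_arm(
    config: AnalysisConfig, label: str, trace: OccupancyTrace | None = None
) -> ArmOutcome:
    """Costs and QALYs for one arm; the trace may be passed in precomputed."""
    if trace is None:
        trace = build_trace(config.arm_model(label), config.grid)
    ae_override, pd_override = config.overrides(label)
    profile = config.ae_profile(label)
    costs = total_costs(
        trace=trace,
        regimen=config.regimen(label),
        pack_specs=config.pack_specs(),
        premedicated_infusion_days=config.premedicated_infusion_days(label),
        ae_profile=profile,
        unit_costs=config.unit_costs(),
        assumptions=config.assumptions,
        ae_override=ae_override,
        pd_override=pd_override,
    )
    q = qaly(
        trace,
        config.utilities(),
        total_ae_incidence=profile.total_incidence,
        annual_discount=config["discount.annual"],
    )
    return ArmOutcome(label, costs, q)


def evaluate_base_case(
    config: AnalysisConfig,
    traces: dict[str, OccupancyTrace] | None = None,
) -> tuple[CEResult, dict[str, ArmOutcome]]:
    traces = traces or {}
    outcomes = {
        label: evaluate_arm(config, label, traces.get(label))
        for label in config.arm_labels
    }
    t, c = outcomes[config.treated], outcomes[config.comparator]
    return compute_icer(t.costs.total, t.qalys, c.costs.total, c.qalys), outcomes


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------


def _dsa_bounds(p: Parameter, rel: float) -> tuple[float, float] | None:
    if p.category == "discount":
        return 0.0, 0.08
    if p.category == "curve_shape":
        return None  # shapes held fixed; scale rows carry the survival rows
    if p.category == "curve":
        return p.value * (1 - rel), p.value * (1 + rel)
    if p.lower is not None and p.upper is not None:
        return p.lower, p.upper
    return p.value * (1 - rel), p.value * (1 + rel)


def run_dsa(config: AnalysisConfig, rel: float = 0.2) -> pd.DataFrame:
    """One-way DSA over every parameter; rows sorted by ICER span (tornado).

    The base case is restored between rows.  Rows where a bound makes the
    comparison dominant/dominated carry NaN at that bound; the span uses the
    finite endpoints.
    """
    base, _ = evaluate_base_case(config)
    rows = []
    for name, p in config.params.items():
        bounds = _dsa_bounds(p, rel)
        if bounds is None:
            continue
        icers = []
        for bound in bounds:
            res, _ = evaluate_base_case(config.with_values({name: bound}))
            icers.append(res.icer)
        lo, hi = icers
        finite = [v for v in icers if math.isfinite(v)]
        span = max(finite) - min(finite) if len(finite) == 2 else float("nan")
        rows.append(
            {
                "parameter": name,
                "category": p.category,
                "low_bound": bounds[0],
                "high_bound": bounds[1],
                "icer_low": lo,
                "icer_high": hi,
                "span": span,
            }
        )
    df = pd.DataFrame(rows)
    df["base_icer"] = base.icer
    return (
        df.sort_values("span", ascending=False, na_position="last")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_PSA_CATEGORIES = ("cost", "override", "incidence", "utility", "discount")


def _param_rng(seed: int, name: str) -> np.random.Generator:
    # per-parameter child stream: stable under addition of other parameters
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def sample_distribution(p: Parameter, n: int, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo draws for one parameter (gamma for costs, beta otherwise).

    Moments: mean = base value, SD = (upper - lower) / (2 * 1.96).  Degenerate
    bounds (or none) give a constant draw.  Negative parameters (the AE
    disutility) are sampled on their magnitude and negated.
    """
    if p.lower is None or p.upper is None or p.upper == p.lower:
        return np.full(n, p.value)
    if p.lower > p.upper:
        raise ValueError(f"{p.name}: inconsistent bounds")
    sign = -1.0 if p.value < 0 else 1.0
    mean = abs(p.value)
    sd = (p.upper - p.lower) / (2 * 1.96)
    if sd <= 0 or mean == 0:
        return np.full(n, p.value)
    if p.distribution == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return sign * rng.gamma(shape, scale, size=n)
    if p.distribution == "beta":
        var = sd**2
        nu = mean * (1 - mean) / var - 1.0
        if nu <= 0:  # variance too large for a beta; fall back to the base
            return np.full(n, p.value)
        a, b = mean * nu, (1 - mean) * nu
        return sign * rng.beta(a, b, size=n)
    return np.full(n, p.value)


@dataclass
class PsaResult:
    draws: pd.DataFrame
    ceac: pd.DataFrame
    base: CEResult


def _psa_parameter_draws(config: AnalysisConfig, n: int, seed: int) -> dict[str, np.ndarray]:
    out = {}
    for name, p in config.params.items():
        if p.category in _PSA_CATEGORIES:
            out[name] = sample_distribution(p, n, _param_rng(seed, name))
    return out


def run_psa(
    config: AnalysisConfig,
    n: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PsaResult:
    """Joint Monte Carlo over all sampled parameters, both arms re-evaluated.

    Survival curves are fixed, so state occupancy is computed once and reused;
    costs, utilities and the discount rate vary per draw.
    """
    traces = {
        label: build_trace(config.arm_model(label), config.grid)
        for label in config.arm_labels
    }
    base, _ = evaluate_base_case(config, traces)
    draws = _psa_parameter_draws(config, n, seed)
    names = list(draws)
    records = np.empty((n, 4))
    for i in range(n):
        cfg_i = config.with_values({name: draws[name][i] for name in names})
        res, _ = evaluate_base_case(cfg_i, traces)
        records[i] = (
            res.cost_treated,
            res.qaly_treated,
            res.cost_comparator,
            res.qaly_comparator,
        )
    df = pd.DataFrame(
        records,
        columns=["cost_treated", "qaly_treated", "cost_comparator", "qaly_comparator"],
    )
    df["delta_cost"] = df["cost_treated"] - df["cost_comparator"]
    df["delta_qaly"] = df["qaly_treated"] - df["qaly_comparator"]
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 300_001.0, 5_000.0)
    ceac_df = ceac(df, wtp_grid)
    return PsaResult(draws=df, ceac=ceac_df, base=base)


def ce_probability(draws: pd.DataFrame, wtp: float) -> float:
    """Fraction of draws with positive net monetary benefit at ``wtp``."""
    if len(draws) == 0:
        raise ValueError("no PSA draws supplied")
    nmb = wtp * draws["delta_qaly"].to_numpy() - draws["delta_cost"].to_numpy()
    return float(np.mean(nmb > 0))


def ceac(draws: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    probs = [ce_probability(draws, w) for w in np.asarray(wtp_grid, dtype=float)]
    return pd.DataFrame({"wtp": np.asarray(wtp_grid, dtype=float), "p_cost_effective": probs})
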
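"""Synthetic two-arm trial data with the structure the analysis assumes.

Emulates a 2:1-randomized trial: per-subject overall-survival times drawn
from the arm's OS curve by inverse transform, progression times coupled only
through PFS = min(progression draw, OS time), uniform accrual over a window,
and administrative censoring at a common study cutoff.  A Kaplan-Meier
"digitizer" turns simulated data into curve coordinates with a number-at-risk
row (optionally jittered), so the reconstruction and fitting stages can be
exercised end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .psm import ArmModel
from .reconstruct import DigitizedKM
from .survival import ParametricSurvival, PseudoIPD

__all__ = ["TrialSimConfig", "simulate_ipd", "km_digitize", "recovery_report"]

_DEFAULT_ARMS = (
    ArmModel(
        "utidelone_capecitabine",
        ParametricSurvival("loglogistic", 15.224, 2.826),
        ParametricSurvival("weibull", 0.0345, 1.51337),
    ),
    ArmModel(
        "capecitabine",
        ParametricSurvival("loglogistic", 12.534, 2.933),
        ParametricSurvival("weibull", 0.072, 1.3696),
    ),
)


@dataclass(frozen=True)
class TrialSimConfig:
    """Generating model of the synthetic trial.

    Defaults: 300/150 subjects (2:1 allocation), the published base-case
    curves, 12-month uniform accrual, study cutoff 60 months after the first
    enrolment.
    """

    n_treated: int = 300
    n_comparator: int = 150
    arms: tuple[ArmModel, ArmModel] = _DEFAULT_ARMS
    accrual_months: float = 12.0
    cutoff_months: float = 60.0

    def __post_init__(self) -> None:
        if min(self.n_treated, self.n_comparator) <= 0:
            raise ValueError("arm sizes must be positive")
        if self.accrual_months < 0:
            raise ValueError("accrual window must be non-negative")
        if self.cutoff_months <= self.accrual_months:
            raise ValueError(
                "study cutoff must exceed the accrual window "
                "(every subject needs positive follow-up)"
            )

    @property
    def allocation_ratio(self) -> float:
        return self.n_treated / self.n_comparator


def simulate_ipd(
    config: TrialSimConfig, seed: int = 0
) -> dict[tuple[str, str], PseudoIPD]:
    """Simulate per-subject OS and PFS records for both arms.

    Returns a mapping ``(arm_label, endpoint)`` -> :class:`PseudoIPD` with
    endpoint in ``{"os", "pfs"}``.  PFS <= OS holds per subject by
    construction.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], PseudoIPD] = {}
    sizes = {config.arms[0].label: config.n_treated, config.arms[1].label: config.n_comparator}
    for arm in config.arms:
        n = sizes[arm.label]
        entry = rng.uniform(0.0, config.accrual_months, size=n)
        censor = config.cutoff_months - entry
        os_true = arm.os_curve.rvs(n, rng)
        pfs_true = np.minimum(arm.pfs_curve.rvs(n, rng), os_true)
        for endpoint, true_t in (("os", os_true), ("pfs", pfs_true)):
            event = (true_t <= censor).astype(int)
            time = np.minimum(true_t, censor)
            time = np.maximum(time, 1e-9)
            out[(arm.label, endpoint)] = PseudoIPD(time, event, arm=arm.label)
    return out


def km_digitize(
    ipd: PseudoIPD,
    grid: np.ndarray | None = None,
    at_risk_times: np.ndarray | None = None,
    jitter: float = 0.0,
    seed: int = 0,
) -> DigitizedKM:
    """Product-limit estimate sampled on a grid, with an at-risk row.

    ``jitter`` adds zero-mean Gaussian noise to the sampled survival values
    (emulating digitization error) before monotonicity is restored.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    t_max = float(ipd.time.max())
    if grid is None:
        grid = np.linspace(0.0, t_max, 101)
    grid = np.asarray(grid, dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    if jitter > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.normal(0.0, jitter, size=surv.size)
        surv[0] = 1.0
        surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
    if at_risk_times is None:
        at_risk_times = grid[:: max(len(grid) // 8, 1)]
    at_risk_times = np.asarray(at_risk_times, dtype=float)
    n_risk = np.array([(ipd.time >= t).sum() for t in at_risk_times], dtype=int)
    return DigitizedKM(grid, surv, at_risk_times, n_risk, arm=ipd.arm)


def recovery_report(
    true: ParametricSurvival,
    fitted: ParametricSurvival,
    scale_tol: float = 0.10,
    shape_tol: float = 0.10,
    median_tol: float = 0.05,
) -> dict:
    """Relative parameter/median errors of a fit against the generating curve.

    A family mismatch is reported (parameters incomparable), not raised.
    """
    report = {
        "true_family": true.family,
        "fitted_family": fitted.family,
        "family_match": true.family == fitted.family,
        "median_true": true.median(),
        "median_fitted": fitted.median(),
    }
    report["median_rel_err"] = abs(report["median_fitted"] - report["median_true"]) / report[
        "median_true"
    ]
    report["median_ok"] = report["median_rel_err"] <= median_tol
    if report["family_match"]:
        report["scale_rel_err"] = abs(fitted.scale - true.scale) / true.scale
        report["shape_rel_err"] = abs(fitted.shape - true.shape) / true.shape
        report["scale_ok"] = report["scale_rel_err"] <= scale_tol
        report["shape_ok"] = report["shape_rel_err"] <= shape_tol
        report["passed"] = bool(
            report["scale_ok"] and report["shape_ok"] and report["median_ok"]
        )
    else:
        report["scale_rel_err"] = report["shape_rel_err"] = float("nan")
        report["passed"] = False
    return report
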
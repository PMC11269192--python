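"""Parametric survival curves: representation, evaluation, fitting, selection.

Six right-skewed lifetime families are supported, each reduced to a
``(scale, shape)`` pair with time measured in months.  The parameterizations
are chosen so that the published model inputs can be used verbatim:

========== =============================================== =====================
family     survival function S(t)                          notes
========== =============================================== =====================
exponential  exp(-scale * t)                               scale = hazard rate
weibull      exp(-scale * t**shape)                        rate-like scale
loglogistic  1 / (1 + (t / scale)**shape)                  scale = median
lognormal    1 - Phi((ln t - ln scale) / shape)            scale = median
gamma        1 - GammaCDF(t; shape, scale)                 scale in months
gompertz     exp(-(scale/shape) * (exp(shape*t) - 1))      scale = baseline rate
========== =============================================== =====================

Maximum-likelihood fitting under right censoring is done on the log-parameter
scale with moment-based multi-starts; densities and quantiles come from
``scipy.stats`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "PseudoIPD",
    "FitDiagnostics",
    "FitError",
    "survival_at",
    "median_survival",
    "fit_parametric",
    "fit_all_families",
    "select_best",
    "selection_report",
]

#: Families in the order the source analysis lists them; used for tie-breaks.
FAMILIES = ("weibull", "lognormal", "loglogistic", "gompertz", "gamma", "exponential")


class FitError(RuntimeError):
    """Raised when maximum-likelihood fitting fails for a family."""


def _frozen_dist(family: str, scale: float, shape: float):
    """Map (family, scale, shape) onto a frozen scipy.stats distribution."""
    if family == "exponential":
        return stats.expon(scale=1.0 / scale)
    if family == "weibull":
        # S(t) = exp(-scale * t**shape)  ->  weibull_min with scale**(-1/shape)
        return stats.weibull_min(c=shape, scale=scale ** (-1.0 / shape))
    if family == "loglogistic":
        return stats.fisk(c=shape, scale=scale)
    if family == "lognormal":
        return stats.lognorm(s=shape, scale=scale)
    if family == "gamma":
        return stats.gamma(a=shape, scale=scale)
    if family == "gompertz":
        return stats.gompertz(c=scale / shape, scale=1.0 / shape)
    raise ValueError(f"unknown survival family: {family!r}")


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival curve with positive scale and shape.

    ``shape`` is ignored by the exponential family (conventionally 1).
    """

    family: str
    scale: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown survival family: {self.family!r}; expected one of {FAMILIES}"
            )
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError(f"shape must be positive and finite, got {self.shape}")

    @property
    def dist(self):
        return _frozen_dist(self.family, self.scale, self.shape)

    def sf(self, t):
        """Survival probability S(t); vectorized; t in months, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be non-negative")
        return self.dist.sf(t)

    def median(self) -> float:
        return float(self.dist.median())

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.dist.rvs(size=size, random_state=rng)

    @property
    def n_params(self) -> int:
        return 1 if self.family == "exponential" else 2


def survival_at(model: ParametricSurvival, t) -> float | np.ndarray:
    """Evaluate S(t) for a model; scalar in, scalar out."""
    out = model.sf(t)
    return float(out) if np.ndim(t) == 0 else out


def median_survival(model: ParametricSurvival) -> float:
    """Time t* with S(t*) = 0.5 (closed form via the distribution's quantile)."""
    return model.median()


# ---------------------------------------------------------------------------
# Pseudo individual-patient data and fitting
# ---------------------------------------------------------------------------


@dataclass
class PseudoIPD:
    """Per-subject right-censored survival records.

    ``time`` in months (> 0), ``event`` 1 for an observed event and 0 for a
    censored record, and an arm label.
    """

    time: np.ndarray
    event: np.ndarray
    arm: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have matching shapes")
        if np.any(self.time <= 0):
            raise ValueError("all survival times must be positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.time, "event": self.event, "arm": self.arm}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, arm: str | None = None) -> "PseudoIPD":
        sub = df if arm is None else df[df["arm"] == arm]
        label = arm if arm is not None else (sub["arm"].iloc[0] if "arm" in sub else "")
        return cls(sub["time_months"].to_numpy(), sub["event"].to_numpy(), str(label))


@dataclass(frozen=True)
class FitDiagnostics:
    """Log-likelihood and information criteria of one maximum-likelihood fit."""

    loglik: float
    n: int
    k: int
    family: str = ""
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.loglik


def _neg_loglik(theta: np.ndarray, family: str, time, event) -> float:
    scale, shape = math.exp(theta[0]), math.exp(theta[1])
    try:
        dist = _frozen_dist(family, scale, shape)
        ll = np.where(event == 1, dist.logpdf(time), dist.logsf(time))
    except (ValueError, FloatingPointError, OverflowError):
        return np.inf
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(ll.sum())


def _starting_points(family: str, time: np.ndarray, event: np.ndarray):
    """Moment-based initial values, several per family for multi-start."""
    t_ev = time[event == 1]
    rate = max(event.sum(), 1) / time.sum()  # exponential MLE
    med = float(np.median(t_ev))
    if family == "exponential":
        return [(rate, 1.0)]
    if family == "weibull":
        # scale from the median given a trial shape: scale = ln2 / med**shape
        return [(math.log(2.0) / med**g, g) for g in (0.8, 1.0, 1.5, 2.5)]
    if family == "loglogistic":
        return [(med, g) for g in (0.8, 1.5, 3.0)]
    if family == "lognormal":
        mu = float(np.mean(np.log(t_ev)))
        sd = float(np.std(np.log(t_ev))) or 1.0
        return [(math.exp(mu), sd), (med, 1.0)]
    if family == "gamma":
        m, v = float(np.mean(t_ev)), float(np.var(t_ev)) or 1.0
        return [(v / m, m * m / v), (m, 1.0)]
    if family == "gompertz":
        return [(rate, g) for g in (0.02, 0.1, 0.5)]
    raise ValueError(family)


def fit_parametric(
    ipd: PseudoIPD, family: str, tol: float = 1e-8
) -> tuple[ParametricSurvival, FitDiagnostics]:
    """Maximum-likelihood fit of one family to right-censored data.

    Raises :class:`FitError` on fewer than two events or non-convergence.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family: {family!r}")
    time, event = ipd.time, ipd.event
    if event.sum() < 2:
        raise FitError(f"cannot fit {family}: need at least 2 events, got {event.sum()}")

    best = None
    with np.errstate(all="ignore"):
        for scale0, shape0 in _starting_points(family, time, event):
            x0 = np.array([math.log(scale0), math.log(shape0)])
            if family == "exponential":
                # one free parameter; shape pinned at 1
                res = optimize.minimize(
                    lambda th: _neg_loglik(np.array([th[0], 0.0]), family, time, event),
                    x0[:1],
                    method="Nelder-Mead",
                    options={"xatol": tol, "fatol": tol, "maxiter": 2000},
                )
                res.x = np.array([res.x[0], 0.0])
            else:
                res = optimize.minimize(
                    _neg_loglik,
                    x0,
                    args=(family, time, event),
                    method="Nelder-Mead",
                    options={"xatol": tol, "fatol": tol, "maxiter": 5000},
                )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"maximum-likelihood fit did not converge for family {family!r}")

    scale, shape = math.exp(best.x[0]), math.exp(best.x[1])
    model = ParametricSurvival(family, scale, shape)
    diag = FitDiagnostics(
        loglik=-float(best.fun),
        n=len(ipd),
        k=model.n_params,
        family=family,
        converged=bool(best.success),
    )
    return model, diag


def fit_all_families(
    ipd: PseudoIPD, families: Sequence[str] = FAMILIES
) -> list[tuple[ParametricSurvival, FitDiagnostics]]:
    """Fit every requested family, skipping any that fail to converge."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_parametric(ipd, fam))
        except FitError:
            continue
    if not fits:
        raise FitError("no family could be fitted to the data")
    return fits


def _family_rank(family: str) -> int:
    return FAMILIES.index(family)


def select_best(
    fits: Iterable[tuple[ParametricSurvival, FitDiagnostics]]
) -> ParametricSurvival:
    """Pick the fit with minimum AIC; ties broken by BIC, then family order."""
    fits = list(fits)
    if not fits:
        raise ValueError("select_best requires at least one candidate fit")
    best = min(fits, key=lambda md: (md[1].aic, md[1].bic, _family_rank(md[0].family)))
    return best[0]


def selection_report(
    fits: Iterable[tuple[ParametricSurvival, FitDiagnostics]]
) -> pd.DataFrame:
    """All candidates with their AIC/BIC, sorted as ``select_best`` ranks them."""
    rows = [
        {
            "family": m.family,
            "scale": m.scale,
            "shape": m.shape,
            "loglik": d.loglik,
            "aic": d.aic,
            "bic": d.bic,
            "n": d.n,
            "k": d.k,
        }
        for m, d in fits
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["aic", "bic"], kind="stable").reset_index(drop=True)
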
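"""Parametric survival calibration for the Markov transition model.

Candidate accelerated-failure-time (AFT) distributions are fitted to
right-censored time-to-event data, compared by AIC/BIC, and the winning
Weibull (or exponential) fit is converted into the rate/shape pair
``(lambda, gamma)`` that parameterises the per-cycle transition
probabilities of the cohort model.

Parameterisation
----------------
Throughout this package the Weibull survival function is

    S(t) = exp(-lambda * t**gamma),      lambda > 0, gamma > 0,

with time in years. The AFT convention used for the intercept/scale pair is

    S(t) = exp(-(t / exp(intercept))**(1 / scale)),

so that ``lambda = exp(-intercept / scale)`` (equivalently
``1 / exp(intercept)**(1/scale)``) and ``gamma = 1 / scale``. Other AFT
conventions exist (e.g. on the log-hazard scale); all conversions in this
module assume the one above, which is the convention of R's ``survreg`` and
of lifelines' univariate fitters after the change of variables noted in
:func:`fit_parametric`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WeibullParams",
    "AFTFit",
    "FitSelection",
    "DISTRIBUTIONS",
    "fit_parametric",
    "select_best",
    "aft_to_weibull",
    "transition_probability",
    "apply_hazard_ratio",
    "calibrate",
    "calibration_report",
]

#: Canonical ordering; also the tie-break order in :func:`select_best`.
DISTRIBUTIONS = ("weibull", "exponential", "lognormal", "loglogistic", "logistic")

#: Distributions whose AFT fit can be converted to a Weibull (lambda, gamma).
_CONVERTIBLE = frozenset({"weibull", "exponential"})


@dataclass(frozen=True)
class WeibullParams:
    """Rate/shape pair of one cause-specific baseline curve.

    ``lam`` is the rate-scale parameter (units 1/year**gamma), ``gamma`` the
    dimensionless shape; ``gamma == 1`` reduces to the exponential.
    """

    lam: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"lambda must be a positive finite number, got {self.lam}")
        if not (self.gamma > 0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be a positive finite number, got {self.gamma}")

    def survival(self, t):
        """S(t) = exp(-lambda * t**gamma), vectorised over ``t``."""
        t = np.asarray(t, dtype=float)
        return np.exp(-self.lam * t**self.gamma)


@dataclass(frozen=True)
class AFTFit:
    """One maximum-likelihood AFT fit with its information criteria."""

    distribution: str
    intercept: float
    scale: float
    loglik: float
    n_params: int
    n_obs: int
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "aic", 2 * self.n_params - 2 * self.loglik)
        object.__setattr__(self, "bic", self.n_params * math.log(self.n_obs) - 2 * self.loglik)

    def to_weibull(self) -> WeibullParams:
        """Convert to (lambda, gamma); only Weibull/exponential fits convert."""
        if self.distribution not in _CONVERTIBLE:
            raise ValueError(
                f"{self.distribution!r} fits do not define a Weibull (lambda, gamma); "
                "only 'weibull' and 'exponential' convert"
            )
        return aft_to_weibull(self.intercept, self.scale)


@dataclass(frozen=True)
class FitSelection:
    """Result of model selection over a set of candidate AFT fits."""

    fits: tuple[AFTFit, ...]
    selected: AFTFit
    criterion: str


def aft_to_weibull(intercept: float, scale: float) -> WeibullParams:
    """Convert an AFT intercept/scale pair to Weibull ``(lambda, gamma)``.

    lambda = 1 / exp(intercept)**(1/scale) = exp(-intercept/scale);
    gamma = 1 / scale.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return WeibullParams(lam=math.exp(-intercept / scale), gamma=1.0 / scale)


def transition_probability(params: WeibullParams, cycle) -> float | np.ndarray:
    """Per-cycle event probability given event-free entry into ``cycle``.

    Equals ``1 - S(cycle)/S(cycle-1)`` for S(t) = exp(-lambda*t**gamma),
    evaluated as ``1 - exp(lambda*((cycle-1)**gamma - cycle**gamma))``.
    Vectorised over ``cycle``; every cycle must be >= 1.
    """
    c = np.asarray(cycle, dtype=float)
    if np.any(c < 1):
        raise ValueError("cycle must be >= 1")
    p = -np.expm1(params.lam * ((c - 1.0) ** params.gamma - c**params.gamma))
    return float(p) if np.isscalar(cycle) or p.ndim == 0 else p


def apply_hazard_ratio(params: WeibullParams, hr: float) -> WeibullParams:
    """Proportional-hazards adjustment: lambda -> lambda*hr, gamma unchanged."""
    if not (hr > 0 and math.isfinite(hr)):
        raise ValueError(f"hazard ratio must be positive and finite, got {hr}")
    return WeibullParams(lam=params.lam * hr, gamma=params.gamma)


# ---------------------------------------------------------------------------
# Fitting


def _extract_arrays(data: pd.DataFrame, cause: str) -> tuple[np.ndarray, np.ndarray]:
    if cause not in ("dialysis", "death"):
        raise ValueError(f"cause must be 'dialysis' or 'death', got {cause!r}")
    if len(data) == 0:
        raise ValueError("cannot fit on an empty dataset")
    times = np.asarray(data["time"], dtype=float)
    if np.any(times <= 0):
        raise ValueError("all observation times must be positive")
    # Competing events are censored at their observed time (cause-specific fit).
    observed = (data["event"] == cause).to_numpy()
    if not observed.any():
        raise ValueError(f"no {cause!r} events in the data: likelihood is degenerate")
    return times, observed


def _fit_lifelines(times, observed, distribution):
    # Imported lazily: lifelines is heavy and only needed for fitting.
    from lifelines import (
        ExponentialFitter,
        LogLogisticFitter,
        LogNormalFitter,
        WeibullFitter,
    )

    if distribution == "weibull":
        f = WeibullFitter().fit(times, observed)
        # S(t) = exp(-(t/lambda_)**rho_)  ->  intercept = ln(lambda_), scale = 1/rho_
        return math.log(f.lambda_), 1.0 / f.rho_, f.log_likelihood_, 2
    if distribution == "exponential":
        f = ExponentialFitter().fit(times, observed)
        # S(t) = exp(-t/lambda_); AFT scale fixed at 1.
        return math.log(f.lambda_), 1.0, f.log_likelihood_, 1
    if distribution == "lognormal":
        f = LogNormalFitter().fit(times, observed)
        return f.mu_, f.sigma_, f.log_likelihood_, 2
    if distribution == "loglogistic":
        f = LogLogisticFitter().fit(times, observed)
        # S(t) = 1/(1+(t/alpha_)**beta_)
        return math.log(f.alpha_), 1.0 / f.beta_, f.log_likelihood_, 2
    raise AssertionError(distribution)


def _fit_plain_logistic(times, observed):
    # Right-censored MLE of a logistic location/scale model on the raw time
    # axis (support includes negative times; kept as a selection candidate
    # only). No lifelines univariate fitter exists for this model.
    def negll(theta):
        mu, log_s = theta
        s = math.exp(log_s)
        ll = stats.logistic.logpdf(times[observed], mu, s).sum()
        ll += stats.logistic.logsf(times[~observed], mu, s).sum()
        return -ll

    x0 = np.array([times.mean(), math.log(max(times.std(), 1e-3))])
    res = optimize.minimize(negll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-8})
    mu, log_s = res.x
    return float(mu), float(math.exp(log_s)), float(-res.fun), 2


def fit_parametric(data: pd.DataFrame, cause: str, distribution: str) -> AFTFit:
    """Fit one candidate AFT distribution to cause-specific event times.

    Parameters
    ----------
    data
        Cohort table with columns ``time`` (years, > 0) and ``event``
        (one of ``dialysis``, ``death``, ``censored``).
    cause
        Which transition to fit; events of the competing cause are treated
        as right-censored at their observed time.
    distribution
        One of :data:`DISTRIBUTIONS`.
    """
    if distribution not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {distribution!r}; choose from {DISTRIBUTIONS}")
    times, observed = _extract_arrays(data, cause)
    if distribution == "logistic":
        intercept, scale, loglik, k = _fit_plain_logistic(times, observed)
    else:
        intercept, scale, loglik, k = _fit_lifelines(times, observed, distribution)
    return AFTFit(
        distribution=distribution,
        intercept=float(intercept),
        scale=float(scale),
        loglik=float(loglik),
        n_params=k,
        n_obs=len(times),
    )


def select_best(fits: Iterable[AFTFit], criterion: str = "aic") -> FitSelection:
    """Pick the fit minimising AIC or BIC.

    Ties are broken by the canonical ordering :data:`DISTRIBUTIONS`
    (weibull < exponential < lognormal < loglogistic < logistic).
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    fits = tuple(fits)
    if not fits:
        raise ValueError("need at least one fit to select from")
    best = min(fits, key=lambda f: (getattr(f, criterion), DISTRIBUTIONS.index(f.distribution)))
    return FitSelection(fits=fits, selected=best, criterion=criterion)


def calibrate(
    data: pd.DataFrame,
    cause: str,
    distributions: Sequence[str] = DISTRIBUTIONS,
    criterion: str = "aic",
) -> FitSelection:
    """Fit every candidate distribution for one cause and select the best."""
    return select_best((fit_parametric(data, cause, d) for d in distributions), criterion)


def calibration_report(data: pd.DataFrame, criterion: str = "aic") -> dict:
    """Full two-cause calibration as a JSON-serialisable report.

    For each cause all five candidates are fitted and compared; the derived
    (lambda, gamma) is included when the winning distribution converts.
    """
    report: dict = {"criterion": criterion, "n_obs": int(len(data)), "causes": {}}
    for cause in ("dialysis", "death"):
        sel = calibrate(data, cause, criterion=criterion)
        entry = {
            "fits": [
                {
                    "distribution": f.distribution,
                    "intercept": f.intercept,
                    "scale": f.scale,
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "bic": f.bic,
                }
                for f in sel.fits
            ],
            "selected": sel.selected.distribution,
        }
        if sel.selected.distribution in _CONVERTIBLE:
            wp = sel.selected.to_weibull()
            entry["weibull_params"] = {"lambda": wp.lam, "gamma": wp.gamma}
        report["causes"][cause] = entry
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
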
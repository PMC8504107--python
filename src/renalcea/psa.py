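"""Probabilistic sensitivity analysis over the model's parameter ranges.

Each Monte Carlo iteration independently draws every varying parameter
uniformly over its [low, high] range (the source analysis names ranges but
no distributions; uniform is the assumption-minimal choice and is recorded
in the summary metadata), reruns both arms, and records the incremental
cost, QALYs and ICER with the RHP-minus-standard-of-care sign convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import WeibullParams, apply_hazard_ratio
from .costs import CostInputs
from .markov import (
    CEAComparison,
    ModelSettings,
    ModelValidityError,
    TransitionSet,
    compare_arms,
    run_arm,
)

__all__ = ["ParameterRange", "PSASummary", "PSAResult", "run_psa", "summarize_iterations"]

#: Parameter names run_psa understands, in sampling order.
PARAMETER_NAMES = (
    "hr_dialysis",
    "hr_death",
    "lambda_dialysis",
    "gamma_dialysis",
    "lambda_death",
    "gamma_death",
    "rhp_treatment_annual",
    "soc_treatment_annual",
    "dialysis_annual",
    "utility_ckd",
    "utility_dialysis",
    "discount_rate",
)

_MAX_RESAMPLES = 100


@dataclass(frozen=True)
class ParameterRange:
    """Base value and sampling interval of one model parameter."""

    name: str
    base: float
    low: float
    high: float
    sampling: str = "uniform"  # or "fixed"

    def __post_init__(self) -> None:
        if self.name not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {self.name!r}; known: {PARAMETER_NAMES}")
        if self.sampling not in ("uniform", "fixed"):
            raise ValueError(f"sampling must be 'uniform' or 'fixed', got {self.sampling!r}")
        if self.sampling == "fixed":
            if not (self.low == self.base == self.high):
                raise ValueError(f"fixed parameter {self.name} must have low == base == high")
        elif not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: need low <= base <= high, got {self.low}, {self.base}, {self.high}"
            )


@dataclass(frozen=True)
class PSASummary:
    """Descriptive statistics of the incremental results over all iterations.

    ``rse_percent`` entries are ``None`` where undefined (zero mean, or a
    single iteration). ``n_dominant`` counts iterations with negative
    incremental cost and positive incremental QALYs.
    """

    n_iterations: int
    stats: dict  # {quantity: {mean, sd, rse_percent, min, max}}
    n_dominant: int
    sampling: str = "uniform"
    sign_convention: str = "rhp_minus_soc"


@dataclass(frozen=True)
class PSAResult:
    summary: PSASummary
    iterations: pd.DataFrame  # sampled parameters + deltas + icer per iteration


def _stat_block(x: np.ndarray, n: int) -> dict:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n > 1 else None
    rse = None
    if sd is not None and mean != 0.0:
        rse = sd / abs(mean) * 100.0
    return {
        "mean": mean,
        "sd": sd,
        "rse_percent": rse,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def summarize_iterations(table: pd.DataFrame, sampling: str = "uniform") -> PSASummary:
    """Summarise a per-iteration table with columns delta_cost, delta_qaly,
    icer_per_qaly (sample-SD denominator n-1; RSE = SD/|mean|*100)."""
    if len(table) == 0:
        raise ValueError("cannot summarise an empty iteration table")
    n = len(table)
    stats = {}
    for col in ("delta_cost", "delta_qaly", "icer_per_qaly"):
        x = table[col].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]  # icer undefined when delta_qaly == 0
        stats[col] = _stat_block(finite, len(finite)) if len(finite) else None
    dominant = int(((table["delta_cost"] < 0) & (table["delta_qaly"] > 0)).sum())
    return PSASummary(n_iterations=n, stats=stats, n_dominant=dominant, sampling=sampling)


def _model_inputs(draw: dict, base_costs: CostInputs, base_settings: ModelSettings):
    soc = TransitionSet(
        ckd_to_dialysis=WeibullParams(draw["lambda_dialysis"], draw["gamma_dialysis"]),
        ckd_to_death=WeibullParams(draw["lambda_death"], draw["gamma_death"]),
        dialysis_to_death=0.05,
    )
    rhp = TransitionSet(
        ckd_to_dialysis=apply_hazard_ratio(soc.ckd_to_dialysis, draw["hr_dialysis"]),
        ckd_to_death=apply_hazard_ratio(soc.ckd_to_death, draw["hr_death"]),
        dialysis_to_death=soc.dialysis_to_death,
    )
    costs = replace(
        base_costs,
        rhp_treatment_annual=draw["rhp_treatment_annual"],
        soc_treatment_annual=draw["soc_treatment_annual"],
        dialysis_annual=draw["dialysis_annual"],
    )
    settings = replace(
        base_settings,
        utility_ckd=draw["utility_ckd"],
        utility_dialysis=draw["utility_dialysis"],
        discount_rate=draw["discount_rate"],
    )
    return rhp, soc, costs, settings


def run_psa(
    ranges: list[ParameterRange],
    base_costs: CostInputs,
    base_settings: ModelSettings,
    n_iterations: int,
    seed: int,
    dialysis_to_death: float = 0.05,
) -> PSAResult:
    """Monte Carlo PSA: sample, rerun both arms, record incremental results.

    ``ranges`` must cover every name in :data:`PARAMETER_NAMES` exactly once
    (use ``sampling="fixed"`` to pin a parameter at its base value). Sampled
    combinations that violate model validity are flagged and resampled, with
    a hard cap of 100 resamples per iteration. Identical seeds give
    bit-identical iteration tables.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    by_name = {r.name: r for r in ranges}
    missing = set(PARAMETER_NAMES) - set(by_name)
    if missing:
        raise ValueError(f"missing parameter range(s): {sorted(missing)}")
    if len(ranges) != len(by_name):
        raise ValueError("duplicate parameter ranges")

    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        for attempt in range(_MAX_RESAMPLES + 1):
            draw = {}
            for name in PARAMETER_NAMES:
                pr = by_name[name]
                if pr.sampling == "fixed" or pr.low == pr.high:
                    draw[name] = pr.base
                else:
                    draw[name] = rng.uniform(pr.low, pr.high)
            try:
                rhp_t, soc_t, costs, settings = _model_inputs(draw, base_costs, base_settings)
                rhp = run_arm(rhp_t, costs, settings, "rhp")
                soc = run_arm(soc_t, costs, settings, "soc")
            except ModelValidityError:
                if attempt == _MAX_RESAMPLES:
                    raise ModelValidityError(
                        f"iteration {it}: no valid draw after {_MAX_RESAMPLES} resamples"
                    )
                continue
            break
        cmp: CEAComparison = compare_arms(rhp, soc, settings)
        row = {"iteration": it, **draw,
               "delta_cost": cmp.delta_cost,
               "delta_yl": cmp.delta_yl,
               "delta_qaly": cmp.delta_qaly,
               "icer_per_qaly": cmp.icer_per_qaly if cmp.icer_per_qaly is not None else math.nan,
               "dominant": cmp.dominance.value == "dominant"}
        rows.append(row)
    table = pd.DataFrame(rows)
    return PSAResult(summary=summarize_iterations(table), iterations=table)
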
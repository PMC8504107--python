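"""Three-state Markov cohort model: CKD -> dialysis -> death.

A closed cohort starts in the pooled CKD state and is stepped through
annual cycles. Exits from CKD use time-varying Weibull cycle probabilities
(cause-specific curves, optionally hazard-ratio adjusted per arm); the
dialysis state carries a fixed per-cycle mortality (memoryless, as the
model has no tunnel states); death absorbs. Costs, dialysis-free life
years (YL) and QALYs are accrued at the end of each cycle on the
post-transition occupancy and discounted geometrically — no half-cycle
correction. The cohort size only matters for allocating the program's
fixed costs; state dynamics are deterministic occupancy fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .calibration import WeibullParams, transition_probability
from .costs import CostInputs, program_cost_per_person

__all__ = [
    "TransitionSet",
    "ModelSettings",
    "CohortTrace",
    "ArmResult",
    "Dominance",
    "CEAComparison",
    "ModelValidityError",
    "run_arm",
    "compare_arms",
    "event_free_curve",
    "microsimulate",
]


class ModelValidityError(ValueError):
    """Raised when per-cycle exit probabilities are not a valid distribution."""


@dataclass(frozen=True)
class TransitionSet:
    """Per-arm transition generators (post any hazard-ratio adjustment)."""

    ckd_to_dialysis: WeibullParams
    ckd_to_death: WeibullParams
    dialysis_to_death: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dialysis_to_death <= 1.0:
            raise ValueError(
                f"dialysis_to_death must be a probability, got {self.dialysis_to_death}"
            )


@dataclass(frozen=True)
class ModelSettings:
    """Cycle structure, discounting, utilities and the WTP anchor."""

    n_cycles: int = 30
    cycle_length: float = 1.0
    discount_rate: float = 0.03
    cohort_size: int = 1000
    utility_ckd: float = 0.84
    utility_dialysis: float = 0.65
    wtp_per_capita_gdp: float = 6571.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        for name in ("utility_ckd", "utility_dialysis"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {u}")
        if self.wtp_per_capita_gdp < 0:
            raise ValueError("wtp_per_capita_gdp must be >= 0")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy (t = 0..T) and discounted accruals (t = 1..T)."""

    ckd: np.ndarray
    dialysis: np.ndarray
    dead: np.ndarray
    disc_cost: np.ndarray
    disc_yl: np.ndarray
    disc_qaly: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        acc = lambda a: np.concatenate([[np.nan], a])  # accruals start at t=1
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.ckd)),
                "ckd": self.ckd,
                "dialysis": self.dialysis,
                "dead": self.dead,
                "disc_cost": acc(self.disc_cost),
                "disc_yl": acc(self.disc_yl),
                "disc_qaly": acc(self.disc_qaly),
            }
        )


@dataclass(frozen=True)
class ArmResult:
    """Discounted per-person totals for one arm."""

    arm: str
    total_cost: float
    total_yl: float
    total_qaly: float
    trace: CohortTrace


class Dominance(str, Enum):
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    TRADEOFF_BELOW_WTP = "tradeoff_below_wtp"
    TRADEOFF_ABOVE_WTP = "tradeoff_above_wtp"


@dataclass(frozen=True)
class CEAComparison:
    """Intervention-minus-comparator deltas, ICERs and dominance class.

    ICER fields are ``None`` when the corresponding effect difference is
    exactly zero (undefined ratio).
    """

    delta_cost: float
    delta_yl: float
    delta_qaly: float
    icer_per_yl: float | None
    icer_per_qaly: float | None
    dominance: Dominance


def _cycle_probabilities(transitions: TransitionSet, n_cycles: int):
    cycles = np.arange(1, n_cycles + 1)
    p_dial = transition_probability(transitions.ckd_to_dialysis, cycles)
    p_death = transition_probability(transitions.ckd_to_death, cycles)
    total = p_dial + p_death
    if np.any(total > 1.0):
        c = int(cycles[np.argmax(total > 1.0)])
        raise ModelValidityError(
            f"CKD exit probabilities sum to {total.max():.4f} > 1 at cycle {c}"
        )
    return p_dial, p_death


def run_arm(
    transitions: TransitionSet,
    costs: CostInputs,
    settings: ModelSettings,
    arm: str,
) -> ArmResult:
    """Run the cohort model for one arm and accrue discounted outcomes.

    ``arm`` selects the annual treatment cost and, for ``"rhp"``, adds the
    program's fixed costs: the one-time investment at cycle 0 (undiscounted)
    and the operational cost every cycle thereafter, both spread over the
    initial cohort.
    """
    if arm not in ("rhp", "soc"):
        raise ValueError(f"arm must be 'rhp' or 'soc', got {arm!r}")
    treat = costs.rhp_treatment_annual if arm == "rhp" else costs.soc_treatment_annual
    T = settings.n_cycles
    p_dial, p_death = _cycle_probabilities(transitions, T)
    p_dd = transitions.dialysis_to_death
    r = settings.discount_rate

    ckd = np.empty(T + 1)
    dial = np.empty(T + 1)
    dead = np.empty(T + 1)
    ckd[0], dial[0], dead[0] = 1.0, 0.0, 0.0
    disc_cost = np.empty(T)
    disc_yl = np.empty(T)
    disc_qaly = np.empty(T)

    init_cost = program_cost_per_person(costs, 0) if arm == "rhp" else 0.0

    for t in range(1, T + 1):
        pd_, pm = p_dial[t - 1], p_death[t - 1]
        dial[t] = dial[t - 1] * (1.0 - p_dd) + ckd[t - 1] * pd_
        dead[t] = dead[t - 1] + dial[t - 1] * p_dd + ckd[t - 1] * pm
        ckd[t] = ckd[t - 1] * (1.0 - pd_ - pm)

        df = (1.0 + r) ** (-t)
        per_person_program = program_cost_per_person(costs, t) if arm == "rhp" else 0.0
        disc_cost[t - 1] = df * (
            ckd[t] * treat + dial[t] * costs.dialysis_annual + per_person_program
        )
        disc_yl[t - 1] = df * ckd[t] * settings.cycle_length
        disc_qaly[t - 1] = df * settings.cycle_length * (
            ckd[t] * settings.utility_ckd + dial[t] * settings.utility_dialysis
        )

    trace = CohortTrace(ckd, dial, dead, disc_cost, disc_yl, disc_qaly)
    return ArmResult(
        arm=arm,
        total_cost=float(init_cost + disc_cost.sum()),
        total_yl=float(disc_yl.sum()),
        total_qaly=float(disc_qaly.sum()),
        trace=trace,
    )


def _classify(dc: float, dq: float, icer_q: float | None, wtp: float) -> Dominance:
    if dc < 0 and dq > 0:
        return Dominance.DOMINANT
    if dc > 0 and dq < 0:
        return Dominance.DOMINATED
    if dq == 0 or icer_q is None:
        # undefined ratio: fall back to the cost sign
        return Dominance.TRADEOFF_BELOW_WTP if dc <= 0 else Dominance.TRADEOFF_ABOVE_WTP
    if dq > 0:  # costlier and more effective: acceptable if ICER within WTP
        return Dominance.TRADEOFF_BELOW_WTP if icer_q <= wtp else Dominance.TRADEOFF_ABOVE_WTP
    # cheaper and less effective: acceptable if savings per QALY lost exceed WTP
    return Dominance.TRADEOFF_BELOW_WTP if icer_q >= wtp else Dominance.TRADEOFF_ABOVE_WTP


def compare_arms(
    intervention: ArmResult, comparator: ArmResult, settings: ModelSettings
) -> CEAComparison:
    """Incremental comparison (intervention minus comparator).

    ICERs are computed from unrounded deltas. Trade-off quadrants are
    classified against the willingness-to-pay anchor (per-capita GDP).
    """
    dc = intervention.total_cost - comparator.total_cost
    dy = intervention.total_yl - comparator.total_yl
    dq = intervention.total_qaly - comparator.total_qaly
    icer_yl = dc / dy if dy != 0 else None
    icer_q = dc / dq if dq != 0 else None
    return CEAComparison(
        delta_cost=dc,
        delta_yl=dy,
        delta_qaly=dq,
        icer_per_yl=icer_yl,
        icer_per_qaly=icer_q,
        dominance=_classify(dc, dq, icer_q, settings.wtp_per_capita_gdp),
    )


def event_free_curve(transitions: TransitionSet, settings: ModelSettings) -> np.ndarray:
    """CKD-state occupancy by cycle (event-free survival), t = 0..T."""
    p_dial, p_death = _cycle_probabilities(transitions, settings.n_cycles)
    surv = np.empty(settings.n_cycles + 1)
    surv[0] = 1.0
    surv[1:] = np.cumprod(1.0 - p_dial - p_death)
    return surv


def microsimulate(
    transitions: TransitionSet,
    costs: CostInputs,
    settings: ModelSettings,
    arm: str,
    n_individuals: int,
    seed: int,
) -> ArmResult:
    """Individual-level Monte Carlo replica of :func:`run_arm`.

    Steps ``n_individuals`` simulated patients through the same per-cycle
    probabilities and accrual rules; an independent oracle for validating
    the deterministic cohort expectation (agreement is within Monte-Carlo
    error, not exact).
    """
    if arm not in ("rhp", "soc"):
        raise ValueError(f"arm must be 'rhp' or 'soc', got {arm!r}")
    rng = np.random.default_rng(seed)
    treat = costs.rhp_treatment_annual if arm == "rhp" else costs.soc_treatment_annual
    T = settings.n_cycles
    p_dial, p_death = _cycle_probabilities(transitions, T)
    p_dd = transitions.dialysis_to_death
    r = settings.discount_rate

    CKD, DIAL, DEAD = 0, 1, 2
    state = np.zeros(n_individuals, dtype=np.int8)
    ckd = np.empty(T + 1)
    dial = np.empty(T + 1)
    dead = np.empty(T + 1)
    ckd[0], dial[0], dead[0] = 1.0, 0.0, 0.0
    disc_cost = np.empty(T)
    disc_yl = np.empty(T)
    disc_qaly = np.empty(T)
    init_cost = program_cost_per_person(costs, 0) if arm == "rhp" else 0.0

    for t in range(1, T + 1):
        u = rng.random(n_individuals)
        in_ckd = state == CKD
        in_dial = state == DIAL
        pd_, pm = p_dial[t - 1], p_death[t - 1]
        # single uniform split into [0,pd) -> dialysis, [pd,pd+pm) -> death
        state[in_ckd & (u < pd_)] = DIAL
        state[in_ckd & (u >= pd_) & (u < pd_ + pm)] = DEAD
        state[in_dial & (u < p_dd)] = DEAD

        f_ckd = np.mean(state == CKD)
        f_dial = np.mean(state == DIAL)
        ckd[t], dial[t], dead[t] = f_ckd, f_dial, 1.0 - f_ckd - f_dial
        df = (1.0 + r) ** (-t)
        per_person_program = program_cost_per_person(costs, t) if arm == "rhp" else 0.0
        disc_cost[t - 1] = df * (f_ckd * treat + f_dial * costs.dialysis_annual + per_person_program)
        disc_yl[t - 1] = df * f_ckd * settings.cycle_length
        disc_qaly[t - 1] = df * settings.cycle_length * (
            f_ckd * settings.utility_ckd + f_dial * settings.utility_dialysis
        )

    trace = CohortTrace(ckd, dial, dead, disc_cost, disc_yl, disc_qaly)
    return ArmResult(
        arm=arm,
        total_cost=float(init_cost + disc_cost.sum()),
        total_yl=float(disc_yl.sum()),
        total_qaly=float(disc_qaly.sum()),
        trace=trace,
    )
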
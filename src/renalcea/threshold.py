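"""Break-even analysis on the annual dialysis cost.

The per-person incremental cost between arms is affine in the annual
dialysis cost (both arms' cost streams are linear in it), so the dialysis
price at which the incremental cost crosses zero — the dominance
boundary — has a unique root whenever the intervention arm accrues fewer
discounted dialysis person-years. The root is located by bisection (kept
generic so other cost parameters could be swept the same way) and
cross-checked against the closed-form linear solve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .costs import CostInputs
from .markov import ModelSettings, TransitionSet, run_arm

__all__ = ["ThresholdResult", "find_breakeven_dialysis_cost"]


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    breakeven_value: float
    bracket: tuple[float, float]
    tolerance: float
    affine_root: float
    n_evaluations: int
    endpoint_values: tuple[float, float]


def _delta_cost(
    dialysis_annual: float,
    costs: CostInputs,
    rhp_transitions: TransitionSet,
    soc_transitions: TransitionSet,
    settings: ModelSettings,
) -> float:
    c = replace(costs, dialysis_annual=dialysis_annual)
    rhp = run_arm(rhp_transitions, c, settings, "rhp")
    soc = run_arm(soc_transitions, c, settings, "soc")
    return rhp.total_cost - soc.total_cost


def find_breakeven_dialysis_cost(
    costs: CostInputs,
    rhp_transitions: TransitionSet,
    soc_transitions: TransitionSet,
    settings: ModelSettings,
    bracket: tuple[float, float] = (0.0, 20_000.0),
    tolerance: float = 0.005,
) -> ThresholdResult:
    """Annual dialysis cost at which the incremental cost equals zero.

    All other inputs are held at their base-case values; the dialysis cost
    applies identically in both arms. Requires an incremental-cost sign
    change over ``bracket``. The default tolerance ($0.005 on the price
    axis) is tight enough that the bisection root coincides with the affine
    closed-form solve to within a cent.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError(f"invalid bracket {bracket}")
    f = lambda d: _delta_cost(d, costs, rhp_transitions, soc_transitions, settings)
    f_lo, f_hi = f(lo), f(hi)
    n_eval = 2
    if f_lo == 0.0 and f_hi == 0.0:
        raise ValueError(
            "incremental cost is identically zero over the bracket (identical arms); "
            "the break-even point is degenerate"
        )
    if f_lo * f_hi > 0:
        raise ValueError(
            "incremental cost does not change sign over the bracket: "
            f"delta_cost({lo}) = {f_lo:.2f}, delta_cost({hi}) = {f_hi:.2f}"
        )

    # Closed-form solve of the affine response a + b*d (slope from the endpoints).
    slope = (f_hi - f_lo) / (hi - lo)
    affine_root = lo - f_lo / slope

    a, b, f_a = lo, hi, f_lo
    while (b - a) > tolerance:
        mid = 0.5 * (a + b)
        f_mid = f(mid)
        n_eval += 1
        if f_mid == 0.0:
            a = b = mid
            break
        if f_a * f_mid < 0:
            b = mid
        else:
            a, f_a = mid, f_mid
    root = 0.5 * (a + b)

    return ThresholdResult(
        parameter="dialysis_annual",
        breakeven_value=float(root),
        bracket=(float(lo), float(hi)),
        tolerance=float(tolerance),
        affine_root=float(affine_root),
        n_evaluations=n_eval,
        endpoint_values=(float(f_lo), float(f_hi)),
    )
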
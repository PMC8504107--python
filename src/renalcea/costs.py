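"""Per-cycle cost inputs: stage-weighted treatment costs, dialysis cost,
and program implementation/operational costs.

The pre-dialysis model state pools all CKD stages, so the annual treatment
cost per patient in each arm is a two-level weighted average: within each
KDIGO stage a diabetic/non-diabetic mixture, across stages the cohort's
stage distribution. Dialysis is costed bottom-up from haemodialysis
sessions, per-session drugs and nephrology visits. Program costs are fixed
costs of the intervention (development, training, record keeping), spread
over the initial cohort — they do not scale with survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StageCostRow",
    "CostInputs",
    "DialysisCostComponents",
    "weighted_stage_cost",
    "weighted_cohort_cost",
    "dialysis_annual_cost",
    "program_cost_per_person",
    "read_stage_costs",
]

_STAGES = ("1", "2", "3a", "3b", "4")

#: Stage-weight sums within this relative distance of 1 are renormalised;
#: anything further apart is treated as inconsistent input.
_WEIGHT_SLACK = 0.02


@dataclass(frozen=True)
class StageCostRow:
    """Annual treatment cost for one CKD stage, split by diabetes status."""

    stage: str
    cost_diabetic: float
    cost_nondiabetic: float
    prop_diabetic: float
    stage_weight: float

    def __post_init__(self) -> None:
        if str(self.stage) not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}, got {self.stage!r}")
        for name in ("cost_diabetic", "cost_nondiabetic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.prop_diabetic <= 1.0:
            raise ValueError(f"prop_diabetic must be in [0,1], got {self.prop_diabetic}")
        if not 0.0 <= self.stage_weight <= 1.0:
            raise ValueError(f"stage_weight must be in [0,1], got {self.stage_weight}")


@dataclass(frozen=True)
class CostInputs:
    """Annual cost inputs of the two arms, USD per person-year (program costs
    in USD per cohort)."""

    rhp_treatment_annual: float
    soc_treatment_annual: float
    dialysis_annual: float
    rhp_initial: float
    rhp_operational_annual: float
    cohort_size: int

    def __post_init__(self) -> None:
        for name in ("rhp_treatment_annual", "soc_treatment_annual", "dialysis_annual",
                     "rhp_initial", "rhp_operational_annual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")


@dataclass(frozen=True)
class DialysisCostComponents:
    """Bottom-up components of one year of haemodialysis."""

    sessions_per_year: float
    cost_per_session: float
    drugs_per_session: float
    nephrology_visits_per_year: float
    cost_per_visit: float

    def __post_init__(self) -> None:
        for name in ("sessions_per_year", "cost_per_session", "drugs_per_session",
                     "nephrology_visits_per_year", "cost_per_visit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def weighted_stage_cost(row: StageCostRow) -> float:
    """Diabetes-mixture cost of one stage, USD/person-year."""
    return row.prop_diabetic * row.cost_diabetic + (1.0 - row.prop_diabetic) * row.cost_nondiabetic


def weighted_cohort_cost(rows: Iterable[StageCostRow]) -> float:
    """Stage- and diabetes-weighted annual treatment cost of the pooled cohort.

    Stage weights must sum to 1 within 2% (renormalised); larger deviations
    raise, since they indicate an inconsistent stage table.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one stage row")
    total_w = sum(r.stage_weight for r in rows)
    if abs(total_w - 1.0) > _WEIGHT_SLACK:
        raise ValueError(f"stage weights sum to {total_w:.4f}, not within 2% of 1")
    return sum(r.stage_weight * weighted_stage_cost(r) for r in rows) / total_w


def dialysis_annual_cost(components: DialysisCostComponents) -> float:
    """Annual haemodialysis cost: sessions*(session+drugs) + visits*visit."""
    c = components
    return (c.sessions_per_year * (c.cost_per_session + c.drugs_per_session)
            + c.nephrology_visits_per_year * c.cost_per_visit)


def program_cost_per_person(inputs: CostInputs, cycle: int) -> float:
    """Program (fixed) cost allocated per initial cohort member at ``cycle``.

    Cycle 0 carries the one-time investment, every later cycle the annual
    operational cost; fixed costs are spread over the initial cohort and do
    not scale with survivors.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if cycle == 0:
        return inputs.rhp_initial / inputs.cohort_size
    return inputs.rhp_operational_annual / inputs.cohort_size


def read_stage_costs(path) -> list[StageCostRow]:
    """Load a stage-cost table from CSV (columns matching StageCostRow fields)."""
    df = pd.read_csv(path, dtype={"stage": str})
    required = {"stage", "cost_diabetic", "cost_nondiabetic", "prop_diabetic", "stage_weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stage cost table lacks column(s) {sorted(missing)}")
    return [StageCostRow(**rec) for rec in df[sorted(required)].to_dict("records")]
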